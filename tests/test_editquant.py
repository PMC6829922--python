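"""Quantification rules: trimming, window semantics, control subtraction,
allele tables and large-insertion attribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyedit.editquant import (
    NoDataError,
    QuantConfig,
    allele_frequency_table,
    call_edit,
    detect_large_insertions,
    indel_frequency,
    large_insertion_read_rate,
    quantify_reads,
    trim_quality,
)
from polyedit.homoeoassign import PHASE2, align_affine
from polyedit.synthetic_data import (
    SimConfig,
    SimRead,
    make_reference_set,
    make_vector_set,
    simulate_reads,
)


def _read(seq, quals):
    qual = "".join(chr(q + 33) for q in quals)
    return SimRead("r1", seq, qual)


class TestTrimQuality:
    def test_high_quality_read_untouched(self):
        r = _read("ACGT" * 10, [37] * 40)
        assert trim_quality(r) is r

    def test_trailing_low_quality_removed(self):
        r = _read("ACGT" * 10, [37] * 37 + [2, 2, 2])
        out = trim_quality(r, 30)
        assert out.sequence == r.sequence[:37]
        assert len(out.quality) == 37

    def test_all_low_quality_discarded(self):
        r = _read("ACGT" * 10, [2] * 40)
        assert trim_quality(r, 30) is None

    def test_short_survivor_discarded(self):
        r = _read("ACGT" * 10, [2] * 15 + [37] * 10 + [2] * 15)
        assert trim_quality(r, 30, min_length=20) is None

    def test_malformed_quality_raises(self):
        r = SimRead("r1", "ACGT", "II")
        with pytest.raises(ValueError):
            trim_quality(r)


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(31)
    return "".join(rng.choice(list("ACGT"), 200))


class TestCallEdit:
    def test_substitution_at_cut_is_unmodified(self, ref):
        # a sequencing-error substitution carries low quality, so the
        # quality-scaled mismatch stays a mismatch rather than a gap pair
        cut = 100
        read = ref[:cut] + ("A" if ref[cut] != "A" else "C") + ref[cut + 1 :]
        qual = np.full(len(read), 37)
        qual[cut] = 18
        aln = align_affine(read, ref, PHASE2, qualities=qual)
        call = call_edit(aln, cut, read=SimRead("r", read, "I" * len(read)))
        assert call.status == "unmodified"
        assert call.events == []

    def test_one_bp_insertion_at_cut_is_edited(self, ref):
        cut = 100
        read = ref[:cut] + "G" + ref[cut:]
        aln = align_affine(read, ref, PHASE2)
        call = call_edit(aln, cut, read=SimRead("r", read, "I" * len(read)))
        assert call.status == "edited"
        # leftmost placement may slide the insert within a homopolymer run
        (ev,) = call.events
        assert (ev.kind, ev.size) == ("ins", 1)
        assert abs(ev.ref_start - cut) <= 3

    def test_compound_event_keeps_both_sizes(self, ref):
        # 42 bp insertion plus 31 bp deletion at the cut: both reported
        cut = 100
        rng = np.random.default_rng(5)
        insert = "".join(rng.choice(list("ACGT"), 42))
        read = ref[:cut] + insert + ref[cut + 31 :]
        aln = align_affine(read, ref, PHASE2)
        call = call_edit(
            aln, cut, read=SimRead("r", read, "I" * len(read)), reference=ref
        )
        sizes = sorted((e.kind, e.size) for e in call.events)
        assert ("ins", 42) in sizes and ("del", 31) in sizes
        assert call.status == "edited"

    def test_indel_outside_window_is_unmodified(self, ref):
        cut = 100
        read = ref[:30] + ref[33:]  # 3 bp deletion far upstream of the window
        aln = align_affine(read, ref, PHASE2)
        call = call_edit(aln, cut, read=SimRead("r", read, "I" * len(read)))
        assert call.status == "unmodified"
        assert len(call.events) == 1  # recorded but not window-overlapping
        assert call.window_overlap == [False]

    def test_deletion_partially_overlapping_window_counts(self, ref):
        cut = 100
        # deletion [75, 85) straddles the window edge at cut-20 = 80
        read = ref[:75] + ref[85:]
        aln = align_affine(read, ref, PHASE2)
        call = call_edit(aln, cut, read=SimRead("r", read, "I" * len(read)))
        assert call.status == "edited"

    def test_event_inside_end_margin_ignored(self, ref):
        cut = 10  # window reaches the read start
        read = "GG" + ref  # 2 bp insertion entirely inside the left margin
        aln = align_affine(read, ref, PHASE2)
        call = call_edit(aln, cut, read=SimRead("r", read, "I" * len(read)))
        assert call.events == []
        assert call.status == "unmodified"

    def test_cut_outside_reference_raises(self, ref):
        aln = align_affine(ref, ref, PHASE2)
        with pytest.raises(ValueError):
            call_edit(aln, 500)

    def test_window_monotonicity(self, ref):
        # enlarging the window never turns an edited read unmodified
        cut = 100
        reads = [
            ref[:60] + ref[63:],
            ref[:99] + "T" + ref[99:],
            ref[:119] + ref[122:],
        ]
        for read in reads:
            aln = align_affine(read, ref, PHASE2)
            edited = []
            for w in (5, 20, 40):
                cfg = QuantConfig(window_halfwidth=w)
                call = call_edit(aln, cut, cfg, read=SimRead("r", read, "I" * len(read)))
                edited.append(call.status == "edited")
            assert edited == sorted(edited)


class TestIndelFrequency:
    def _calls(self, n_edited, n_total, allele="7AS"):
        from polyedit.editquant import EditCall

        calls = [
            EditCall(f"e{i}", allele, "edited", [], [True]) for i in range(n_edited)
        ]
        calls += [
            EditCall(f"u{i}", allele, "unmodified")
            for i in range(n_total - n_edited)
        ]
        return calls

    def test_control_subtraction_arithmetic(self):
        est = indel_frequency(self._calls(100, 1000), self._calls(2, 1000), "7AS")
        assert est.indel_frequency == pytest.approx(10.0 - 0.2)

    def test_equal_treated_and_control_gives_zero(self):
        est = indel_frequency(self._calls(5, 100), self._calls(5, 100))
        assert est.indel_frequency == 0.0

    def test_negative_difference_warns_but_reports(self):
        with pytest.warns(UserWarning):
            est = indel_frequency(self._calls(1, 100), self._calls(5, 100))
        assert est.indel_frequency == pytest.approx(-4.0)

    def test_empty_denominator_raises(self):
        with pytest.raises(NoDataError):
            indel_frequency([], self._calls(1, 10))


class TestPipeline:
    def test_partition_and_binomial_recovery(self):
        p = 0.05
        cfg = SimConfig(
            seed=41, edit_fraction_per_allele=p, n_reads_per_allele=2000,
            n_alleles=3,
        )
        refs = make_reference_set(cfg)
        reads, _ = simulate_reads(refs, cfg)
        run = quantify_reads(reads, refs)
        for allele, calls in run.calls.items():
            statuses = {c.status for c in calls}
            assert statuses <= {"edited", "unmodified"}
            pct = 100.0 * sum(c.status == "edited" for c in calls) / len(calls)
            tol = 3 * math.sqrt(p * (1 - p) / len(calls)) * 100
            assert abs(pct - p * 100) <= tol

    def test_substitution_only_errors_give_exactly_zero_edited(self):
        cfg = SimConfig(
            seed=42, edit_fraction_per_allele=0.0, substitution_error_rate=0.01,
            n_reads_per_allele=500,
        )
        refs = make_reference_set(cfg)
        reads, _ = simulate_reads(refs, cfg)
        run = quantify_reads(reads, refs)
        assert all(
            c.status == "unmodified" for calls in run.calls.values() for c in calls
        )

    def test_read_count_conservation_through_assign_and_quantify(self):
        cfg = SimConfig(seed=43, n_reads_per_allele=400)
        refs = make_reference_set(cfg)
        reads, _ = simulate_reads(refs, cfg)
        run = quantify_reads(reads, refs)
        n_called = sum(len(c) for c in run.calls.values())
        assert n_called + run.n_discarded + run.n_unassigned == len(reads)


class TestAlleleFrequencyTable:
    def _call(self, rid, sig, status="unmodified"):
        from polyedit.editquant import EditCall

        return EditCall(rid, "7AS", status, aligned_sequence=sig)

    def test_uniform_reads_single_row(self):
        calls = [self._call(f"r{i}", "ACGT") for i in range(100)]
        df = allele_frequency_table(calls)
        assert len(df) == 1
        assert df.loc[0, "pct"] == pytest.approx(100.0)

    def test_ninety_ten_split(self):
        calls = [self._call(f"w{i}", "ACGT") for i in range(90)]
        calls += [self._call(f"m{i}", "ACGGT", "edited") for i in range(10)]
        df = allele_frequency_table(calls)
        assert df["pct"].tolist() == pytest.approx([90.0, 10.0])
        assert df.loc[0, "signature"] == "ACGT"

    @settings(max_examples=20, deadline=None)
    @given(counts=st.lists(st.integers(1, 30), min_size=1, max_size=8))
    def test_percentages_sum_to_hundred(self, counts):
        calls = [
            self._call(f"r{i}-{j}", f"SIG{i}")
            for i, c in enumerate(counts)
            for j in range(c)
        ]
        df = allele_frequency_table(calls)
        assert df["pct"].sum() == pytest.approx(100.0, abs=0.01)


class TestLargeInsertions:
    def _call_with_insert(self, rid, insert, status="edited"):
        from polyedit.editquant import EditCall
        from polyedit.homoeoassign import IndelEvent

        ev = IndelEvent("ins", len(insert), 100, 100)
        return EditCall(rid, "7AS", status, [ev], [True], [insert])

    def test_size_threshold_is_twenty(self):
        vectors = {"vec": "A" * 50}
        calls = [
            self._call_with_insert("a", "G" * 19),
            self._call_with_insert("b", "C" * 20),
        ]
        found = detect_large_insertions(calls, vectors)
        assert [li.size for li in found] == [20]

    def test_origin_attribution_forward_and_reverse(self):
        rng = np.random.default_rng(6)
        vec = "".join(rng.choice(list("ACGT"), 500))
        from polyedit.homoeoassign import revcomp

        fwd = vec[100:130]
        rev = revcomp(vec[200:225])
        calls = [
            self._call_with_insert("a", fwd),
            self._call_with_insert("b", rev),
        ]
        found = {li.sequence: li for li in detect_large_insertions(calls, {"v": vec})}
        assert found[fwd].origin == ("v", 100, "+")
        assert found[rev].origin == ("v", 200, "-")

    def test_insert_reported_without_vectors(self):
        calls = [self._call_with_insert("a", "ACGTACGTACGTACGTACGTT")]
        (li,) = detect_large_insertions(calls, None)
        assert li.origin is None
        assert li.count == 1

    def test_pct_denominator_is_edited_reads(self):
        from polyedit.editquant import EditCall

        calls = [self._call_with_insert("a", "C" * 25)]
        calls += [EditCall(f"e{i}", "7AS", "edited", [], [True]) for i in range(3)]
        calls += [EditCall(f"u{i}", "7AS", "unmodified") for i in range(96)]
        (li,) = detect_large_insertions(calls, None)
        assert li.pct_of_edited_reads == pytest.approx(25.0)
        assert large_insertion_read_rate(calls) == pytest.approx(25.0)

    def test_end_to_end_vector_insert_recovery(self):
        vectors = make_vector_set(seed=7)
        cfg = SimConfig(
            seed=44, edit_fraction_per_allele=1.0,
            large_insertion_fraction_of_edited=1.0, vector_sequences=vectors,
            n_reads_per_allele=30, substitution_error_rate=0.0,
        )
        refs = make_reference_set(cfg)
        reads, truth = simulate_reads(refs, cfg)
        run = quantify_reads(reads, refs)
        found = detect_large_insertions(run.all_calls(), vectors)
        assert found
        assert all(li.origin is not None for li in found)
        assert large_insertion_read_rate(run.all_calls()) == pytest.approx(100.0)
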