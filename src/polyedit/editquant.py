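"""Windowed indel quantification with control subtraction and large-insertion
detection.

Assigned reads are classified as edited or unmodified by the indels their
end-to-end alignment places inside a window around the canonical cut site
(default half-width 20 bp).  Substitutions never count (so a pure
substitution-error process yields exactly 0% edited), events confined to the
excluded read-end margins (default 5 bp each side) are ignored, and reads are
Q30 end-trimmed before alignment with too-short survivors discarded.  The
editing frequency of a treated sample is reported minus that of its negative
control.  Insertions of >= 20 bp are additionally collected and attributed to
transformation vectors by exact (forward or reverse-complement) substring
match, with their frequency expressed as a percent of edited reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import homoeoassign
from .homoeoassign import (
    PHASE1,
    PHASE2,
    AlignmentResult,
    Assignment,
    IndelEvent,
    indel_events,
    revcomp,
)
from .synthetic_data import ReferenceSet, SimRead

__all__ = [
    "QuantConfig",
    "EditCall",
    "EditingEstimate",
    "LargeInsertion",
    "RunCalls",
    "NoDataError",
    "trim_quality",
    "call_edit",
    "consolidated_events",
    "quantify_reads",
    "indel_frequency",
    "allele_frequency_table",
    "detect_large_insertions",
    "large_insertion_read_rate",
]


class NoDataError(ValueError):
    """No usable reads for the requested allele after discards."""


@dataclass(frozen=True)
class QuantConfig:
    """Quantification-window and filtering parameters.

    The quantification window is ``[cut - window_halfwidth,
    cut + window_halfwidth)`` in reference coordinates (left-inclusive,
    right-exclusive).  ``exclude_left``/``exclude_right`` are read-end margins
    inside which events are ignored when entirely contained.
    """

    window_halfwidth: int = 20
    exclude_left: int = 5
    exclude_right: int = 5
    min_quality: int = 30
    ignore_substitutions: bool = True
    min_large_insertion: int = 20
    #: aligned (match/mismatch) runs at least this long separate indel
    #: clusters; shorter runs inside a cluster are coincidental diagonal
    #: matches and are folded back into the compound event sizes
    event_merge_anchor: int = 10

    def __post_init__(self):
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")
        if min(self.exclude_left, self.exclude_right, self.min_quality,
               self.min_large_insertion) < 0:
            raise ValueError("parameters must be nonnegative")


@dataclass
class EditCall:
    """Edited/unmodified classification of one assigned read.

    ``events`` are the counted (non-margin) indel events; insertion and
    deletion sizes of a compound event are kept separate by construction.
    ``window_overlap`` flags, per event, whether it intersects the window.
    ``inserted_sequences`` holds the read bases of each insertion event, in
    event order (empty string for deletions).
    """

    read_id: str
    allele_id: str
    status: str  # "unmodified" | "edited" | "discarded"
    events: list = field(default_factory=list)
    window_overlap: list = field(default_factory=list)
    inserted_sequences: list = field(default_factory=list)
    aligned_sequence: Optional[str] = None


@dataclass
class EditingEstimate:
    """Control-subtracted editing frequency for one allele (percent units)."""

    allele_id: str
    pct_edited_treated: float
    pct_edited_control: float

    @property
    def indel_frequency(self) -> float:
        return self.pct_edited_treated - self.pct_edited_control


@dataclass
class LargeInsertion:
    """A >= min-size insertion, optionally attributed to a vector.

    ``origin`` is ``(vector name, offset, strand)`` on an exact substring
    match (forward or reverse complement), else None.  ``pct_of_edited_reads``
    uses edited reads -- not total reads -- as the denominator.
    """

    sequence: str
    size: int
    origin: Optional[tuple]
    count: int
    pct_of_edited_reads: float


@dataclass
class RunCalls:
    """Per-allele edit calls for one sample run, plus bookkeeping."""

    calls: dict  # allele id -> list[EditCall]
    n_discarded: int
    n_unassigned: int
    assignments: list = field(default_factory=list, repr=False)

    def all_calls(self) -> list[EditCall]:
        return [c for calls in self.calls.values() for c in calls]


def _trim_bounds(
    read: SimRead, min_quality: int, min_length: int
) -> Optional[tuple[int, int]]:
    if len(read.quality) != len(read.sequence):
        raise ValueError(f"malformed quality string for read {read.read_id}")
    q = read.quality_array()
    keep = np.flatnonzero(q >= min_quality)
    if keep.size == 0:
        return None
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    if hi - lo < min_length:
        return None
    return lo, hi


def trim_quality(
    read: SimRead, min_quality: int = 30, min_length: int = 20
) -> Optional[SimRead]:
    """End-trim bases below ``min_quality``; return None (discard) if the
    surviving read is shorter than ``min_length``.

    Trimming is leading/trailing per-base: bases are removed from each end
    until one with Phred >= ``min_quality`` is met.  ``min_length`` defaults
    to twice the combined end-exclusion margins (2 * (5 + 5)).
    """
    bounds = _trim_bounds(read, min_quality, min_length)
    if bounds is None:
        return None
    lo, hi = bounds
    if lo == 0 and hi == len(read.sequence):
        return read
    return SimRead(read.read_id, read.sequence[lo:hi], read.quality[lo:hi])


def _aligned_signature(alignment: AlignmentResult, read_seq: str) -> str:
    """Reference-anchored aligned read string: deletions as '-', insertions
    included in place (so identical editing outcomes share a signature)."""
    parts = []
    rp = 0
    for op, length in alignment.operations:
        if op in ("match", "mismatch", "ins"):
            parts.append(read_seq[rp : rp + length])
            rp += length
        else:
            parts.append("-" * length)
    return "".join(parts)


def consolidated_events(
    alignment: AlignmentResult,
    min_anchor: int = 10,
    read_seq: Optional[str] = None,
    ref_seq: Optional[str] = None,
    anchor: Optional[int] = None,
    skip_balanced: bool = False,
) -> list[IndelEvent]:
    """Cluster nearby indel ops into compound events with true segment sizes.

    Under affine pricing an optimal alignment of a large or compound insertion
    fragments the event: short coincidental diagonal matches inside the
    inserted segment are cheaper than staying in the gap, so a true +42/-31
    outcome appears as several small gaps.  Merging all indel ops separated by
    aligned runs shorter than ``min_anchor`` and re-reading the cluster's read
    span (R) and reference span (G) recovers the molecular interpretation: the
    read segment of length R replaced the reference segment of length G,
    reported as an insertion of R and/or a deletion of G at the cluster start.
    """
    raw = []
    ref_pos = read_pos = 0
    for op, length in alignment.operations:
        raw.append((op, length, ref_pos, read_pos))
        if op != "ins":
            ref_pos += length
        if op != "del":
            read_pos += length
    clusters: list[list[tuple]] = []
    aligned_since = None  # aligned bases since last indel op in open cluster
    for item in raw:
        op = item[0]
        if op in ("match", "mismatch"):
            if aligned_since is not None:
                aligned_since += item[1]
                if aligned_since >= min_anchor:
                    aligned_since = None
            continue
        if aligned_since is None:
            clusters.append([item])
        else:
            clusters[-1].append(item)
        aligned_since = 0
    out = []
    for cluster in clusters:
        first = cluster[0]
        last = cluster[-1]
        ref_start, read_start = first[2], first[3]
        ref_end = last[2] + (0 if last[0] == "ins" else last[1])
        read_end = last[3] + (0 if last[0] == "del" else last[1])
        if read_seq is not None and ref_seq is not None:
            # normalise: trim ambiguity-matched bases shared by the replaced
            # read and reference segments from both ends
            while (
                read_start < read_end
                and ref_start < ref_end
                and read_seq[read_start] == ref_seq[ref_start]
            ):
                read_start += 1
                ref_start += 1
            while (
                read_start < read_end
                and ref_start < ref_end
                and read_seq[read_end - 1] == ref_seq[ref_end - 1]
            ):
                read_end -= 1
                ref_end -= 1
        R = read_end - read_start
        G = ref_end - ref_start
        if skip_balanced and R == G:
            # equal-length replacement: net length change zero, i.e. a
            # multi-nucleotide substitution in gap notation (the affine
            # pricing renders adjacent high-quality mismatches as a balanced
            # gap pair); substitutions are ignored by contract
            continue
        if R > 0 and G == 0 and read_seq is not None and ref_seq is not None:
            # pure insertion: its placement is ambiguous when flanking bases
            # match the segment ends; slide to the equivalent placement
            # nearest the anchor (cut site) so the reported segment is the
            # biologically inserted one
            seg = list(read_seq[read_start:read_end])
            if anchor is not None:
                while (
                    ref_start < anchor
                    and ref_start < len(ref_seq)
                    and seg[0] == ref_seq[ref_start]
                ):
                    seg.append(seg.pop(0))
                    ref_start += 1
                    read_start += 1
                while (
                    ref_start > anchor
                    and ref_start > 0
                    and seg[-1] == ref_seq[ref_start - 1]
                ):
                    seg.insert(0, seg.pop())
                    ref_start -= 1
                    read_start -= 1
        if R > 0:
            out.append(IndelEvent("ins", R, ref_start, read_start))
        if G > 0:
            out.append(IndelEvent("del", G, ref_start, read_start))
    return out


def call_edit(
    alignment: AlignmentResult,
    cut_site: int,
    cfg: QuantConfig = QuantConfig(),
    read: Optional[SimRead] = None,
    reference: Optional[str] = None,
) -> EditCall:
    """Classify one aligned read as edited or unmodified.

    An indel counts if it is not entirely inside a read-end exclusion margin;
    a counted event marks the read edited when it overlaps the window
    ``[cut - w, cut + w)`` -- deletions by their reference interval, insertions
    by their anchor boundary.  Substitutions are never events (they are
    ignored by contract).  Nearby indel ops are consolidated (see
    :func:`consolidated_events`), so a compound insertion+deletion outcome is
    recorded as separate ins/del events with their true segment sizes.
    """
    ref_len = alignment.ref_length()
    if not 0 <= cut_site <= ref_len:
        raise ValueError("cut site lies outside the reference")
    read_len = alignment.read_length()
    w = cfg.window_halfwidth
    win_lo, win_hi = cut_site - w, cut_site + w
    events: list[IndelEvent] = []
    overlap: list[bool] = []
    inserted: list[str] = []
    for ev in consolidated_events(
        alignment,
        cfg.event_merge_anchor,
        read_seq=read.sequence if read is not None else None,
        ref_seq=reference,
        anchor=cut_site,
        skip_balanced=cfg.ignore_substitutions,
    ):
        if ev.kind == "ins":
            in_margin = (
                ev.read_start + ev.size <= cfg.exclude_left
                or ev.read_start >= read_len - cfg.exclude_right
            )
            hits = win_lo <= ev.ref_start < win_hi
        else:
            in_margin = (
                ev.read_start < cfg.exclude_left
                or ev.read_start > read_len - cfg.exclude_right
            )
            hits = ev.ref_start < win_hi and ev.ref_start + ev.size > win_lo
        if in_margin:
            continue
        events.append(ev)
        overlap.append(bool(hits))
        if ev.kind == "ins":
            inserted.append(
                read.sequence[ev.read_start : ev.read_start + ev.size]
                if read is not None
                else ""
            )
        else:
            inserted.append("")
    status = "edited" if any(overlap) else "unmodified"
    signature = (
        _aligned_signature(alignment, read.sequence) if read is not None else None
    )
    return EditCall(
        read_id=read.read_id if read is not None else "read",
        allele_id=alignment.allele_id or "",
        status=status,
        events=events,
        window_overlap=overlap,
        inserted_sequences=inserted,
        aligned_sequence=signature,
    )


def quantify_reads(
    reads: Sequence[SimRead],
    refs: ReferenceSet,
    cfg: QuantConfig = QuantConfig(),
    phase1=PHASE1,
    phase2=PHASE2,
) -> RunCalls:
    """Full quantification pass: quality-trim -> assign -> per-read edit calls.

    Quality trimming acts as a mask compatible with end-to-end alignment:
    reads whose Q>=min_quality core is too short are discarded, and for the
    rest the low-quality end runs are folded into the end-exclusion margins
    (the full read is aligned, so unedited reads still satisfy the strict
    ungapped phase).  Discarded and UNASSIGNED reads are excluded from all
    per-allele denominators.
    """
    min_len = 2 * (cfg.exclude_left + cfg.exclude_right)
    kept: list[SimRead] = []
    margins: list[tuple[int, int]] = []
    n_discarded = 0
    for read in reads:
        bounds = _trim_bounds(read, cfg.min_quality, min_len)
        if bounds is None:
            n_discarded += 1
        else:
            kept.append(read)
            lo, hi = bounds
            margins.append((lo, len(read.sequence) - hi))
    assignments = homoeoassign.assign_reads(
        [(r.read_id, r.sequence, r.quality_array()) for r in kept],
        refs.sequences,
        phase1=phase1,
        phase2=phase2,
    )
    calls: dict[str, list[EditCall]] = {a: [] for a in refs.allele_ids}
    n_unassigned = 0
    for read, (t_lo, t_hi), asn in zip(kept, margins, assignments):
        if not asn.assigned:
            n_unassigned += 1
            continue
        read_cfg = replace(
            cfg,
            exclude_left=cfg.exclude_left + t_lo,
            exclude_right=cfg.exclude_right + t_hi,
        )
        calls[asn.allele_id].append(
            call_edit(
                asn.alignment,
                refs.cut_site,
                read_cfg,
                read=read,
                reference=refs.sequences[asn.allele_id],
            )
        )
    return RunCalls(calls, n_discarded, n_unassigned, assignments)


def _pct_edited(calls: Sequence[EditCall]) -> float:
    usable = [c for c in calls if c.status != "discarded"]
    if not usable:
        raise NoDataError("no usable reads for allele")
    edited = sum(c.status == "edited" for c in usable)
    return 100.0 * edited / len(usable)


def indel_frequency(
    treated: Sequence[EditCall],
    control: Sequence[EditCall],
    allele_id: str = "",
) -> EditingEstimate:
    """Percent edited in the treated sample minus the negative control.

    The raw (possibly negative) difference is reported; a negative value
    triggers a warning rather than clamping, preserving the arithmetic.
    """
    est = EditingEstimate(allele_id, _pct_edited(treated), _pct_edited(control))
    if est.indel_frequency < 0:
        warnings.warn(
            f"control-subtracted indel frequency is negative for "
            f"{allele_id or 'allele'} ({est.indel_frequency:.3f}%)",
            stacklevel=2,
        )
    return est


def allele_frequency_table(calls: Sequence[EditCall]) -> pd.DataFrame:
    """Aggregate identical aligned-read signatures into a frequency table.

    Returns a DataFrame with columns ``signature``, ``count``, ``pct`` sorted
    by count descending (signature as tie-break); percentages sum to 100 up
    to rounding.
    """
    sigs = [c.aligned_sequence for c in calls if c.aligned_sequence is not None]
    if not sigs:
        return pd.DataFrame(columns=["signature", "count", "pct"])
    counts = pd.Series(sigs).value_counts()
    df = counts.rename_axis("signature").reset_index(name="count")
    df = df.sort_values(
        ["count", "signature"], ascending=[False, True], ignore_index=True
    )
    df["pct"] = 100.0 * df["count"] / df["count"].sum()
    return df


def _find_origin(insert: str, vectors: Mapping[str, str]) -> Optional[tuple]:
    for name in sorted(vectors):
        vec = vectors[name]
        idx = vec.find(insert)
        if idx >= 0:
            return (name, idx, "+")
        idx = vec.find(revcomp(insert))
        if idx >= 0:
            return (name, idx, "-")
    return None


def detect_large_insertions(
    calls: Sequence[EditCall],
    vectors: Optional[Mapping[str, str]] = None,
    cfg: QuantConfig = QuantConfig(),
) -> list[LargeInsertion]:
    """Collect insertions >= ``cfg.min_large_insertion`` across calls.

    Identical insert sequences are grouped; each group is attributed to a
    vector by exact substring search (forward, then reverse complement) when
    vectors are supplied.  Frequencies are percent of *edited* reads.  Calls
    from the rescue assignment path participate like any other.
    """
    n_edited = sum(c.status == "edited" for c in calls)
    groups: dict[str, int] = {}
    for c in calls:
        seen = set()
        for ev, seq in zip(c.events, c.inserted_sequences):
            if ev.kind == "ins" and ev.size >= cfg.min_large_insertion and seq:
                if seq not in seen:  # one count per read per insert sequence
                    groups[seq] = groups.get(seq, 0) + 1
                    seen.add(seq)
    out = []
    for seq in sorted(groups, key=lambda s: (-groups[s], s)):
        count = groups[seq]
        origin = _find_origin(seq, vectors) if vectors else None
        pct = 100.0 * count / n_edited if n_edited else 0.0
        out.append(LargeInsertion(seq, len(seq), origin, count, pct))
    return out


def large_insertion_read_rate(
    calls: Sequence[EditCall], cfg: QuantConfig = QuantConfig()
) -> float:
    """Percent of edited reads carrying at least one >= min-size insertion."""
    edited = [c for c in calls if c.status == "edited"]
    if not edited:
        return 0.0
    carrying = sum(
        any(ev.kind == "ins" and ev.size >= cfg.min_large_insertion
            for ev in c.events)
        for c in edited
    )
    return 100.0 * carrying / len(edited)
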