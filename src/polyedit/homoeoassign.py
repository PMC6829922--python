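"""Homoeoallele read assignment via two-phase end-to-end affine-gap alignment.

Amplicon reads from a polyploid locus are near-identical across subgenomes and
differ only at a handful of diagnostic SNPs, so generic mappers cannot place
them reliably.  This module assigns each read to its source homoeoallele with
an explicit end-to-end (global) aligner run in two acceptance phases:

* phase 1 -- strict, ungapped: intended for unedited reads.  Gap penalties are
  effectively infinite and at most one full-quality mismatch fits under the
  total-penalty cap of 6.
* phase 2 -- indel-tolerant: quality-scaled mismatch penalty up to 76, read-gap
  (deletion) open/extend 24/1, reference-gap (insertion) open/extend 9/14,
  total cap 75.  The caps admit deletions of up to 51 bp (24 + 51*1 = 75) and
  insertions of up to 4 bp (9 + 4*14 = 65 <= 75 < 9 + 5*14).
* rescue -- phase-2 penalties with the insertion cap lifted: the total-penalty
  cap is applied to the non-insertion part of the penalty only, so reads
  carrying large (>=20 bp) vector-derived insertions remain assignable and
  quantifiable.

A read is assigned to the unique strictly best allele of the phase that first
accepts it; ties leave the read UNASSIGNED.  All penalties are integers and
all tie-breaks are deterministic, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "PhaseParams",
    "PHASE1",
    "PHASE2",
    "AlignmentResult",
    "Assignment",
    "IndelEvent",
    "UNASSIGNED",
    "align_affine",
    "assign_read",
    "assign_reads",
    "indel_events",
    "mismatch_penalties",
    "revcomp",
]

UNASSIGNED = "UNASSIGNED"

_INF = 1 << 28

# base encoding: A C G T N -> 0..4; code 4 (N) is penalty-free against anything
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC beyond ACGTN maps to N)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0 C=1 G=2 T=3, other=N=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PhaseParams:
    """Penalty scheme for one acceptance phase of the end-to-end aligner.

    Mismatch penalties interpolate with base quality q (clipped at 40):
    ``floor(mismatch_min + (mismatch_max - mismatch_min) * q / 40)``.
    Gap penalties follow the open+extend*length convention, i.e. a gap of
    length N costs ``open + N * extend``.  ``read_gap`` is a gap in the read
    (deletion from the reference), ``ref_gap`` a gap in the reference
    (insertion in the read).  ``max_penalty`` is the acceptance cap on the
    total alignment penalty; ``cap_excludes_insertions`` marks the rescue
    variant where insertion gap penalties are not counted against the cap.
    """

    mismatch_min: int
    mismatch_max: int
    read_gap_open: int
    read_gap_extend: int
    ref_gap_open: int
    ref_gap_extend: int
    max_penalty: int
    cap_excludes_insertions: bool = False


#: Strict ungapped phase (unedited reads); gaps are priced out entirely.
PHASE1 = PhaseParams(1, 6, 999, 999, 999, 999, 6)
#: Indel-tolerant phase (deletions <=51 bp, insertions <=4 bp under the cap).
PHASE2 = PhaseParams(1, 76, 24, 1, 9, 14, 75)
#: Rescue phase: phase-2 penalties, insertion penalties exempt from the cap.
RESCUE = PhaseParams(1, 76, 24, 1, 9, 14, 75, cap_excludes_insertions=True)


def mismatch_penalties(qualities: np.ndarray, params: PhaseParams) -> np.ndarray:
    """Per-base mismatch penalty vector from Phred qualities.

    Parameters
    ----------
    qualities
        Integer Phred scores, one per read base.
    params
        Phase whose (min, max) mismatch range to interpolate.
    """
    q = np.minimum(np.asarray(qualities, dtype=np.int64), 40)
    span = params.mismatch_max - params.mismatch_min
    return params.mismatch_min + (span * q) // 40


@dataclass
class IndelEvent:
    """One insertion or deletion in an alignment, in reference coordinates.

    ``ref_start`` is the 0-based reference position of the first deleted base
    (deletions) or the reference boundary the insertion sits at (insertions).
    ``read_start`` is the 0-based read position of the first inserted base
    (insertions) or of the read boundary at the deletion (deletions).
    """

    kind: str  # "ins" | "del"
    size: int
    ref_start: int
    read_start: int


@dataclass
class AlignmentResult:
    """End-to-end alignment of one read against one reference.

    ``operations`` is an ordered run-length list of ``(op, length)`` with op in
    {match, mismatch, ins, del}; match/mismatch/ins consume the read,
    match/mismatch/del consume the reference.  ``score`` is the total integer
    penalty (0 = perfect).
    """

    allele_id: Optional[str]
    score: int
    operations: tuple
    mismatch_count: int
    max_ins: int
    max_del: int

    @property
    def insertion_penalty(self) -> int:
        """Total penalty contributed by insertion gaps under phase-2 pricing."""
        total = 0
        for op, length in self.operations:
            if op == "ins":
                total += PHASE2.ref_gap_open + PHASE2.ref_gap_extend * length
        return total

    def read_length(self) -> int:
        return sum(n for op, n in self.operations if op != "del")

    def ref_length(self) -> int:
        return sum(n for op, n in self.operations if op != "ins")


@dataclass
class Assignment:
    """Outcome of assigning one read to a homoeoallele."""

    read_id: str
    allele_id: str  # allele name or UNASSIGNED
    phase: str  # "1" | "2" | "rescue" | "none"
    best_penalty: Optional[int]
    second_penalty: Optional[int]
    alignment: Optional[AlignmentResult] = field(default=None, repr=False)

    @property
    def assigned(self) -> bool:
        return self.allele_id != UNASSIGNED


@njit(cache=True)
def _affine_dp(read, ref, mp, rdg_o, rdg_e, rfg_o, rfg_e):  # pragma: no cover
    n = read.shape[0]
    m = ref.shape[0]
    INF = 1 << 28
    M = np.full((n + 1, m + 1), INF, np.int64)
    I = np.full((n + 1, m + 1), INF, np.int64)
    D = np.full((n + 1, m + 1), INF, np.int64)
    M[0, 0] = 0
    for i in range(1, n + 1):
        I[i, 0] = rfg_o + rfg_e * i
    for j in range(1, m + 1):
        D[0, j] = rdg_o + rdg_e * j
    for i in range(1, n + 1):
        ri = read[i - 1]
        pi = mp[i - 1]
        for j in range(1, m + 1):
            rj = ref[j - 1]
            sub = 0 if (ri == rj or ri == 4 or rj == 4) else pi
            best = M[i - 1, j - 1]
            if D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            if I[i - 1, j - 1] < best:
                best = I[i - 1, j - 1]
            if best < INF:
                M[i, j] = best + sub
            a = M[i - 1, j] + rfg_o + rfg_e
            b = I[i - 1, j] + rfg_e
            c = D[i - 1, j] + rfg_o + rfg_e
            v = a
            if b < v:
                v = b
            if c < v:
                v = c
            I[i, j] = v
            a = M[i, j - 1] + rdg_o + rdg_e
            b = D[i, j - 1] + rdg_e
            c = I[i, j - 1] + rdg_o + rdg_e
            v = a
            if b < v:
                v = b
            if c < v:
                v = c
            D[i, j] = v
    return M, I, D


def _traceback(M, I, D, read, ref, mp, params: PhaseParams):
    """Deterministic traceback: prefer match/mismatch, then deletion, then
    insertion on ties (and gap extension over opening), which places gaps
    leftmost for a fixed optimum."""
    i, j = read.shape[0], ref.shape[0]
    finals = (M[i, j], D[i, j], I[i, j])
    score = min(finals)
    state = "MDI"[finals.index(score)]
    ops = []  # reversed per-step ops
    rdg_o, rdg_e = params.read_gap_open, params.read_gap_extend
    rfg_o, rfg_e = params.ref_gap_open, params.ref_gap_extend
    while i > 0 or j > 0:
        if state == "M":
            ri, rj = read[i - 1], ref[j - 1]
            matched = ri == rj or ri == 4 or rj == 4
            sub = 0 if matched else int(mp[i - 1])
            prev = M[i, j] - sub
            ops.append("match" if matched else "mismatch")
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] == prev:
                state = "M"
            elif D[i, j] == prev:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            ops.append("del")
            here = D[i, j]
            j -= 1
            if D[i, j] + rdg_e == here:
                state = "D"
            elif M[i, j] + rdg_o + rdg_e == here:
                state = "M"
            else:
                state = "I"
        else:  # I
            ops.append("ins")
            here = I[i, j]
            i -= 1
            if I[i, j] + rfg_e == here:
                state = "I"
            elif M[i, j] + rfg_o + rfg_e == here:
                state = "M"
            else:
                state = "D"
    ops.reverse()
    runs = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1][1] += 1
        else:
            runs.append([op, 1])
    return int(score), tuple((op, n) for op, n in runs)


def align_affine(
    read: str,
    reference: str,
    params: PhaseParams = PHASE2,
    qualities: Optional[np.ndarray] = None,
    allele_id: Optional[str] = None,
) -> AlignmentResult:
    """Optimal end-to-end affine-gap alignment of ``read`` against ``reference``.

    Penalties are minimised (0 = perfect).  When ``qualities`` is given the
    mismatch penalty is quality-scaled per base; otherwise every mismatch costs
    ``params.mismatch_max``.  Traceback is deterministic: on ties,
    mismatch < deletion < insertion, with gaps placed leftmost.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    r = encode(read)
    g = encode(reference)
    if qualities is None:
        mp = np.full(len(read), params.mismatch_max, dtype=np.int64)
    else:
        mp = mismatch_penalties(qualities, params)
        if mp.shape[0] != len(read):
            raise ValueError("quality vector length does not match read length")
    M, I, D = _affine_dp(
        r, g, mp,
        params.read_gap_open, params.read_gap_extend,
        params.ref_gap_open, params.ref_gap_extend,
    )
    score, ops = _traceback(M, I, D, r, g, mp, params)
    n_mm = sum(n for op, n in ops if op == "mismatch")
    max_ins = max((n for op, n in ops if op == "ins"), default=0)
    max_del = max((n for op, n in ops if op == "del"), default=0)
    return AlignmentResult(allele_id, score, ops, n_mm, max_ins, max_del)


def indel_events(alignment: AlignmentResult) -> list[IndelEvent]:
    """Extract insertion/deletion events with reference and read coordinates."""
    events = []
    ref_pos = 0
    read_pos = 0
    for op, length in alignment.operations:
        if op in ("match", "mismatch"):
            ref_pos += length
            read_pos += length
        elif op == "del":
            events.append(IndelEvent("del", length, ref_pos, read_pos))
            ref_pos += length
        elif op == "ins":
            events.append(IndelEvent("ins", length, ref_pos, read_pos))
            read_pos += length
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown alignment op {op!r}")
    return events


def _mismatch_ops_from_positions(length: int, mm_pos: np.ndarray) -> tuple:
    """Run-length ops for a gapless alignment given mismatch positions."""
    if mm_pos.size == 0:
        return (("match", length),)
    runs = []
    prev = 0
    for p in mm_pos:
        p = int(p)
        if p > prev:
            runs.append(("match", p - prev))
        runs.append(("mismatch", 1))
        prev = p + 1
    if prev < length:
        runs.append(("match", length - prev))
    # merge adjacent mismatch runs
    merged = []
    for op, n in runs:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return tuple(merged)


def _pick_best(penalties: dict[str, int]) -> tuple[Optional[str], int, Optional[int]]:
    """Unique strict minimum over accepted alleles; ties return (None, best, best)."""
    ranked = sorted(penalties.items(), key=lambda kv: (kv[1], kv[0]))
    best_allele, best = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else None
    if second is not None and second == best:
        return None, best, second
    return best_allele, best, second


def assign_read(
    read_seq: str,
    read_qual: Optional[np.ndarray],
    references: Mapping[str, str],
    read_id: str = "read",
    phase1: PhaseParams = PHASE1,
    phase2: PhaseParams = PHASE2,
) -> Assignment:
    """Assign a single read; see :func:`assign_reads` for the batch interface."""
    return assign_reads(
        [(read_id, read_seq, read_qual)], references, phase1=phase1, phase2=phase2
    )[0]


def _phase1_penalty(read_codes, qual, ref_codes, params):
    mism = (read_codes != ref_codes) & (read_codes != 4) & (ref_codes != 4)
    if qual is None:
        pen = np.full(read_codes.shape[0], params.mismatch_max, dtype=np.int64)
    else:
        pen = mismatch_penalties(qual, params)
    return int(pen[mism].sum()), np.flatnonzero(mism)


def assign_reads(
    reads: Sequence[tuple],
    references: Mapping[str, str],
    phase1: PhaseParams = PHASE1,
    phase2: PhaseParams = PHASE2,
) -> list[Assignment]:
    """Assign reads to homoeoalleles through phase 1, phase 2, then rescue.

    Parameters
    ----------
    reads
        Sequence of ``(read_id, sequence, qualities)`` where qualities is an
        integer array or None (None = treat every base as full quality).
    references
        Mapping allele id -> reference amplicon sequence (>=2 entries).

    Returns
    -------
    list of :class:`Assignment`, one per read, in input order.  Assigned
    entries carry the winning :class:`AlignmentResult`.  Phase-2 alignments
    against every allele are computed once and shared with the rescue path
    (rescue applies the total-penalty cap to non-insertion penalties only).
    """
    if len(references) < 2:
        raise ValueError("need at least two reference alleles")
    allele_ids = list(references)
    ref_codes = {a: encode(references[a]) for a in allele_ids}

    out: list[Assignment] = []
    for read_id, seq, qual in reads:
        codes = encode(seq)
        if qual is not None:
            qual = np.asarray(qual, dtype=np.int64)
        # --- phase 1: strict ungapped, only meaningful at equal length
        p1: dict[str, int] = {}
        p1_mm: dict[str, np.ndarray] = {}
        for a in allele_ids:
            if ref_codes[a].shape[0] != codes.shape[0]:
                continue
            pen, mm = _phase1_penalty(codes, qual, ref_codes[a], phase1)
            if pen <= phase1.max_penalty:
                p1[a] = pen
                p1_mm[a] = mm
        if p1:
            best_a, best, second = _pick_best(p1)
            if best_a is None:
                out.append(Assignment(read_id, UNASSIGNED, "1", best, second))
            else:
                ops = _mismatch_ops_from_positions(len(seq), p1_mm[best_a])
                aln = AlignmentResult(
                    best_a, best, ops,
                    int(p1_mm[best_a].size), 0, 0,
                )
                out.append(Assignment(read_id, best_a, "1", best, second, aln))
            continue
        # --- phase 2 (DP once per allele, shared with rescue)
        alignments = {
            a: align_affine(seq, references[a], phase2, qual, allele_id=a)
            for a in allele_ids
        }
        p2 = {a: r.score for a, r in alignments.items() if r.score <= phase2.max_penalty}
        if p2:
            best_a, best, second = _pick_best(p2)
            if best_a is None:
                out.append(Assignment(read_id, UNASSIGNED, "2", best, second))
            else:
                out.append(
                    Assignment(read_id, best_a, "2", best, second, alignments[best_a])
                )
            continue
        # --- rescue: cap applies to the non-insertion penalty only
        resc = {
            a: r.score - r.insertion_penalty
            for a, r in alignments.items()
            if r.score - r.insertion_penalty <= phase2.max_penalty
        }
        if resc:
            best_a, best, second = _pick_best(resc)
            if best_a is None:
                out.append(Assignment(read_id, UNASSIGNED, "rescue", best, second))
            else:
                out.append(
                    Assignment(
                        read_id, best_a, "rescue", best, second, alignments[best_a]
                    )
                )
            continue
        out.append(Assignment(read_id, UNASSIGNED, "none", None, None))
    return out
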