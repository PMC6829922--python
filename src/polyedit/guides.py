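"""Guide (gRNA) target-site discovery and predicted specificity across homoeoalleles.

Candidate target sites are 20-22 nt protospacers lying immediately 5' of an
NGG PAM, on either strand.  Against each homoeoallele a candidate gets a
:class:`MatchProfile` (mismatch positions in PAM-proximal numbering, where
position 1 is the base adjacent to the PAM, plus PAM presence), and the
profile maps to an ordinal predicted-specificity class:

* no PAM at the locus -> activity abolished (``non_target``);
* >=2 mismatches with at least one in the PAM-proximal seed -> ``negligible``;
* a single seed mismatch -> ``reduced`` (activity cut but not abolished);
* mismatches only outside the seed -> ``near_full``;
* perfect match -> ``full``.

The seed defaults to the PAM-proximal 12 nt.  The classes are ordinal labels
for ranking candidate sites, not quantitative activity predictions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from . import homoeoassign
from .homoeoassign import revcomp

__all__ = [
    "GuideTarget",
    "MatchProfile",
    "SpecificityClass",
    "UnlocatableTargetError",
    "find_target_sites",
    "annotate_match",
    "predict_specificity",
    "u6_prefix",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class UnlocatableTargetError(ValueError):
    """The guide's target locus could not be located on the given allele."""


class SpecificityClass(enum.IntEnum):
    """Ordinal predicted activity at a locus; higher value = higher activity."""

    NON_TARGET = 0
    NEGLIGIBLE = 1
    REDUCED = 2
    NEAR_FULL = 3
    FULL = 4


@dataclass(frozen=True)
class GuideTarget:
    """A protospacer + PAM on a reference sequence.

    ``cut_site`` is the 0-based boundary of the blunt cut in the coordinates
    of the scanned (plus-strand) sequence: the cut falls between positions
    ``cut_site - 1`` and ``cut_site``, i.e. 3 bp 5' of the PAM (between guide
    positions 3 and 4 counted from the PAM).
    """

    protospacer: str
    pam: str
    strand: str  # "+" or "-"
    reference_id: Optional[str]
    cut_site: int
    u6_prefix_added: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class MatchProfile:
    """How a guide matches one homoeoallele.

    ``mismatch_positions`` uses PAM-proximal numbering: position 1 is the
    protospacer base adjacent to the PAM, position 20 (for a 20-mer) the
    PAM-distal end.
    """

    allele_id: str
    mismatch_positions: frozenset
    pam_present: bool


def _pam_matches(site: str, pam: str) -> bool:
    return len(site) == len(pam) and all(
        b in _IUPAC.get(p, "") for b, p in zip(site, pam)
    )


def find_target_sites(
    sequence: str,
    length_range: tuple[int, int] = (20, 22),
    pam: str = "NGG",
    reference_id: Optional[str] = None,
) -> list[GuideTarget]:
    """Scan both strands for every protospacer immediately 5' of a PAM.

    Returns one :class:`GuideTarget` per (position, strand, length), sorted by
    (cut_site, strand, protospacer length).  A sequence too short to hold the
    minimum protospacer plus PAM yields an empty list.
    """
    sequence = sequence.upper()
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid protospacer length range")
    hits: list[GuideTarget] = []
    n = len(sequence)
    plen = len(pam)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for p in range(n - plen + 1):
            if not _pam_matches(seq[p : p + plen], pam):
                continue
            for length in range(lo, hi + 1):
                if p - length < 0:
                    continue
                cut = p - 3
                if strand == "-":
                    cut = n - cut  # map boundary back to plus coordinates
                hits.append(
                    GuideTarget(
                        protospacer=seq[p - length : p],
                        pam=seq[p : p + plen],
                        strand=strand,
                        reference_id=reference_id,
                        cut_site=cut,
                    )
                )
    hits.sort(key=lambda g: (g.cut_site, g.strand, len(g.protospacer)))
    return hits


def _locate_locus(
    guide: GuideTarget,
    allele_sequence: str,
    source_sequence: str,
    anchor_length: int,
) -> int:
    """Return the protospacer start on ``allele_sequence`` (plus-frame of the
    guide), located via exact flanking anchors from the source sequence, with
    an alignment fallback when both anchors fail."""
    pam_start = guide.cut_site + 3
    start = pam_start - len(guide.protospacer)
    end = pam_start + len(guide.pam)
    left = source_sequence[max(0, start - anchor_length) : start]
    right = source_sequence[end : end + anchor_length]
    if left:
        idx = allele_sequence.find(left)
        if idx >= 0 and allele_sequence.find(left, idx + 1) < 0:
            return idx + len(left)
    if right:
        idx = allele_sequence.find(right)
        if idx >= 0 and allele_sequence.find(right, idx + 1) < 0:
            return idx - (end - start)
    # fallback: end-to-end alignment of source against allele, map coordinates
    aln = homoeoassign.align_affine(
        source_sequence, allele_sequence, homoeoassign.PHASE2
    )
    src_pos = 0
    all_pos = 0
    for op, length in aln.operations:
        if op in ("match", "mismatch"):
            if src_pos <= start < src_pos + length:
                return all_pos + (start - src_pos)
            src_pos += length
            all_pos += length
        elif op == "ins":  # consumes source
            if src_pos <= start < src_pos + length:
                break
            src_pos += length
        else:  # del consumes allele
            all_pos += length
    raise UnlocatableTargetError(
        f"target locus for guide at cut {guide.cut_site} not found on allele"
    )


def annotate_match(
    guide: GuideTarget,
    allele_sequence: str,
    allele_id: str = "allele",
    source_sequence: Optional[str] = None,
    anchor_length: int = 15,
) -> MatchProfile:
    """Profile a guide against one homoeoallele sequence.

    The target locus is located by exact flanking anchors (``anchor_length``
    nt each side, taken from ``source_sequence``); if both anchors fail, an
    end-to-end alignment of the source against the allele maps the locus.
    When ``source_sequence`` is omitted the allele is assumed to share the
    guide's coordinate frame.  Minus-strand guides are handled by reverse
    complementing both sequences into the guide's frame.
    """
    allele_sequence = allele_sequence.upper()
    if guide.strand == "-":
        n = len(allele_sequence)
        flipped = replace(
            guide,
            strand="+",
            cut_site=len(source_sequence) - guide.cut_site
            if source_sequence is not None
            else n - guide.cut_site,
        )
        return annotate_match(
            flipped,
            revcomp(allele_sequence),
            allele_id,
            revcomp(source_sequence) if source_sequence is not None else None,
            anchor_length,
        )
    if source_sequence is None:
        start = guide.cut_site + 3 - len(guide.protospacer)
        if start < 0 or guide.cut_site + 3 + len(guide.pam) > len(allele_sequence):
            raise UnlocatableTargetError("guide coordinates fall outside the allele")
    else:
        start = _locate_locus(guide, allele_sequence, source_sequence, anchor_length)
    L = len(guide.protospacer)
    locus = allele_sequence[start : start + L]
    pam_site = allele_sequence[start + L : start + L + len(guide.pam)]
    if len(locus) < L or len(pam_site) < len(guide.pam):
        raise UnlocatableTargetError("located target locus is truncated")
    mismatches = frozenset(
        L - i for i in range(L) if locus[i] != guide.protospacer[i]
    )
    return MatchProfile(allele_id, mismatches, _pam_matches(pam_site, "NGG"))


def predict_specificity(
    profile: MatchProfile, seed_length: int = 12, core_length: int = 5
) -> SpecificityClass:
    """Classify predicted activity of a guide at the profiled locus.

    ``seed_length`` is the PAM-proximal window in which mismatches are most
    disruptive (default 12 nt).  ``core_length`` (the PAM-proximal ~5 nt) is
    accepted for annotation/parameter symmetry; the default rules do not
    distinguish core from seed.
    """
    if not profile.pam_present:
        return SpecificityClass.NON_TARGET
    mm = profile.mismatch_positions
    if not mm:
        return SpecificityClass.FULL
    in_seed = any(p <= seed_length for p in mm)
    if not in_seed:
        return SpecificityClass.NEAR_FULL
    if len(mm) == 1:
        return SpecificityClass.REDUCED
    return SpecificityClass.NEGLIGIBLE


def u6_prefix(guide: GuideTarget) -> GuideTarget:
    """Prepend a 5' G when absent (for efficient U6/Pol III transcription).

    Returns the guide unchanged if its 5' base is already G; idempotent.
    """
    if not guide.protospacer:
        raise ValueError("empty protospacer")
    if guide.protospacer[0] == "G":
        return guide
    return replace(
        guide, protospacer="G" + guide.protospacer, u6_prefix_added=True
    )
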