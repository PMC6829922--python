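"""Synthetic homoeoallelic amplicons, edited reads and Sanger-style traces.

Every downstream stage of the pipeline (assignment, quantification, trace
decomposition, summaries) is validated against data from this generator, which
emulates a polyploid amplicon-sequencing experiment with fully known ground
truth:

* k homoeoallelic reference amplicons (default three, ~270 bp) identical up to
  a small set of diagnostic SNPs near a Cas9 cut site, optional guide-site
  mismatch injections and PAM knockouts;
* amplicon reads with configurable per-allele edit fractions, an indel-size
  spectrum, optional large vector-derived insertions, substitution sequencing
  errors and Phred qualities (FASTQ plus a truth table);
* paired control/treated 4-channel chromatogram traces in which the treated
  trace is a fraction-weighted mixture of shifted wild-type traces downstream
  of the cut.

Coordinates are 0-based, half-open, plus strand throughout.  A fixed seed
yields byte-identical FASTQ/TSV output.

Conventions (stated so tests can be exact): each edited read carries one
event; insertions are placed at the cut boundary; deletions are centred on the
cut with left bias on ties (a deletion of size d removes
``[cut - ceil(d/2), cut - ceil(d/2) + d)``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import guides
from .guides import GuideTarget, MatchProfile
from .homoeoassign import revcomp

__all__ = [
    "SimConfig",
    "TraceSimConfig",
    "ReferenceSet",
    "SimRead",
    "TruthRecord",
    "ConfigurationConflictError",
    "make_reference_set",
    "make_vector_set",
    "simulate_reads",
    "simulate_trace_pair",
    "write_fasta",
    "write_fastq",
    "write_truth_table",
    "write_trace_tsv",
    "read_trace_tsv",
]

BASES = "ACGT"
CHANNELS = "ACGT"  # fixed trace channel order
_DEFAULT_NAMES = ("7AS", "4AL", "7DS", "HA4")


class ConfigurationConflictError(ValueError):
    """Mutually contradictory simulation settings (e.g. an injection that
    clashes with a diagnostic-SNP base assignment at the same position)."""


@dataclass
class SimConfig:
    """Study conditions for the amplicon-read simulation.

    Defaults mirror the emulated experiment: three ~270 bp homoeoallelic
    amplicons carrying three diagnostic SNPs near the cut site, an NGG guide
    site on the plus strand, substitution-only sequencing errors at 0.5%/base
    and constant Q37 base quality (error positions get low quality, U{2..20},
    so Q30 end-trimming is exercisable).
    """

    amplicon_length: int = 270
    n_alleles: int = 3
    snp_positions: Sequence[int] = (110, 125, 165)
    #: pos -> {allele id -> base}; None = assign distinct bases automatically
    snp_alleles: Optional[Mapping[int, Mapping[str, str]]] = None
    guide_anchor: int = 150  # 0-based PAM start on the plus strand
    guide_length: int = 20
    #: (allele id, guide position 1..len PAM-proximal, substituted base)
    per_allele_mismatch_injections: Sequence[tuple] = ()
    pam_knockouts: frozenset = frozenset()
    allele_names: Optional[Sequence[str]] = None
    read_length: Optional[int] = None  # None = full edited molecule
    n_reads_per_allele: int = 1000
    edit_fraction_per_allele: Union[float, Mapping[str, float]] = 0.1
    indel_spectrum: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, -1: 0.3, -2: 0.2}
    )
    large_insertion_fraction_of_edited: float = 0.0
    large_insertion_size_range: tuple[int, int] = (20, 60)
    vector_sequences: Optional[Mapping[str, str]] = None
    substitution_error_rate: float = 0.005
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self):
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")
        names = self.allele_names
        if names is None:
            if self.n_alleles <= len(_DEFAULT_NAMES):
                names = _DEFAULT_NAMES[: self.n_alleles]
            else:
                names = tuple(f"HA{i + 1}" for i in range(self.n_alleles))
        if len(names) != self.n_alleles or len(set(names)) != self.n_alleles:
            raise ValueError("allele_names must be n_alleles unique names")
        self.allele_names = tuple(names)
        pos = tuple(self.snp_positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("snp_positions must be strictly increasing")
        if pos and (pos[0] < 0 or pos[-1] >= self.amplicon_length):
            raise ValueError("snp_positions must lie within the amplicon")
        self.snp_positions = pos
        total = float(sum(self.indel_spectrum.values()))
        if self.indel_spectrum and abs(total - 1.0) > 1e-9:
            raise ValueError("indel_spectrum probabilities must sum to 1")
        if any(s == 0 for s in self.indel_spectrum):
            raise ValueError("indel_spectrum sizes are signed and non-zero")
        for frac in (
            self.large_insertion_fraction_of_edited,
            self.substitution_error_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        edits = self.edit_fraction_per_allele
        values = edits.values() if isinstance(edits, Mapping) else [edits]
        if any(not 0.0 <= float(v) <= 1.0 for v in values):
            raise ValueError("edit fractions must lie in [0, 1]")
        start = self.guide_anchor - self.guide_length
        if start < 0 or self.guide_anchor + 3 > self.amplicon_length:
            raise ValueError("guide site plus PAM must fit inside the amplicon")
        self.pam_knockouts = frozenset(self.pam_knockouts)

    def edit_fraction(self, allele_id: str) -> float:
        e = self.edit_fraction_per_allele
        return float(e[allele_id]) if isinstance(e, Mapping) else float(e)


@dataclass
class TraceSimConfig:
    """Conditions for a paired control/treated chromatogram simulation.

    ``allele_fractions`` maps signed indel size (0 = wild type) to molecular
    fraction; ``cut_index`` is the 0-based position of the cut inside the
    simulated window.  Intensities are arbitrary units; the default noise
    (5% of peak height) reflects a clean capillary trace.
    """

    allele_fractions: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0}
    )
    noise_sd: float = 50.0
    peak_height: float = 1000.0
    cut_index: int = 30
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.allele_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("allele fractions must sum to 1")
        if any(f < 0 for f in self.allele_fractions.values()):
            raise ValueError("allele fractions must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.peak_height <= 0:
            raise ValueError("peak_height must be positive")


@dataclass
class ReferenceSet:
    """Homoeoallelic amplicon references with guide-site ground truth."""

    sequences: dict  # allele id -> sequence, in allele order
    snp_positions: tuple
    guide: GuideTarget
    profiles: dict  # allele id -> MatchProfile

    @property
    def allele_ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def cut_site(self) -> int:
        return self.guide.cut_site


@dataclass
class SimRead:
    """One simulated amplicon read (Phred+33 quality string)."""

    read_id: str
    sequence: str
    quality: str

    def quality_array(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode("ascii"), np.uint8).astype(
            np.int64
        ) - 33


@dataclass
class TruthRecord:
    """Ground truth for one simulated read.

    ``events`` is a tuple of ``(kind, size, ref_start)`` on the source
    reference; ``insert_origin`` is ``(vector name, offset, strand)`` when the
    inserted sequence was copied from a vector.
    """

    read_id: str
    source_allele: str
    edited: bool
    events: tuple
    insert_origin: Optional[tuple] = None


def make_vector_set(seed: int = 0, sizes: Mapping[str, int] | None = None) -> dict:
    """Synthetic stand-ins for transformation vectors (random sequences).

    These are *synthetic* plasmid-like sequences used purely as sources for
    exact-substring insertion attribution; they share nothing with any real
    vector beyond their role.
    """
    if sizes is None:
        sizes = {"pCas9-like-synthetic": 3000, "pU6-gRNA-like-synthetic": 2000}
    rng = np.random.default_rng([seed, 0x5EC])
    return {
        name: "".join(rng.choice(list(BASES), size=n))
        for name, n in sizes.items()
    }


def _auto_snp_base(backbone_base: str, allele_index: int) -> str:
    k = BASES.index(backbone_base)
    return BASES[(k + allele_index) % 4]


def make_reference_set(cfg: SimConfig) -> ReferenceSet:
    """Build the homoeoallelic reference amplicons and guide-site truth.

    All alleles share a random backbone (seeded from ``cfg.seed``) and differ
    only at diagnostic SNP positions, injected guide-site mismatches, and
    PAM-knockout positions (second G of the NGG replaced).  The guide is read
    from the first allele (post-SNP, pre-injection), with its PAM forced to
    NGG on the backbone.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    backbone = list(rng.choice(list(BASES), size=cfg.amplicon_length))
    backbone[cfg.guide_anchor + 1] = "G"
    backbone[cfg.guide_anchor + 2] = "G"
    names = list(cfg.allele_names)
    if names[0] in cfg.pam_knockouts:
        raise ConfigurationConflictError(
            "the guide-source allele cannot be a PAM knockout"
        )
    seqs = {a: list(backbone) for a in names}
    for pos in cfg.snp_positions:
        for i, a in enumerate(names):
            if cfg.snp_alleles is not None and pos in cfg.snp_alleles:
                base = cfg.snp_alleles[pos][a]
            else:
                base = _auto_snp_base(backbone[pos], i)
            seqs[a][pos] = base
    start = cfg.guide_anchor - cfg.guide_length
    protospacer = "".join(seqs[names[0]][start : cfg.guide_anchor])
    guide = GuideTarget(
        protospacer=protospacer,
        pam="".join(seqs[names[0]][cfg.guide_anchor : cfg.guide_anchor + 3]),
        strand="+",
        reference_id=names[0],
        cut_site=cfg.guide_anchor - 3,
    )
    for allele, gpos, base in cfg.per_allele_mismatch_injections:
        if not 1 <= gpos <= cfg.guide_length:
            raise ValueError("injection guide position out of range")
        if base not in BASES:
            raise ValueError(f"invalid injection base {base!r}")
        coord = cfg.guide_anchor - gpos
        if base == protospacer[cfg.guide_length - gpos]:
            raise ConfigurationConflictError(
                f"injection at guide position {gpos} on {allele} equals the "
                "guide base and would create no mismatch"
            )
        if coord in cfg.snp_positions and seqs[allele][coord] != base:
            raise ConfigurationConflictError(
                f"injection at guide position {gpos} on {allele} contradicts "
                f"the SNP base assignment at amplicon position {coord}"
            )
        seqs[allele][coord] = base
    for allele in cfg.pam_knockouts:
        pos = cfg.guide_anchor + 2  # second G of NGG
        seqs[allele][pos] = "T" if seqs[allele][pos] != "T" else "A"
    sequences = {a: "".join(seqs[a]) for a in names}
    profiles = {
        a: guides.annotate_match(
            guide, sequences[a], allele_id=a, source_sequence=None
        )
        for a in names
    }
    return ReferenceSet(sequences, cfg.snp_positions, guide, profiles)


def _apply_errors(seq: list, qual: np.ndarray, cfg: SimConfig, rng) -> None:
    n_err = rng.binomial(len(seq), cfg.substitution_error_rate)
    if n_err == 0:
        return
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in sorted(int(x) for x in positions):
        alternatives = [b for b in BASES if b != seq[p]]
        seq[p] = alternatives[rng.integers(0, 3)]
        qual[p] = rng.integers(2, 21)


def simulate_reads(
    refs: ReferenceSet, cfg: SimConfig
) -> tuple[list[SimRead], list[TruthRecord]]:
    """Simulate edited amplicon reads with a truth row per read.

    Each allele contributes ``cfg.n_reads_per_allele`` reads.  A read is
    edited with its allele's edit fraction; an edited read carries either one
    indel drawn from ``cfg.indel_spectrum`` (insertions at the cut boundary,
    deletions centred on the cut, left-biased) or -- with probability
    ``cfg.large_insertion_fraction_of_edited`` -- an exact substring of a
    supplied vector inserted at the cut.  Substitution errors are then applied
    at ``cfg.substitution_error_rate`` per base.  Identical configs (including
    seed) produce identical reads, in identical order.
    """
    if (
        cfg.large_insertion_fraction_of_edited > 0
        and not cfg.vector_sequences
    ):
        raise ValueError(
            "large_insertion_fraction_of_edited > 0 requires vector_sequences"
        )
    rng = np.random.default_rng([cfg.seed, 1])
    cut = refs.cut_site
    sizes = sorted(cfg.indel_spectrum)
    probs = np.array([cfg.indel_spectrum[s] for s in sizes], dtype=float)
    if probs.size:
        probs = probs / probs.sum()
    vec_names = sorted(cfg.vector_sequences) if cfg.vector_sequences else []
    reads: list[SimRead] = []
    truth: list[TruthRecord] = []
    for allele in refs.allele_ids:
        ref_seq = refs.sequences[allele]
        p_edit = cfg.edit_fraction(allele)
        for i in range(cfg.n_reads_per_allele):
            read_id = f"{allele}:{i:06d}"
            edited = bool(rng.random() < p_edit)
            events: tuple = ()
            origin = None
            seq = list(ref_seq)
            if edited:
                large = (
                    vec_names
                    and rng.random() < cfg.large_insertion_fraction_of_edited
                )
                if large:
                    vname = vec_names[rng.integers(0, len(vec_names))]
                    vec = cfg.vector_sequences[vname]
                    lo, hi = cfg.large_insertion_size_range
                    size = int(rng.integers(lo, hi + 1))
                    offset = int(rng.integers(0, len(vec) - size + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    ins = vec[offset : offset + size]
                    if strand == "-":
                        ins = revcomp(ins)
                    seq[cut:cut] = list(ins)
                    events = (("ins", size, cut),)
                    origin = (vname, offset, strand)
                else:
                    if not sizes:
                        raise ValueError("edit requested but indel_spectrum empty")
                    s = int(sizes[rng.choice(len(sizes), p=probs)])
                    if s > 0:
                        ins = "".join(rng.choice(list(BASES), size=s))
                        seq[cut:cut] = list(ins)
                        events = (("ins", s, cut),)
                    else:
                        d = -s
                        start = cut - (d + 1) // 2
                        if start < 0 or start + d > len(seq):
                            raise ValueError(
                                "deletion extends beyond the amplicon; shrink "
                                "the indel spectrum or move the guide"
                            )
                        del seq[start : start + d]
                        events = (("del", d, start),)
            if cfg.read_length is not None:
                seq = seq[: cfg.read_length]
            qual = np.full(len(seq), cfg.base_quality, dtype=np.int64)
            _apply_errors(seq, qual, cfg, rng)
            reads.append(
                SimRead(
                    read_id,
                    "".join(seq),
                    "".join(chr(int(q) + 33) for q in qual),
                )
            )
            truth.append(TruthRecord(read_id, allele, edited, events, origin))
    return reads, truth


def simulate_trace_pair(
    ref_window: str, cfg: TraceSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a (control, treated) pair of 4-channel chromatogram traces.

    The control is the pure wild-type trace of ``ref_window`` (peak height in
    the channel of each base, channel order A,C,G,T).  The treated trace
    equals the control upstream of ``cfg.cut_index`` and, downstream, the
    fraction-weighted sum of the control translated by each signed indel size
    (position i of the +s allele shows the control at i - s).  Gaussian noise
    of ``cfg.noise_sd`` is added to the treated trace and intensities are
    clamped at zero.
    """
    ref_window = ref_window.upper()
    L = len(ref_window)
    control = np.zeros((L, 4), dtype=float)
    for i, b in enumerate(ref_window):
        if b in CHANNELS:
            control[i, CHANNELS.index(b)] = cfg.peak_height
    treated = np.zeros_like(control)
    cut = cfg.cut_index
    treated[:cut] = control[:cut]
    for s, frac in sorted(cfg.allele_fractions.items()):
        for i in range(cut, L):
            j = i - s
            if 0 <= j < L:
                treated[i] += frac * control[j]
    if cfg.noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 2])
        treated = treated + rng.normal(0.0, cfg.noise_sd, size=treated.shape)
    return control, np.clip(treated, 0.0, None)


# ---------------------------------------------------------------------------
# plain-text serialisation (deterministic bytes)

def _open(path_or_handle, mode="w"):
    if hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


def write_fasta(sequences: Mapping[str, str], path) -> None:
    handle, close = _open(path)
    try:
        for name in sequences:
            handle.write(f">{name}\n{sequences[name]}\n")
    finally:
        if close:
            handle.close()


def write_fastq(reads: Sequence[SimRead], path) -> None:
    handle, close = _open(path)
    try:
        for r in reads:
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    finally:
        if close:
            handle.close()


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    handle, close = _open(path)
    try:
        handle.write("read_id\tallele\tedited\tevents\tinsert_origin\n")
        for t in truth:
            ev = ";".join(f"{k}:{s}:{p}" for k, s, p in t.events)
            orig = (
                f"{t.insert_origin[0]}:{t.insert_origin[1]}:{t.insert_origin[2]}"
                if t.insert_origin
                else ""
            )
            handle.write(
                f"{t.read_id}\t{t.source_allele}\t{int(t.edited)}\t{ev}\t{orig}\n"
            )
    finally:
        if close:
            handle.close()


def write_trace_tsv(trace: np.ndarray, path) -> None:
    """One row per position, four tab-separated nonnegative intensities."""
    handle, close = _open(path)
    try:
        for row in np.asarray(trace, dtype=float):
            handle.write("\t".join(f"{v:.6f}" for v in row) + "\n")
    finally:
        if close:
            handle.close()


def read_trace_tsv(path) -> np.ndarray:
    if hasattr(path, "read"):
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    else:
        data = np.loadtxt(str(path), delimiter="\t", ndmin=2)
    if data.shape[1] != 4:
        raise ValueError("trace TSV must have exactly four channels")
    if (data < 0).any():
        raise ValueError("trace intensities must be nonnegative")
    return data
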