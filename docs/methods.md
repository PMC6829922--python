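# Methods

`polyedit` quantifies CRISPR-Cas9 editing outcomes per homoeoallele from
amplicon reads and Sanger-style traces.  This note records the models, the
parameters that matter, the design choices made where the design was open, and
what the synthetic benchmarks do and do not demonstrate.

## Problem setting

A guide RNA directs Cas9 to a 20–22 nt protospacer immediately 5′ of an NGG
PAM; the blunt double-strand break falls 3 bp 5′ of the PAM and error-prone
end joining leaves small insertions/deletions there.  In an allopolyploid such
as bread wheat the target gene exists as two or three homoeologous copies that
differ only at sparse diagnostic SNPs, so a guide can be active on one copy
and (depending on mismatch placement and PAM integrity) partially or not at
all on the others.  A validation screen amplifies a ~270 bp window around the
cut from treated and negative-control cells and asks, per homoeoallele: what
fraction of molecules carry an indel, what is the indel spectrum, and how much
vector DNA was captured at the break.

## Read assignment: two-phase end-to-end alignment

Reads are assigned by a global (end-to-end) affine-gap aligner minimising an
integer penalty, with the mismatch penalty interpolated in base quality q
(clipped at 40) as `floor(min + (max − min)·q/40)`.

* **Phase 1** (`min,max = 1,6`, gaps priced out at 999/999, total cap 6):
  accepts only gapless alignments with at most one full-quality mismatch —
  the unedited-read phase.  It is evaluated directly as a quality-weighted
  Hamming distance; reads whose length differs from the reference skip it.
* **Phase 2** (`min,max = 1,76`; deletion gap open/extend 24/1; insertion gap
  open/extend 9/14; total cap 75): the caps imply deletions up to 51 bp
  (24 + 51 ≤ 75) and insertions up to 4 bp (9 + 4·14 = 65 ≤ 75 < 9 + 5·14),
  and low-quality mismatches remain cheap (floor 1).
* **Rescue**: phase-2 penalties with the cap applied to the *non-insertion*
  penalty only, so reads carrying arbitrarily large inserts (vector capture)
  stay assignable and their alleles quantifiable.

A read is assigned to the unique strictly-best allele of the first phase that
accepts any allele; equal-best ties leave it UNASSIGNED (deterministically —
there are no random tie-breaks).  UNASSIGNED and discarded reads are excluded
from all per-allele denominators.  Traceback tie-breaks prefer
mismatch < deletion < insertion and place gaps leftmost.  The dynamic program
is exact (no seeding heuristics; amplicons are short enough for full DP, with
the inner loop jit-compiled via numba); its optimality is tested against an
exhaustive alignment-path enumerator and an independent memoized recursion on
small instances.

Consequences of this pricing, observed and handled:

* Reads accumulating several moderate-quality errors can exceed both caps and
  drop out (~5% at 0.5%/base error with error qualities U{2..20}); this
  mirrors the two-phase mapping scheme being emulated, slightly and almost
  symmetrically deflating treated and control percentages.
* A full-quality substitution costs 76 while a balanced 1 bp del + 1 bp ins
  pair costs 48, so the optimal gapped representation of adjacent high-quality
  mismatches is a balanced gap pair.  Quantification therefore treats any
  *balanced* event cluster (equal read and reference spans, net length change
  zero) as a multi-nucleotide substitution and ignores it when substitutions
  are ignored — making a substitution-only error process yield exactly 0%
  edited.
* Optimal alignments fragment large inserts: short coincidental diagonal
  matches inside an inserted segment are cheaper than gap extension (a 3 bp
  match run saves 45 against 33 for re-opening), the same failure mode widely used
  amplicon analysis tools exhibit on compound insertion+deletion events.
  Quantification consolidates indel ops separated by fewer than
  `event_merge_anchor = 10` aligned bases into one cluster and reads off the
  cluster's read span R and reference span G: the molecular interpretation is
  an insertion of R and/or deletion of G.  Cluster boundaries are normalised
  by trimming bases shared by the two segments, and pure insertions are slid
  along their ambiguity range to the placement nearest the cut, recovering the
  exact inserted sequence.  The anchor length 10 sits well above the longest
  gap-profitable coincidental match run.

## Quantification window and filters

Defaults follow the emulated analysis: window half-width 20 bp around the cut
(left-inclusive, right-exclusive overlap test — deletions by reference
interval, insertions by anchor point; the edge semantics of the original tools
are undocumented, so ours are declared), read-end exclusion margins of 5 bp
(events entirely inside a margin are ignored), Phred 30 end-trimming, and
substitutions ignored.  Because the aligner is end-to-end, quality trimming is
realised as masking: reads whose Q ≥ 30 core is shorter than twice the summed
margins are discarded, and for the rest the low-quality end runs are folded
into the exclusion margins while the full read is aligned (trimming the bases
off would force spurious end gaps through a global aligner).  Editing
frequency is percent edited minus the negative control, reported raw (a
negative difference warns rather than clamps).  Large insertions are ≥ 20 bp;
their frequency uses *edited* reads as denominator, and origin attribution
requires an exact forward or reverse-complement substring match against a
supplied vector — by construction a sequencing error inside the insert voids
attribution, so the attribution benchmark runs error-free.

## Trace decomposition

The treated chromatogram window (default: 5 bp downstream of the cut to 10 bp
before the usable trace end) is regressed on shifted copies of the control
trace, one column per signed indel size in −10..+10, all four channels
stacked, with non-negative least squares (scipy's NNLS).  Coefficients are
molecular fractions (renormalised only if their sum exceeds 1.05); standard
errors and two-sided p-values come from the OLS covariance restricted to the
active set (coefficients pinned at zero report p = 1), significance is
p < 0.001, and R² reports fit quality.  With a realistically long window
(hundreds of positions, as real capillary reads provide) a 1% indel is
significant at this threshold; with very short windows it is not — window
length, not solver accuracy, is the limiting factor.  Zero-noise fits
reproduce the simulated spectrum to ≤ 1e−6.  A per-position aberrant-signal
profile (percent intensity off the control's dominant channel, treated minus
control, floored at 0) localises the onset of editing at the cut.

## Synthetic data: what it emulates and what it omits

The generator produces k homoeoallelic amplicons (default three of 270 bp,
the scale of a typical deep-sequencing amplicon over a Cas9 site) from one random
backbone, differing at diagnostic SNP positions (default 110/125/165, flanking
a plus-strand guide with PAM start 150, cut at 147), with optional guide-site
mismatch injections (PAM-proximal numbering) and PAM knockouts (second G of
NGG replaced).  Reads are whole edited molecules: each edited read (Bernoulli
per read at the allele's edit fraction) carries one event — an indel drawn
from the spectrum (default {+1: 0.5, −1: 0.3, −2: 0.2}) or, with configurable
probability, a 20–60 bp substring of a synthetic vector inserted at the cut —
then substitution errors at 0.5%/base with quality drawn U{2..20} against a
constant Q37 background.  Insertions sit at the cut boundary; deletions are
centred with left bias.  Traces are four-channel peak matrices; the treated
trace is the fraction-weighted sum of shifted control traces downstream of the
cut plus truncated Gaussian noise (default sd 5% of the 1000-unit peak).

Not emulated: PCR chimeras and polymerase slippage, paired-end reads, indel
sequencing errors, homopolymer-dependent error profiles, basecalling artefacts
and true AB1 chromatogram shapes, and compound multi-event molecules (unless
configured).  Passing benchmarks therefore demonstrate correctness of the
analysis under a clean single-event error model, not robustness to every
artefact of real libraries.  The substitution-only error default is a declared
choice — real platform error profiles vary — and is configurable.

## Benchmark problem sizes

The acceptance script simulates 20000 reads per allele for the
negative-control floor and the off/on ratio, ~20000 reads total for the
large-insertion recovery, and a 420-position trace for the decomposition fit
— the scales at which the respective sampling errors are a small fraction of
the quantities measured.  The test suite runs the same checks at a few
thousand reads with tolerances widened to the corresponding 3·binomial-SD
bands.

## Other declared choices

* Seed region = PAM-proximal 12 nt (the literature range is 8–12; 12 chosen
  so that position-8 mismatches, which behave like seed mismatches in wheat
  protoplast screens, fall inside it); core = PAM-proximal 5 nt, carried as a parameter but not used by the
  default classification.  Specificity classes are ordinal labels, not
  activity predictions — observed activity correlates poorly with in-silico
  scores, which is why the report layer treats external scores as opaque
  numbers and censored values ("< 50") as missing, never imputed.
* Guide loci on other alleles are located by 15 nt exact flanking anchors with
  an alignment fallback — adequate at amplicon scale.
* Per-gRNA activity pooled over target homoeoalleles is the unweighted average
  of per-allele means by default; read-weighted pooling is available
  (`pooled_on_target_mean(..., weights=...)`).
* Replicate aggregation: SEM = sample sd (n−1)/√n; group comparisons use the
  Welch unequal-variance t-test with Satterthwaite degrees of freedom; no
  multiple-testing correction is applied.

## Known limitations

* Equal-length replacements (e.g. a true +2/−2 compound at the cut) are
  indistinguishable from multi-nucleotide substitutions in gap notation and
  are ignored under `ignore_substitutions`.
* Activity-class boundaries are rules, not fitted models; they encode PAM
  loss, seed mismatches and mismatch accumulation but no position-specific
  energetics.
* The assignment denominators omit reads that fail both acceptance phases and
  rescue; at high error rates this deflates absolute frequencies slightly
  (ratios are nearly unaffected).
* Trace decomposition assumes the control trace is noise-free and shift
  columns are exact translations; real chromatograms have dye blobs, mobility
  shifts and decaying peak height that would require baseline correction and
  per-position rescaling before decomposition.
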