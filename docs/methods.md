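# Methods

This note documents the models, rules and numerical choices behind
`taprootmir`, and what the synthetic-data generator does and does not
emulate.

## Study design the package assumes

Three unreplicated small-RNA libraries from successive developmental stages
of a thickening storage root, sequenced on a short-read instrument. All
quantification happens on *tags* — unique cleaned insert sequences with one
read count per library — and all normalization uses the clean-read total of
each library as denominator. Stage labels are `stage1..3`; comparisons are
always later-vs-earlier with the earlier stage as control.

## Read cleaning

* Quality gate (before any adapter logic): reject reads containing `N`,
  more than 4 bases with Phred quality < 10, or more than 6 bases with
  quality < 13. Rejected reads count against "raw" but not "high-quality".
* 3′ adapter search: the earliest read position where a prefix of the
  adapter matches through the read end (minimum overlap 6 nt, ≤ 1
  mismatch). Earliest-position matching is what makes the null-insert
  (adapter at position 0) and short-insert categories observable at all; a
  matcher restricted to positions past the minimum insert length could not
  produce them.
* Category order (first failing check wins): adapter absent → empty insert →
  5′ adapter contaminant (insert begins with an 8-nt exact prefix of the 5′
  adapter) → poly(A) (≥ 80% A) → shorter than 18 nt → longer than 30 nt.
  "Longer than 30 nt" is kept as its own category and reported as a footnote
  row in the accounting table, which classically prints only the five
  shorter-side categories.
* Percentages are reported against high-quality reads at 2 decimals,
  round-half-even. The partition `high_quality = clean + Σ removed` is
  asserted, not assumed.

## Annotation hierarchy

Non-coding RNA matching (exact substring of a catalog sequence, sense or
antisense) strictly precedes known-miRNA matching; the remainder is
unannotated. Known-miRNA matching compares the tag against each mature over
the mature's length with the tag 5′ end anchored at offsets −2..+2, no
indels; uncovered mature positions count as mismatches; ≤ 2 mismatches
qualify. Ties are broken by mismatch count, then |offset|, then mature name;
a multi-family tie is logged as a warning. Reference mapping is exact
two-strand substring search — a deliberate simplification of seed-and-extend
read mapping that is lossless for error-free tags.

## Folding model

The novel-miRNA predictor needs reproducible minimum-free-energy folding
with kcal/mol-scale outputs. We use a compact nearest-neighbor model over
nested structures (no pseudoknots):

* Pairs: Watson–Crick and G:U. Stacking energies for WC-on-WC stacks range
  −0.9 to −3.4 kcal/mol (table pinned in `_fold.py`); a stack involving one
  wobble pair scores −1.4, two wobble pairs −0.5.
* Loops: hairpin +5.0 (minimum 3 unpaired); bulge +3.0 + 1.0/nt; interior
  +4.0 + 0.5/nt (≤ 30 unpaired per loop); multibranch +4.0 + 0.5 per
  unpaired base, branches free.

The Zuker-style dynamic program (`V`/`WM` recursions, O(n³)) is exact for
this model; a brute-force enumerator of all nested pairings
(`brute_force_mfe`) serves as its oracle on short sequences, and the test
suite checks equality on 50 seeded sequences of length ≤ 14. The DP is
JIT-compiled with numba when available; the pure-Python fill is the
reference path and produces identical numbers. Energies are deterministic,
invariant under T↔U spelling, and the empty structure bounds the MFE at 0.
The constants are calibrated only to the extent that realistic hairpins land
in the −18…−95 kcal/mol range reported for plant precursors; they are not a
thermodynamic parameter fit.

## Novel-miRNA criteria

For each mapped unannotated tag with ≥ 5 total reads (lowest abundance
reported for credible novel candidates), two windows are excised per locus:
`[start − flank, end + small]` and `[start − small, end + flank]` with
flank 160 nt and small 15 nt, clipped to the contig and strand-adjusted so
the mature reads sense. Defaults make precursor lengths 47–354 nt reachable.
Acceptance requires all of:

* `mature_in_one_arm`: the mature's paired bases are all `(` or all `)`.
* `stem_loop`: their partners are strictly monotone — one contiguous
  opposite arm with a single terminal loop between.
* `duplex_mismatches_ok`: ≤ 4 unpaired mature bases.
* `bulge_ok`: no asymmetric bulge > 2 nt between consecutive paired bases.
* `mfe_ok`: window MFE ≤ −18 kcal/mol.

The star search derives the expected star interval from the duplex geometry
(partners of the mature minus its two 3′-overhang bases, extended 2 nt past
the partner of the mature 5′ end) and accepts a tag whose mapped span agrees
within ± 1 nt. When the "star" is the more abundant arm the two are swapped
— the field convention names the abundant arm the mature — and near-parity
duplexes (star ≥ half the mature reads) are flagged, never rejected.
Overlapping accepted windows are collapsed to the lowest-MFE one, with
overlap judged on the duplex extent in genomic coordinates (whole windows
overlap merely by flank for nearby loci; duplex extents do not), ties broken
toward the more abundant mature.

## Differential expression

* RPM = count / clean-library-size × 10⁶, full precision internally,
  2 decimals in reports. The 0 → 0.01 substitution is a fold-change rule and
  never enters normalization, so ΣRPM over a full tag table is 10⁶.
* A comparison is skipped only when *both* substituted values are < 1;
  skipping on "either" would forbid exactly the comparisons against 0.01
  that make stage-specific miRNAs reportable.
* The exact test conditions on the total count of a tag in two libraries.
  The implementation evaluates the two tails through
  `K | x ~ NegativeBinomial(x+1, N₁/(N₁+N₂))` via the regularized
  incomplete beta function; `ac_pvalue_reference` re-derives the same
  quantity by direct term-by-term summation in 80-bit floats and agrees to
  better than 10⁻¹⁰ relative. Below ~10⁻²⁹⁰ both routes underflow double
  precision and only agreement-at-zero is meaningful. The two-sided
  construction (double the smaller tail, cap at 1) is *not* exactly
  symmetric under swapping the libraries — the underlying conditional model
  is symmetric pointwise, but the tail that gets doubled changes — so the
  package fixes the orientation: x is always the earlier (control) stage.
* No multiple-testing correction is applied, matching the unreplicated
  screening design this pipeline reproduces.
* Clustering is the deterministic sign pattern of the two transitions
  (`up`/`down`/`flat` at |log₂FC| ≥ 1), not a distance-based clustering:
  with three points per profile, pattern labels are the reproducible content
  of any such clustering.

## Target scanning

The expectation score is a penalty sum over an antiparallel gapped
alignment: mismatch +1, G:U +0.5, gap +2, doubled at miRNA positions 2–13
(5′-anchored seed). At most one gap is allowed, enumerated exactly rather
than solved by general alignment; cutoff 3.0. `N` in a transcript counts as
a mismatch. A non-wobble defect at positions 9–11 switches the predicted
mode from cleavage to translational repression. Overlapping reported
windows collapse to the best score, so lowering the cutoff never adds hits.

## Synthetic data: what it emulates, and what it does not

The generator plants, per stage library (default 20,000 clean reads,
~1000× below real depth):

* eight known matures across familiar families, including a miR156a-like
  decline proportional to 505,759 : 50,613 : 16,238 reads (≈ 3% → 0.27% →
  0.095% of clean reads), a rising miR172-like, a dip-and-recover
  miR166-like, a stage-specific miR398-like (absent from stage 1), three
  exact nulls and one sub-threshold drifter; two catalog matures stay
  unplanted as negative controls;
* four ncRNA contaminants (rRNA/tRNA/snRNA/snoRNA, 3% each);
* three perfect hairpins (21-bp duplex, 12–14-nt loop, 2-nt 3′ overhangs,
  one on the reverse strand) with mature and one-fifth-abundance star reads,
  one of them declining across stages;
* artifact reads at rates inspired by published accounting tables (0.9%
  5′ adapter contaminants, 0.6% short inserts, 0.05–0.1% the rest) and a
  0.05%/base low-quality injection;
* the remainder (~60%, emulating the typical unannotatable majority) drawn
  from random contig positions with a 21/24-nt-dominated length profile.

Reads are 36 nt (insert + 3′ adapter fill), Phred+33. All sampling is one
multinomial per library over artifact classes, entities and background, so
realized counts carry exact multinomial statistics and are recorded in a
truth table together with expected per-million log₂ fold changes and DE
status at |log₂FC| ≥ 1.

Deliberately not modeled: sequencing errors in base calls (only quality
scores are degraded), PCR duplicates, GC bias, isomiR heterogeneity,
multi-locus miRNA families, and genome-scale reference complexity. Passing
tests therefore demonstrate correctness of the pipeline's logic and
statistics under clean mapping conditions, not robustness to base-call
error or to ambiguous multi-mapping — on real data the exact matcher and
the 0-mismatch recovery guarantees would degrade first.

## Problem sizes and determinism

Tests and the acceptance script run three 20,000-read libraries (a scale at
which every planted effect of |log₂FC| ≥ 2 with ≥ 50 expected reads is
decisively detectable by the exact test), a 200-case p-value oracle grid
spanning counts to 10⁵, and 50 enumeration-oracle folds. All randomness
flows from explicit `numpy` generators; identical seeds give byte-identical
FASTQ, truth tables and results.

## Known limitations

* The energy model is compact by design; absolute MFE values are
  model-specific and should be compared only within this package.
* Exact substring mapping cannot place tags across assembly gaps or
  polymorphisms.
* With three stages, Spearman-based miRNA–target anti-correlation can only
  take values {−1, −0.5, 0, 0.5, 1}; the `anti`/`co`/`none` summary is a
  coarse screen, not an inference.
* Family-level expression rows aggregate by summing member counts; studies
  that print the top member's values instead will differ at the family
  level (member-level values are identical).
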