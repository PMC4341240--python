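# taprootmir

A small RNA-seq analysis pipeline for staged plant miRNA studies: read
cleaning and tag collapsing, hierarchical small-RNA annotation, hairpin-based
novel-miRNA prediction, per-million normalization with exact-test
differential-expression screening, expression-pattern clustering, plant-style
miRNA target scanning, and 2^−ΔΔCt RT-qPCR arithmetic.

The package targets the classic unreplicated three-library design used to
study storage-root (taproot) thickening in radish: one small-RNA library per
developmental stage (pre-cortex splitting, cortex splitting, expanding),
sequenced to tens of millions of reads, with miRNA families such as miR156
declining steeply as the root thickens. Because such data are large and
externally hosted, the package ships a first-class synthetic-data generator
that emulates the design at ~1000× scale-down with fully known planted truth,
so every stage of the pipeline is testable end to end.

## The statistics and algorithms at the core

**Cleaning.** A read is high-quality when it has no `N`, at most 4 bases with
Q < 10 and at most 6 with Q < 13. High-quality reads are then partitioned by
the first failing check: 3′ adapter absent → empty insert → 5′ adapter
contaminant → poly(A) insert → insert < 18 nt → insert > 30 nt → clean.
Clean inserts are collapsed into unique tags with per-library counts.

**Annotation.** Tags are mapped to the reference by exact matching on both
strands and classified with strict priority: rRNA/tRNA/snRNA/snoRNA first
(exact substring of a catalog sequence, either strand), then known miRNA
(≤ 2 mismatches against a mature catalog, tag 5′ end anchored at offsets
−2..+2), else unannotated.

**Novel miRNA prediction.** Around each mapped unannotated tag (≥ 5 reads)
two candidate precursor windows are excised (5′-arm and 3′-arm hypotheses),
folded by a nearest-neighbor minimum-free-energy dynamic program (Watson–
Crick and G:U stacking, loop penalties; see `docs/methods.md`), and accepted
when the mature sits in one arm of a stem–loop, pairs contiguously with the
opposite arm (≤ 4 unpaired bases, no asymmetric bulge > 2 nt) and the window
folds below −18 kcal/mol. A star tag with 2-nt 3′-overhang duplex geometry
(± 1 nt) upgrades the evidence.

**Differential expression.** Counts are normalized to reads per million
clean reads (RPM = x/N × 10⁶). For a pairwise comparison, a zero normalized
value is replaced by 0.01; when both values are below 1 the comparison is
skipped. Significance uses the Audic–Claverie exact test for two libraries,

    p(y | x) = (N₂/N₁)^y · (x+y)! / ( x! · y! · (1 + N₂/N₁)^(x+y+1) ),

with two-sided p = 2·min(P(K ≤ y), P(K ≥ y)) capped at 1, evaluated through
the negative-binomial identity K | x ~ NB(x+1, N₁/(N₁+N₂)) so counts up to
10⁷ never overflow. A miRNA is differentially expressed when at least one of
the three stage comparisons reaches |log₂FC| ≥ 1 with p < 0.05; DE records
are clustered by the deterministic sign pattern of their stage1→2 and
stage2→3 moves.

**Target scanning.** A miRNA is aligned antiparallel against every
transcript window (≤ 1 gap); columns cost mismatch +1, G:U +0.5, gap +2,
doubled in the seed (miRNA positions 2–13). Windows with expectation ≤ 3.0
are reported; a central defect (positions 9–11) marks translational
repression rather than cleavage.

**RT-qPCR.** Relative expression is 2^−ΔΔCt against a reference gene and a
calibrator sample.

## Worked example

```bash
$ taprootmir run --outdir demo/ --seed 1
clean reads: {'stage1': 19999, 'stage2': 20004, 'stage3': 19999}
novel candidates: 3
DE miRNAs: 5 of 11
```

The run simulates three 20,000-clean-read stage libraries, cleans and
annotates them, predicts novel hairpins, screens differential expression and
writes report tables under `demo/reports/`. The expression table
(`expression_table2.tsv`) starts:

```
mirna_id     family  reads_stage1  reads_stage2  reads_stage3  normalized_stage1 ...  log2fc_stage2_stage1 ...  de     cluster
rsa-miR156a  miR156  643           55            13            32151.61               -3.55                     True   down_down
rsa-miR159a  miR159  793           764           817           39651.98               -0.05                     False
rsa-miR166a  miR166  411           98            450           20551.03               -2.07                     True   down_up
```

The planted miR156-like entity declines ~25-fold from stage 1 to stage 3 and
is flagged DE with a monotone `down_down` pattern; the flat miR159-like null
is not flagged. Three novel candidates are the three planted hairpins, each
recovered with its star strand. Every number recomputes from the upstream
tables: e.g. 32151.61 = 643 / 19999 × 10⁶.

Each pipeline stage is also exposed separately (`taprootmir simulate`,
`clean`, `annotate`, `novel`, `diffexp`, `targets`, `qpcr`), and as library
functions (`taprootmir.clean_library`, `taprootmir.classify`,
`taprootmir.predict_novel`, `taprootmir.expression_table`, ...).

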