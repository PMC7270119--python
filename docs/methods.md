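# Methods

## Design under analysis

The pipeline analyses the classic parent–hybrid trio design: two inbred
lines are crossed, the F1 hybrid and both parents are phenotyped and
RNA-sequenced, and the question is which genes are expressed non-additively
in the hybrid and whether that non-additivity (expression-level dominance or
overdominance) tracks the phenotypic heterosis. The expression input is one
FPKM-like column per genotype — a single library per genotype, no replicate
structure — so all significance judgements are fold-change thresholds, not
statistical tests. Replicate averaging, if any, is assumed to have happened
upstream; the readers accept exactly one column per genotype.

## Fold-change convention and pseudocount

All expression comparisons use the signed (symmetric) ratio
fc(a,b) = (a+c)/(b+c) for a ≥ b and −(b+c)/(a+c) otherwise. This is the
convention under which "FC ≥ 2 / FC ≤ −2" thresholds and printed values
like −2.96 are coherent; it is antisymmetric and never falls in (−1, 1).
Both operands receive a pseudocount c (default 0.01 FPKM) so ratios are
defined for unexpressed genes; c is recorded in every run's metadata. A
consequence worth knowing: the pseudocount attenuates ratios, so a gene
whose raw abundances sit exactly at a 2-fold ratio lands fractionally below
the threshold. Thresholds are inclusive (≥ 2, ≤ −2) and configurable; an
optional expression floor (`min_abundance`) can suppress calls on genes
whose larger operand is below a given FPKM, off by default.

## DEG sets across crosses

Per cross, a gene enters the common-up (common-down) set when it is up
(down) versus *both* parents; opposite-direction genes belong to neither.
Across two crosses, universal-up/down are the concordant intersections,
"discordant" collects genes common to both crosses with opposite direction,
and the unique-union count is the size of the union of all four common
sets (it obeys inclusion–exclusion with the pairwise overlaps, which the
tests assert on random instances). A gene found in both the up and the down
set of one cross is an integrity error, not a warning.

## The 12-class scheme

With states from the same threshold t ("higher"/"lower"/"equal" by
fc ≥ t / fc ≤ −t / otherwise) for F1-vs-maternal, F1-vs-paternal and
maternal-vs-paternal, plus an F1-vs-midparent state:

* F1 higher than both parents → transgressive up-regulation; class 5/6/8 as
  the parents are higher/equal/lower (maternal relative to paternal).
* F1 lower than both → transgressive down-regulation; class 3/7/10 by the
  same parent relation.
* Parents differ, F1 ≈ one parent and differs from the other →
  expression-level dominance: maternal (class 4 if maternal > paternal,
  else 9) or paternal (class 2 if paternal > maternal, else 11).
* Parents differ, F1 strictly between them *and* F1 ≈ midparent → additive
  (class 1 if maternal > paternal, else 12).
* Anything else (including no differential expression at all) → "none".

The extra midparent condition on additivity matters: a gene intermediate
between very distant parents can be more than t-fold away from their mean,
and such genes are deliberately left unclassified rather than called
additive. The mapping from class numbers to coarse groups (additive {1,12},
ELD {2,4,9,11}, overdominance {3,5,6,7,8,10}) is fixed; the assignment of
numbers *within* each transgressive triple follows the maternal-vs-paternal
relation in left-to-right order and is a documented convention — analyses
should key on the coarse groups, which are the tested surface. Swapping the
parent columns maps 1↔12, 2↔4, 9↔11, 5↔8, 3↔10 and fixes 6, 7; this
symmetry is property-tested.

Whether "≈" should be judged on the natural or log2 scale is immaterial
here: the signed-ratio cutoff t is exactly a symmetric log2 cutoff of
log2 t.

The coarse per-hybrid rule (overdominance / dominance / additive when the
hybrid is significantly changed versus both / one / neither parent, with
opposite-signed significant changes labelled "discordant") reproduces all
56 printed per-hybrid labels of the bundled 28-gene universal-DEG table.

## Mode summaries

Percentages are computed over classified genes (class ≠ none), per cross and
pooled over crosses; dominance% = maternal-ELD% + paternal-ELD% and
overdominance% = transgressive-up% + transgressive-down% by construction.
An all-"none" input yields zero percentages with an explicit
`n_classified = 0` rather than NaNs.

## Phenotypic heterosis

MPH = 100·(F1 − MP)/MP and HPH = 100·(F1 − HP)/HP with MP the parental
mean and HP the *larger* parental mean for every trait, including
days-to-flowering — direction-of-desirability is metadata. Both statistics
are scale-invariant and parent-symmetric, and MPH ≥ HPH whenever both
parents are positive; these invariants are property-tested. Computation is
in full precision; reports round to 2 decimals half-up. A zero mid- or
high-parent value raises an explicit "undefined heterosis" error. Against
the bundled lily trait table, 17 of the 18 internally consistent printed
percentages reproduce exactly at 2 decimals; the plant-height cross-A MPH
computes to 31.0153 (printed: 31.01, a truncation of the last digit), and
the two flower-diameter HPH cells are flagged as inconsistent with their
own printed means rather than reproduced.

## qPCR validation

Relative expression follows 2^−ΔΔCt with amplification efficiency fixed at
2: ΔCt = Ct(target) − Ct(reference) per genotype (technical replicates
averaged on the Ct scale), ΔΔCt = ΔCt(sample) − ΔCt(calibrator). The
calibrator genotype is an explicit user parameter. Biological-replicate
folds are summarized as geometric mean with range. Concordance with RNA-seq
treats fold > 1 as "up", fold < 1 as "down", and compares "ns" calls against
a band [1/1.5, 1.5] by default. Reciprocity (fold(s,c)·fold(c,s) = 1) is
property-tested.

## Synthetic data generator

The generator emulates RSEM-style FPKM output for one or two trios, one
column per genotype. Each gene draws a true class from configurable
proportions (12 classes + none); its noise-free levels are built from a
log2-normal baseline (mean 3, sd 1.5 on the log2 scale, i.e. a median of
8 FPKM with a heavy right tail, floored at 0.5 FPKM so pseudocount
distortion of ratios stays negligible). "Equal" levels are exactly equal;
"different" levels differ by `effect_size` (default 4, i.e. a comfortable
margin above the calling threshold of 2) — except in the additive classes,
where the constraint set is tighter: if the hybrid sits g-fold from each
parent, the parents are g²-fold apart and the hybrid is (g²+1)/(2g)-fold
from their mean, which must stay *below* the threshold while g stays above
it. At t = 2 that forces g < 2+√3; a 4-fold gap is impossible for a gene
that is additive under the classifier's own definition. Additive genes are
therefore placed at the geometric mean of parents separated by 2t²−1
(g = √7 ≈ 2.65 at t = 2), the equal-margin point that maximizes robustness
of both the F1-vs-parent calls and the midparent test under noise.

Multiplicative log2-normal noise (sd `noise_sd`, default 0.1) is applied to
every cell — simpler than count-level negative-binomial noise and
appropriate because the pipeline consumes FPKM without replicates, so the
noise model only needs to stress the classifier, not a variance estimator.
With noise 0 the classifier provably recovers every truth label; the tests
assert exact recovery at n = 1000, misclassification monotone in
noise_sd ∈ {0, 0.1, 0.25, 0.5}, and recovery of the "paper_like" coarse
proportions (19.35% additive / 4.76% dominance / 75.89% overdominance,
split evenly within groups) within 3 percentage points at n = 5000,
noise 0.1.

Two crosses draw truth independently by default; an `overlap` parameter
forces the first genes to be transgressive in both crosses with chosen
concordant/discordant direction counts (default 11/7 concordant up/down,
14/2 discordant) so the universal-set logic can be exercised end to end.
Trait trios are simulated by inverting the MPH formula (draw parents and a
target MPH, set F1 = MP·(1+MPH/100)), so the heterosis stage must reproduce
the stored truth to floating-point accuracy.

What the generator does *not* emulate: read-level sampling noise,
gene-length and GC biases, assembly artifacts, correlated noise across
genotypes, or a realistic proportion of near-zero genes. Passing tests on
synthetic data therefore demonstrate correctness of the arithmetic and the
classification logic under the stated noise model, not robustness to
real-library artifacts.

## Problem sizes and numerical choices

Default test and validation runs use 300–5000 genes and 1–2 crosses, which
exercise every code path at interactive speeds. Row ordering of every
output table is fully specified (gene id, then cross id, lexicographic), so
repeated runs are byte-identical; rerun determinism is tested. Zero-variance
libraries yield NaN correlations with a warning rather than a silent 0.
Ties at thresholds are resolved inclusively everywhere (≥/≤). Percentages
in summaries are reported in full precision and rounded only in reports.

## Known limitations

* No replicate-aware testing (dispersion modelling à la DESeq2); the
  fold-change-only design inherits the false-positive behaviour of
  threshold calling on single libraries.
* The 12-class geometry for a gene near several thresholds simultaneously
  is resolved to "none" rather than forced into a class; on heavily
  pre-filtered DEG sets this residual category is small, but on whole
  matrices it is the majority (most genes are not differentially
  expressed).
* ANOVA-based significance stars for trait tables, GO/KEGG annotation and
  heat-map rendering are out of scope; a log2 matrix export is provided for
  external clustering/heat-map tools.
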