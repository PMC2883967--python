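# Methods

Precise definitions and conventions for every statistical procedure in
`renalclass`. All expression values are log2-scale (RMA-style); matrices
are probes × samples.

## Probe filtering (`renalclass.preprocess`)

A probe is retained when both hold:

1. its coefficient of variation `sd/mean` (sample sd, `ddof=1`), computed on
   the log2 values by default (`cv_scale="linear"` switches to `2**x`),
   is at least `cv_min` (default 0.05), and
2. at least `min_samples_at_expr` samples (default 2) reach the expression
   floor `expr_min` (default log2 = 8).

The filter is deterministic and idempotent; an empty result is a warning,
not an error.

## Hierarchical clustering (`renalclass.preprocess`)

Samples are clustered by complete linkage (`scipy.cluster.hierarchy`) under
correlation distance `1 − r` (default) or Euclidean distance. The
`Dendrogram` records merges, heights and the leaf order, and exports Newick.
`cut_tree(dendrogram, k)` applies the first `n − k` merges (a union-find
pass) and labels clusters by first appearance.

## SAM (`renalclass.sam`)

For two classes (lexicographic order unless overridden), per probe:

    d_i = (mean₂ − mean₁) / (s_i + s₀),
    s_i = sqrt(var₁/n₁ + var₂/n₂)   (unbiased variances; Welch form).

A pooled-variance form is available. The exchangeability constant `s₀` is
chosen from the percentiles {0, 5, …, 100} of `{s_i}`: probes are windowed
by `s_i` quantiles and the candidate minimizing the coefficient of variation
of windowed median absolute deviations of `d` (scaled by 1/0.64) wins, ties
going to the lowest percentile.

The permutation null enumerates all `C(n, n₁)` label assignments when that
count is at most `n_perm` (the result is then seed-independent); otherwise
`n_perm` assignments are sampled uniformly with replacement from a seeded
generator. Sorted permuted statistics are averaged into the expected order
statistics `d̄_(i)`.

**Delta calling (asymmetric rule).** For threshold Δ the upper cut is the
smallest observed order statistic with `d_(i) − d̄_(i) ≥ Δ`, the lower cut
the largest with `d̄_(i) − d_(i) ≥ Δ`. Probes beyond either cut are called;
if the cuts cross, every probe is called. The estimated number of false
calls is the median over permutations of permuted statistics beyond the
cuts, and `FDR = π₀ · false_calls / called` with `π₀ = 1` (conservative).
Fold changes are reported on the linear scale, oriented to the first class:
`FC = 2^(mean₁ − mean₂)`.

## Nearest shrunken centroids (`renalclass.nsc`)

With `K` classes, class sizes `n_k`, pooled within-class standard deviation
`s_i` (divisor `n − K`) and offset `s₀` (default: 30th percentile of
`{s_i}`), the standardized centroid score is

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s₀)),   m_k = sqrt(1/n_k − 1/n).

For `K = 2` the numerator is computed in the algebraically identical
pairwise form `±(n_other/n)(x̄_{i1} − x̄_{i2})`, which makes the
antisymmetry `d_{i1} = −d_{i2}` exact in floating point. Soft thresholding
by Δ gives `d′ = sign(d)·max(|d| − Δ, 0)`; features with all-zero shrunken
scores drop out of the predictor. New samples minimize the discriminant

    δ_k(x) = Σ_surviving (x_i − x̄′_ik)² / (s_i + s₀)² − 2 log π_k,

ties broken toward the larger prior. With no survivors the rule reduces to
the prior alone.

**Model selection.** Stratified 10-fold cross-validation (seeded shuffle)
over 100 relative positions of each training fold's own threshold grid
`[0, max|d_ik|]`; curves aggregate at shared relative positions. The
selected threshold is the one whose cross-validated error is at most 10%
with the fewest mean surviving features, ties going to the largest
threshold (the smallest acceptable predictor).

## CGMA (`renalclass.cgma`)

Relative expression `R = log2(T) − mean log2(N)` against the normal
reference, probes collapsed to genes by the mean. Per sample and chromosome
arm, with `n` the mapped genes whose `R ≠ 0` and `k` the count with `R > 0`,
the sign-test statistic is `z = (k − n/2)/sqrt(n/4)`; calls are gain at
`z ≥ 1.96`, loss at `z ≤ −1.96`, neutral otherwise. Arms with fewer than 10
genes are skipped. A cohort summary reports per-region gain/loss fractions.

## SNP copy-number analysis (`renalclass.cnv`)

Per sample and chromosome (SNPs in position order), a **loss** is a maximal
run of at least 4 consecutive SNPs with copy number strictly below 1.6; a
**gain**, strictly above 3.5. Missing values break runs; no smoothing.
A **recurrent (CNA) region** for a cohort is a maximal run of at least 4
SNPs each covered by same-type calls in strictly more than 30% of the
cohort's samples; its prevalence is the minimum covered fraction over the
span. Calls export to BED (0-based half-open).

## Gene-set enrichment (`renalclass.enrichment`)

With universe size `U`, set size within the universe `m`, selection size `s`
and overlap `k`, the p-value is the hypergeometric upper tail
`P(X ≥ k)` (`scipy.stats.hypergeom.sf(k−1, U, m, s)`). Reported alongside:
`ExpCount = s·m/U` and the sample odds ratio
`k(U−m−s+k) / ((s−k)(m−k))` (infinite when a denominator cell is zero).
Collection-level results keep rows with `p <` threshold (default 0.01),
sorted by p-value; a Benjamini–Hochberg column is informative only and
never filters. **Conditional testing** for hierarchical collections
processes terms in reverse topological order of the parent→child DAG and
removes the genes of each significant term (default threshold 0.001) from
all of its ancestors before they are tested.

## Exact 2×2 tests (`renalclass.exact_tests`)

The two-sided Fisher exact p-value follows the point-probability criterion:
with margins fixed, sum the hypergeometric probabilities of all tables
whose point probability does not exceed the observed one, up to a relative
tolerance of 1e−7. Totals ≤ 170 use exact integer/rational arithmetic;
larger tables use log-space factorials. Printed-precision rounding is two
decimals at `p ≥ 0.01` and one significant figure below. The odds ratio is
the sample `ad/bc`. The immunohistochemistry marker panel of the motivating
study ships as module data (`IHC_MARKER_TABLES`).

## Synthetic data (`renalclass.simulate`)

A miniature genome (23 chromosomes with declining lengths, centromere at
40%, four cytobands per arm) hosts the probe and SNP annotations.
Expression: shared per-probe baseline `Normal(8, 1.5)`, class-specific
log2 effects of alternating sign on a chosen number of discriminative
probes, arm-level shifts per class (whole-arm or terminal fraction), and
iid `Normal(0, 0.5)` noise; a normal-tissue reference shares the baseline.
Copy number: `Normal(2, 0.15)` background clipped at zero with injected
segments (per-cohort, per-chromosome fraction spans) overwriting a sampled
subset of samples. Every generator draws from `numpy` streams keyed by
`[seed, stream]`, is bitwise reproducible, and emits a truth ledger of the
injected structure for parameter-recovery tests.

## Pipeline (`renalclass.pipeline`, CLI `renalclass`)

Stages: simulate/load → filter → cluster, SAM, nearest shrunken centroids,
CGMA on expression; segment calling → CNA regions on copy number;
enrichment on the SAM-called genes; Fisher tests on the marker panel.
Every output is registered in `manifest.json` with its SHA-256 hash; no
timestamps are written, so a rerun with the same config and seed is
byte-identical. Stage failures raise `PipelineError` naming the stage.
Results never depend on `--threads` (single-threaded contract).
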