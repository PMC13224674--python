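# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `nichecompare`.

## Cell-level model and QC

Cells live in an `AnnData` (cells × genes, raw integer counts) with metadata
`group ∈ {Ctrl, EuE, EcP, EcO}`, `patient`, `cell_type`, and the three QC
metrics.  QC removes cells with fewer than 500 detected genes, fewer than
1,000 UMIs, or more than 25% mitochondrial content; the thresholds follow
common single-cell practice and the removal is strict (a cell exactly at a
threshold is kept), matching the "< 500 / > 25%" phrasing the rule derives
from.  Normalization is `log(1 + 10⁴ · count / cell_total)`.  This is a
deliberate divergence from variance-stabilizing transforms (sctransform):
every downstream operation here needs only "log-normalized expression", the
log1p form is exactly reproducible, and tests cross-check it against
scanpy's `normalize_total` + `log1p`.

Positivity ("expressing cell") is `raw count > 0`, evaluated on counts.
Under the monotone normalization above this is equivalent to positivity on
normalized values; whether the original analysis assessed positivity pre- or
post-normalization is not stated anywhere we could check, so the counts
convention is recorded here once and reused everywhere.

## The two-step sparse-gene test

For a gene expressed in a small fraction of cells, the package tests two
separable hypotheses:

1. **Frequency.**  Expressing fractions are compared with the pooled
   two-proportion z-test (no continuity correction).  The pooled form makes
   z² identical to the 2×2 Pearson chi-square, which the tests exploit as an
   oracle.  The degenerate case (both fractions 0 or both 1) is defined as
   (z = 0, p = 1).
2. **Intensity.**  Among expressors only, intensity is the *linear* relative
   expression `count / cell_total`.  The reported effect is the ratio of
   geometric means (a fold change, invariant to the normalization scale);
   the test is Welch's t on natural-log values with Welch–Satterthwaite df.
   Natural logs are used because the base cancels from both t and the ratio.
   With fewer than two expressors on a side, the intensity step is marked
   not evaluable and the frequency step still returns.

The two p-values are never combined.  Across a batch of gene × comparison
rows, frequency and intensity p-values are BH-adjusted as two separate
families — they answer different questions and the original report keeps
them distinct.  Null calibration (checked at n = 2,000 cells per group,
base fraction 0.02): the frequency step's type-I error at nominal 0.05 is
≈ 0.045–0.05 (its p-values are discrete, so the rejection rate, not a KS
statistic, is the meaningful check), and the intensity step's null p-values
are KS-uniform.

## Pseudo-bulk negative-binomial Wald test

Counts are summed per patient–tissue combination (the study design gives
3 + 9 + 8 + 4 = 24 samples), genes are filtered, and size factors are
estimated by median-of-ratios (reference = per-gene geometric mean over
samples among genes positive everywhere; factors rescaled to geometric mean
one; total-count fallback with a warning when no gene is positive
everywhere).

The published filter wording ("row sums < 10 across fewer than 3 samples")
is ambiguous; the default reading keeps genes with **count ≥ 10 in ≥ 3
samples**, which preserves genes with replicated signal, and the row-sum
reading is available via `mode="row_sum"`.

Per gene, a negative-binomial GLM with log link, `offset = log(size
factor)`, and a single group coefficient is fitted by IRLS (statsmodels).
Dispersion is a per-gene method-of-moments estimate on normalized counts,
pooled over the two groups and floored at 10⁻⁸ — transparent and
oracle-checkable, unlike shrinkage estimators, at the cost that per-gene
log₂FC values are noisier than a shrunk estimator would give.

**Calibration choice.**  The Wald statistic `coef/SE` is referred to a t
distribution with `n_samples − 2` degrees of freedom, not the normal.  With
a handful of samples and a noisy moment dispersion the normal reference is
anti-conservative (empirical type-I ≈ 0.10 at 4 vs 4, ≈ 0.07 at 8 vs 4);
the t reference restores 0.05-level calibration and KS-uniform null
p-values at both designs.  This is the package's own small-sample decision.

Significance is |log₂FC| > 1 with BH q < 0.05.  A caveat the tests
quantify: with a sizeable one-sided DE fraction (250/2000 genes at log₂FC
2), median-of-ratios absorbs part of the shift, and the mean recovered
log₂FC is ≈ 1.85–1.89 — inside the ±0.3 recovery band but systematically
slightly low.  This is a property of median-of-ratios normalization
generally, not of this implementation.

## Spatial segment analysis

Segments QC on detection rate (> 30% of panel genes with count > 0,
strict).  Q3 normalization computes each segment's 75th percentile **over
positive counts** and rescales toward the geometric mean of all segment
Q3s; the post-normalization Q3 is constant across segments and the
operation is idempotent.  The platform convention motivates both choices;
the source only states "75th percentile".  Cross-platform harmonization
keeps gene symbols with > 5 counts in > 10% of units in **both** datasets
(strict inequalities; integer count comparisons keep the boundary exact).

Co-expression is rank-based throughout: Spearman with average-rank ties and
the t approximation for p (adequate at n = 60; an exact-permutation check
is in the test suite's oracles), BH within the tested family, and the
ligand–receptor screen at ρ > 0.7, q < 0.001.  The partial Spearman
correlation uses the first-order formula on ranks with p from t on n − 3
df; it is algebraically identical to residualizing the ranks on the
covariate and correlating residuals, which is the test oracle (pingouin's
`partial_corr` is a second, independent cross-check).  The covariate is the
single composite immune score (mean log expression of CD68, CD3D, CD3E,
PTPRC, CD4, CD8A), not six separate markers — one covariate mirrors how the
adjustment is reported and keeps n − 3 df honest.  Denominators below 10⁻¹²
(covariate numerically collinear with an input) return NaN with a warning.

Co-expression modules: genes standardized over segments, complete-linkage
agglomeration on Euclidean distance, tree cut at k.  Genes are processed in
lexicographic order and module labels renumbered by first appearance, so
the assignment is deterministic and input-order invariant.

Variance partitioning standardizes genes, runs PCA over segments, regresses
each PC's scores on tissue + compartment dummies (biology) and separately
on slide dummies (batch), and reports the explained-variance-weighted sums
of the R²s.  The two fractions come from separate regressions and need not
add with the residual to exactly one; that non-additivity is deliberate
(the two quantities are reported separately in the kind of QC figure this
reproduces).  Plain R² carries an upward finite-sample bias of roughly
k/(n−1) per PC (≈ 0.05 for the biological design at n = 60), well inside
the ±0.1 recovery tolerance used in validation; a nested slide-in-tissue
design is flagged as confounded.

## Niche classification

The immune-hot/cold rule is this package's own operationalization of a
qualitative dichotomy, with explicit stored thresholds: *hot* = immune cell
fraction ≥ 0.30 AND checkpoint score above the reference-group mean;
*cold* = fraction ≤ 0.20 AND score at or below it; otherwise
*indeterminate* with a reason.  The thresholds bracket the observed group
range (≈ 0.15–0.46) with a deliberate gap so borderline groups are not
forced into a call.  The call is a pure function of its stored inputs.

## The synthetic-data generator

The generator emulates the study's statistical structure, not its biology:

* **Design.**  3/9/8/4 patients per group; desk scale is 500 cells/patient
  and a 2,000-gene panel (≈ seconds per simulation, config-scalable to the
  published 81,676 cells).  Both published EuE totals (10,806 and 24,440)
  are exposed as constants; the per-group totals used for arithmetic checks
  are the set consistent with the positive-cell denominators, which sum to
  81,676.
* **Background counts.**  Negative binomial via gamma–Poisson with shared
  dispersion 0.5 and gene means log-uniform on [0.05, 5] — overdispersed
  scRNA-seq-like counts without per-gene fitting.
* **Sparse genes.**  Per-cell Bernoulli expressor indicators with per-group
  fractions (CCL19-like: 0.25/0.5/1.61/0.06%; NNMT-like: 29/20.5/23.9/24.6%)
  and lognormal intensities among expressors.  Counts are `ceil` of the
  lognormal draw; since rounding up inflates a geometric mean, the lognormal
  scale is calibrated numerically so that the *post-discretization*
  geometric mean equals the configured intensity — the planted 7.6×
  EcP/Ctrl intensity ratio is then recovered without bias.
* **Programs.**  Multiplicative group shifts: smooth muscle +3 log₂ in EcO;
  checkpoints +2 and cytotoxicity +2 in EcP; hormone receptors −1 in EcP and
  −2.5 in EcO; ECM +1 in EuE; immune markers +1.5 in EcP; and cytotoxicity
  −1 / checkpoints −0.5 in EcO, reflecting that immune activity is lowest in
  the ovarian lesions.  Cell-type proportions are fixed per group so the
  immune aggregates come out at 23.9/33.9/46.3/15.3%.
* **QC structure.**  5% of cells are "low quality": counts binomially
  thinned to 15% and mitochondrial fractions drawn high, so the standard
  thresholds remove them; metrics (`n_umi`, `n_genes_detected`) are computed
  from the final matrix, so `n_umi ≥ n_genes_detected` holds by
  construction.
* **Segments.**  60 segments (30 per tissue × 3 compartments, slides
  24/24/12 crossing tissue).  Gene profiles carry additive tissue +
  compartment effects, a slide effect, segment noise, and a per-segment
  lognormal technical depth factor (sd 0.3) — the nuisance Q3 normalization
  exists to remove.  Ligand–receptor pairs follow a Gaussian copula with
  Pearson parameter `2 sin(πρ_s/6)` so the latent Spearman is exact; LR
  genes sit at fixed high abundance (mean 150) so Poisson noise barely
  perturbs ranks, and the immune-content factor loads the six immune markers
  and, via the configured loading, the LR genes — the planted confounder the
  partial correlation must remove.  At panels of ≥ 300 genes the observed
  Spearman tracks the latent target to within ≈ 0.02.
* **Variance planting.**  `planted_variance_segments` builds continuous
  profiles from mutually orthogonalized unit-variance components weighted by
  the target fractions (default 60.9% biology, 12.3% batch), giving exact
  ground truth for the variance-partition estimator.

What the generator does **not** emulate: doublets, spliced/unspliced counts,
gene–gene covariance beyond the configured programs, cell-type-specific
expression of the named genes (program shifts act on whole groups), batch
effects in the single-cell data, or spatial autocorrelation within slides.
Passing tests therefore demonstrate that the estimators recover the
parameters of *this* model at the stated sizes — calibration, power and
bias properties that are necessary, not sufficient, for real data.

## Problem sizes used in validation

Null calibration uses 2,500 null sparse genes (4,000 cells), 10,000
two-proportion replicates, and 2,000 null NB genes at 4 vs 4 samples;
recovery uses 250 planted genes inside a 2,000-gene panel at 8 vs 4;
confounder-removal and screen-power checks use 200 seeded replicates of the
60-segment design; variance recovery uses 60 segments × 200 genes.  These
sizes keep each check to seconds-to-minutes while leaving the Monte-Carlo
error small relative to the acceptance bands.

## Known limitations

* The NB dispersion is per-gene moment-based: fine for calibration, noisy
  for ranking borderline genes; DESeq2-style shrinkage would differ gene by
  gene, so published log₂FC values are approximate references only.
* Cell-level scores ignore gene-length/depth biases beyond the single
  normalization; no control-gene background correction is applied (the
  plain mean is the specified statistic).
* The pathway gene sets beyond the four printed signatures are small,
  non-authoritative defaults; users with curated GMTs should load them via
  `read_gmt`.
* `two_step_sparse_test` trusts `obs["n_umi"]` as the cell totals when
  present (exact for matrices produced by this package's QC/normalization
  path); callers supplying hand-edited metadata should drop the column to
  force recomputation.
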