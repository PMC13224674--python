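# nichecompare

Comparative single-cell + spatial transcriptomics of endometriosis lesion
niches — a tested, reusable implementation of the statistical pipeline behind
the "immune-hot peritoneal / immune-cold ovarian" dichotomy, exercised
end-to-end on synthetic data that emulates the study's structure.

## The problem

Endometriosis lesions fall into two major subtypes with sharply different
microenvironments: peritoneal lesions (EcP) are immune-rich and organized
around a CCL19–CCR7 chemokine axis, while ovarian lesions (EcO) are
immune-sparse and fibromuscular.  Comparing them against control endometrium
(Ctrl) and patients' eutopic endometrium (EuE) raises several recurring
statistical problems that this package solves as a library:

* **Sparse-gene differential testing.**  A chemokine expressed in < 2% of
  cells is invisible to bulk cell-level comparisons diluted by zeros.  The
  two-step test separates the *frequency* of expressing cells from the
  *intensity* among expressors:

  - step (i): expressing fractions `p₁ = k₁/n₁`, `p₂ = k₂/n₂` compared with
    the pooled two-proportion z-test,
    `z = (p₁ − p₂) / √(p̄(1−p̄)(1/n₁ + 1/n₂))`;
  - step (ii): geometric means `exp(mean(ln x))` of relative expression among
    expressors only, compared with Welch's t-test on log values
    (Welch–Satterthwaite df).  The two p-values are reported separately and
    BH-adjusted as separate families.

* **Patient-level pseudo-bulk DE.**  Cell-level tests pseudo-replicate; counts
  are summed per patient–tissue sample (3/9/8/4 patients per group → 24
  samples), filtered (count ≥ 10 in ≥ 3 samples), normalized with
  median-of-ratios size factors, and tested per gene with an explicit
  negative-binomial Wald GLM (log link, `offset = ln s_j`, moment-estimated
  dispersion, t reference with n − 2 df).  Significance: |log₂FC| > 1 and
  BH q < 0.05.

* **Spatial co-expression with composition adjustment.**  GeoMx-style
  segments (two tissues × three sorted compartments, slides of 24/24/12) are
  Q3-normalized (each segment scaled by its 75th percentile of positive
  counts toward the geometric-mean target).  Ligand–receptor pairs are
  screened by Spearman ρ > 0.7 with BH q < 0.001 across segments, and
  re-tested with a first-order partial Spearman correlation
  `ρ_xy·z = (ρ_xy − ρ_xz ρ_yz)/√((1−ρ_xz²)(1−ρ_yz²))`
  controlling a composite immune score — the check that "co-expression" is
  not just shared immune content.

* **Scores, modules, variance.**  Gene-set activity as the plain mean of
  log-normalized expression (cytotoxicity {GZMB, PRF1, GNLY}; exhaustion
  {CTLA4, PDCD1, LAG3, HAVCR2, TIGIT}; smooth muscle {MYH11, ACTA2, DES,
  TAGLN}; segment immune {CD68, CD3D, CD3E, PTPRC, CD4, CD8A}), rank-based
  ROC AUC, complete-linkage co-expression modules, and a PCA-based
  variance partition of biology (tissue + compartment) versus slide batch.

* **Niche classification.**  An explicit, reproducible operationalization of
  the hot/cold dichotomy: immune-hot needs immune fraction ≥ 0.30 *and*
  checkpoint score above the reference-group mean; immune-cold needs ≤ 0.20
  and at-or-below; anything else is indeterminate.

A first-class synthetic-data module (`simulate_cells`, `simulate_segments`,
`planted_variance_segments`) generates data with exactly this structure plus
a ground-truth table, so every estimator is validated by parameter recovery.

The intended users are computational biologists who want these pieces as
composable, tested functions on `AnnData`/`pandas` containers rather than a
monolithic pipeline.

## Worked example

```python
import nichecompare as nc

cells, truth = nc.simulate_cells(nc.SimConfig(cells_per_patient=1500), seed=7)
kept, _ = nc.qc_filter_cells(cells)            # <500 genes, <1000 UMI, >25% mito
norm = nc.lognormalize(kept)
table = nc.sparse_test_table(norm, ["CCL19"], [("EcP", "Ctrl")])
print(table[["frac1", "frac2", "z", "p_frac", "intensity_ratio", "p_intensity"]])
```

prints (seed 7):

```
 frac1  frac2       z  p_frac  intensity_ratio  p_intensity
0.0184 0.0022  7.6117  0.0000           9.9763       0.0000
```

i.e. 1.84% of peritoneal-lesion cells express the chemokine versus 0.22% of
control cells (planted: 1.61% vs 0.25%), a difference the proportion z-test
calls at p ≈ 10⁻¹⁴, and among expressing cells the geometric-mean intensity
is ~10× higher (planted 7.6×; the estimate is noisy with ~20 control
expressors).  The `examples/` directory walks through each capability the
same way: simulation + QC, the sparse-gene test, pseudo-bulk DE, spatial
co-expression with partial correlation, and niche classification.

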