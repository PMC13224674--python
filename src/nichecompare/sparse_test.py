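"""Two-step differential test for genes expressed in a small fraction of cells.

For a sparse gene, a bulk comparison of all cells is dominated by the zeros.
The two-step procedure separates the two ways such a gene can differ between
groups: (i) the *frequency* of expressing cells (count > 0), compared with a
pooled two-proportion z-test, and (ii) the *intensity* of expression among
expressing cells only, compared as geometric means via Welch's t-test on the
log values.  The two p-values are reported separately and never combined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sc_core import _counts, two_proportion_ztest


def geometric_mean_positive(values: np.ndarray) -> float:
    """exp of the mean natural log; values must be strictly positive."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("geometric mean of an empty sample is undefined")
    if (values <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def welch_t_log(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's t-test on natural-log values; returns (t, Welch df, two-sided p).

    Both samples need n >= 2 and positive values.  Two zero-variance samples
    with equal means give (t=0, p=1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("values must be positive before logging")
    lx, ly = np.log(x), np.log(y)
    vx, vy = lx.var(ddof=1), ly.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(lx.mean(), ly.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.inf if lx.mean() > ly.mean() else -math.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(lx, ly, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class SparseGeneResult:
    """One gene x one group comparison from the two-step test."""

    gene: str
    group_a: str
    group_b: str
    k1: int
    n1: int
    k2: int
    n2: int
    frac1: float
    frac2: float
    z: float
    p_frac: float
    geomean1: float = float("nan")
    geomean2: float = float("nan")
    intensity_ratio: float = float("nan")
    t: float = float("nan")
    df: float = float("nan")
    p_intensity: float = float("nan")
    intensity_evaluable: bool = False
    q_frac: float = float("nan")
    q_intensity: float = float("nan")


def two_step_sparse_test(
    adata: ad.AnnData, gene: str, group_a: str, group_b: str
) -> SparseGeneResult:
    """Run both steps for one gene between two groups.

    Positivity is evaluated on raw counts (``layers["counts"]`` when present,
    else ``X``).  Intensity is evaluated on *linear* relative expression —
    count over cell total — so the ratio of geometric means is a fold change
    and the Welch test logs each value exactly once; the normalization scale
    cancels from both statistics.  With fewer than two expressors on either
    side, step (ii) is marked not evaluable and step (i) is still returned.
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    j = adata.var_names.get_loc(gene)
    groups = adata.obs["group"].to_numpy()
    raw = _counts(adata)
    if "n_umi" in adata.obs:  # the raw cell totals, avoids a full resum per gene
        totals = adata.obs["n_umi"].to_numpy().astype(float)
    else:
        totals = np.asarray(raw.sum(axis=1)).ravel().astype(float)
    counts = raw[:, j]
    counts = np.asarray(counts.todense()).ravel() if sp.issparse(counts) else np.asarray(counts).ravel()
    norm = np.divide(counts, totals, out=np.zeros_like(totals), where=totals > 0)

    idx_a = np.flatnonzero(groups == group_a)
    idx_b = np.flatnonzero(groups == group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both groups must be non-empty")

    pos_a = counts[idx_a] > 0
    pos_b = counts[idx_b] > 0
    k1, n1 = int(pos_a.sum()), idx_a.size
    k2, n2 = int(pos_b.sum()), idx_b.size
    z, p_frac = two_proportion_ztest(k1, n1, k2, n2)
    res = SparseGeneResult(
        gene=gene, group_a=group_a, group_b=group_b,
        k1=k1, n1=n1, k2=k2, n2=n2,
        frac1=k1 / n1, frac2=k2 / n2, z=z, p_frac=p_frac,
    )
    if k1 >= 2 and k2 >= 2:
        xa = norm[idx_a][pos_a]
        xb = norm[idx_b][pos_b]
        res.geomean1 = geometric_mean_positive(xa)
        res.geomean2 = geometric_mean_positive(xb)
        res.intensity_ratio = res.geomean1 / res.geomean2
        res.t, res.df, res.p_intensity = welch_t_log(xa, xb)
        res.intensity_evaluable = True
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sparse_test_table(
    adata: ad.AnnData,
    genes: list[str],
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Two-step results for several genes and group comparisons.

    The fraction and intensity p-values are BH-adjusted as two separate
    families across all gene x comparison rows.
    """
    rows = [
        two_step_sparse_test(adata, g, a, b) for g in genes for a, b in comparisons
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["q_frac"] = bh_adjust(df["p_frac"].to_numpy())
    ev = df["intensity_evaluable"].to_numpy()
    if ev.any():
        q = np.full(len(df), np.nan)
        q[ev] = bh_adjust(df.loc[ev, "p_intensity"].to_numpy())
        df["q_intensity"] = q
    if (~ev).any():
        warnings.warn(
            f"{int((~ev).sum())} comparisons had <2 expressors on one side; "
            "intensity step not evaluable"
        )
    return df
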