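"""Cell-level QC, normalization, composition tables, and positive-cell statistics.

Cells live in an :class:`anndata.AnnData` with raw integer counts in ``X``
(or in ``layers["counts"]`` after normalization) and per-cell metadata columns
``group``, ``patient``, ``cell_type``, ``n_genes_detected``, ``n_umi`` and
``mito_fraction``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy import stats

from .simulate import IMMUNE_CELL_TYPES

QC_FIELDS = ("n_genes_detected", "n_umi", "mito_fraction")


class SchemaError(ValueError):
    """Raised when required metadata columns are missing."""


@dataclass(frozen=True)
class QCThresholds:
    """Cell QC cut-offs; removal is strict (a cell *at* a threshold is kept)."""

    min_genes: int = 500
    min_umi: int = 1000
    max_mito: float = 0.25

    def __post_init__(self):
        if self.min_genes <= 0 or self.min_umi <= 0:
            raise ValueError("min_genes and min_umi must be positive")
        if not 0.0 < self.max_mito <= 1.0:
            raise ValueError("max_mito must lie in (0, 1]")


def _counts(adata: ad.AnnData):
    """Raw counts: ``layers['counts']`` when present, else ``X``."""
    return adata.layers["counts"] if "counts" in adata.layers else adata.X


def qc_filter_cells(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, dict[str, int]]:
    """Remove cells below the gene/UMI floors or above the mitochondrial cap.

    Returns the filtered matrix (a column subset of the input, cell order
    preserved) and a report counting removals per criterion; criterion counts
    overlap, ``removed_total`` does not.
    """
    thresholds = thresholds or QCThresholds()
    missing = [f for f in QC_FIELDS if f not in adata.obs]
    if missing:
        raise SchemaError(f"missing QC metadata fields: {missing}")
    genes_ok = adata.obs["n_genes_detected"].to_numpy() >= thresholds.min_genes
    umi_ok = adata.obs["n_umi"].to_numpy() >= thresholds.min_umi
    mito_ok = adata.obs["mito_fraction"].to_numpy() <= thresholds.max_mito
    keep = genes_ok & umi_ok & mito_ok
    report = {
        "n_input": int(adata.n_obs),
        "removed_low_genes": int((~genes_ok).sum()),
        "removed_low_umi": int((~umi_ok).sum()),
        "removed_high_mito": int((~mito_ok).sum()),
        "removed_total": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    return adata[keep].copy(), report


def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log(1 + scale * count / cell_total) per entry.

    Raw counts are preserved in ``layers["counts"]``.  Cells with zero total
    get an all-zero column and a warning.
    """
    X = _counts(adata)
    if sp.issparse(X):
        if (X.data < 0).any():
            raise ValueError("negative counts")
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        if (X < 0).any():
            raise ValueError("negative counts")
        totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero total counts")
    safe = np.where(zero, 1.0, totals)
    out = adata.copy()
    if sp.issparse(X):
        norm = X.tocsr().astype(float)
        row_of_data = np.repeat(np.arange(norm.shape[0]), np.diff(norm.indptr))
        norm.data = np.log1p(scale * norm.data / safe[row_of_data])
    else:
        norm = np.log1p(scale * X / safe[:, None])
    out.layers["counts"] = X.copy()
    out.X = norm
    return out


def composition_table(adata: ad.AnnData, by: str = "group") -> pd.DataFrame:
    """Per-group cell-type fractions plus an ``immune`` aggregate column.

    The immune aggregate sums T cells, macrophages, B cells and NK cells
    (whichever are labelled).  Rows sum to one; empty groups are omitted
    with a warning.
    """
    if "cell_type" not in adata.obs:
        raise SchemaError("cell_type labels required")
    tab = pd.crosstab(adata.obs[by], adata.obs["cell_type"])
    empty = tab.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"empty groups omitted: {list(tab.index[empty])}")
        tab = tab.loc[~empty]
    frac = tab.div(tab.sum(axis=1), axis=0)
    immune_cols = [c for c in frac.columns if c in IMMUNE_CELL_TYPES]
    frac["immune"] = frac[immune_cols].sum(axis=1)
    return frac


def positive_cell_proportions(adata: ad.AnnData, gene: str) -> pd.DataFrame:
    """Fraction of cells with raw count > 0 for ``gene``, per group."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    X = _counts(adata)
    col = X[:, adata.var_names.get_loc(gene)]
    positive = (
        np.asarray((col > 0).todense()).ravel() if sp.issparse(col) else np.asarray(col > 0).ravel()
    )
    rows = []
    for group, idx in adata.obs.groupby("group", observed=True).indices.items():
        k = int(positive[idx].sum())
        n = int(len(idx))
        rows.append({"group": group, "k_positive": k, "n_total": n, "fraction": k / n})
    return pd.DataFrame(rows).set_index("group")


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test, two-sided.

    z is antisymmetric under swapping the samples; the degenerate case (both
    proportions 0 or both 1) returns (0, 1).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n and n >= 1")
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(p_pool * (1.0 - p_pool) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(max(p, np.finfo(float).tiny))


def fold_enrichment(p1: float, p2: float) -> float:
    """Ratio p1 / p2 of two fractions; NaN with a warning when p2 is zero."""
    if p2 == 0:
        warnings.warn("reference proportion is zero; fold enrichment undefined")
        return float("nan")
    return p1 / p2


def per_patient_frequencies(adata: ad.AnnData, gene: str) -> dict[str, dict]:
    """Per-patient positive-cell fractions, summarized per group.

    Returns, per group, the patient-level fractions plus their mean, sample
    SD (ddof=1; NaN for a single patient), and range.
    """
    if "patient" not in adata.obs:
        raise SchemaError("patient IDs required")
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    X = _counts(adata)
    col = X[:, adata.var_names.get_loc(gene)]
    positive = (
        np.asarray((col > 0).todense()).ravel() if sp.issparse(col) else np.asarray(col > 0).ravel()
    )
    out: dict[str, dict] = {}
    obs = adata.obs
    for group, gidx in obs.groupby("group", observed=True).indices.items():
        fractions = {}
        sub = obs.iloc[gidx]
        for patient, pidx in sub.groupby("patient", observed=True).indices.items():
            cells = gidx[pidx] if isinstance(pidx, np.ndarray) else gidx[list(pidx)]
            if len(cells) == 0:
                warnings.warn(f"patient {patient} has no cells; excluded")
                continue
            fractions[patient] = float(positive[cells].mean())
        vals = np.asarray(list(fractions.values()))
        out[str(group)] = {
            "per_patient": fractions,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out
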