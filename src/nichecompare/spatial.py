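"""Segment-level spatial analysis: QC, Q3 normalization, co-expression.

Segments (GeoMx-style regions of interest, sorted into Macrophage /
Epithelium / Stroma compartments) live in an :class:`anndata.AnnData`
(segments x genes) with ``tissue``, ``compartment`` and ``slide`` metadata.
The co-expression machinery is rank-based throughout: Spearman gene-gene
correlation, a ligand-receptor screen at rho > 0.7 and BH q < 0.001, and a
first-order partial Spearman correlation that removes the contribution of a
composite immune score from a ligand-receptor association.
"""

from __future__ import annotations

import itertools
import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .genescores import SEGMENT_IMMUNE, geneset_score
from .sc_core import _counts
from .sparse_test import bh_adjust


def detection_rates(adata: ad.AnnData) -> np.ndarray:
    """Per-segment fraction of panel genes with count > 0."""
    X = _counts(adata)
    if sp.issparse(X):
        return np.asarray((X > 0).mean(axis=1)).ravel()
    return (np.asarray(X) > 0).mean(axis=1)


def qc_filter_segments(adata: ad.AnnData, min_detection: float = 0.30) -> ad.AnnData:
    """Keep segments whose gene detection rate strictly exceeds the cut-off."""
    rates = detection_rates(adata)
    keep = rates > min_detection
    out = adata[keep].copy()
    out.obs["detection_rate"] = rates[keep]
    return out


def q3_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Scale each segment by its 75th percentile of positive counts.

    The common target is the geometric mean of all segment Q3s, so the
    post-normalization Q3 is identical across segments and re-running the
    normalization is a no-op.  Segments with zero Q3 are dropped with a
    warning.  Raw counts are kept in ``layers["counts"]``.
    """
    X = _counts(adata)
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    q3 = np.zeros(dense.shape[0])
    for i in range(dense.shape[0]):
        pos = dense[i][dense[i] > 0]
        q3[i] = np.percentile(pos, 75) if pos.size else 0.0
    ok = q3 > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} segments with zero Q3 excluded")
    target = np.exp(np.mean(np.log(q3[ok])))
    out = adata[ok].copy()
    sub = dense[ok]
    out.layers["counts"] = sub.copy()
    out.X = sub * (target / q3[ok])[:, None]
    out.obs["q3"] = q3[ok]
    return out


def log_segments(adata: ad.AnnData) -> ad.AnnData:
    """log1p of the (Q3-normalized) segment expression, for scoring."""
    out = adata.copy()
    X = out.X
    out.X = np.log1p(np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X))
    return out


def harmonize_genes(
    cells: ad.AnnData,
    segments: ad.AnnData,
    min_count: int = 5,
    min_frac: float = 0.10,
) -> list[str]:
    """Genes detected consistently on both platforms.

    A gene qualifies in a dataset when strictly more than ``min_frac`` of its
    units have strictly more than ``min_count`` counts; the result is the
    sorted intersection of qualifying gene symbols.
    """

    def qualifying(adata: ad.AnnData) -> set[str]:
        X = _counts(adata)
        if sp.issparse(X):
            n_pass = np.asarray((X > min_count).sum(axis=0)).ravel()
        else:
            n_pass = (np.asarray(X) > min_count).sum(axis=0)
        # integer unit counts keep the strict boundary exact
        return set(np.asarray(adata.var_names)[n_pass > min_frac * adata.n_obs])

    shared = qualifying(cells) & qualifying(segments)
    if not shared:
        raise ValueError("no genes pass the harmonization filter in both datasets")
    return sorted(shared)


def spearman_matrix(
    adata: ad.AnnData, genes: list[str], subset: np.ndarray | None = None
) -> pd.DataFrame:
    """Spearman correlation for every gene pair across segments.

    Average-rank ties, two-sided p via the t approximation, BH adjustment
    over the tested family.  ``subset`` restricts to a boolean segment mask
    (e.g. stroma-only).  Constant genes yield flagged NaN records.
    """
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    idx = [adata.var_names.get_loc(g) for g in genes]
    X = adata.X
    M = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    M = M[:, idx]
    if subset is not None:
        M = M[np.asarray(subset, dtype=bool)]
    n = M.shape[0]
    if n < 3:
        raise ValueError("need at least 3 segments")
    constant = M.std(axis=0) == 0
    rho, pval = stats.spearmanr(M)
    if len(genes) == 2:  # spearmanr returns scalars for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    rows = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        flagged = bool(constant[i] or constant[j])
        rows.append(
            {
                "gene_a": genes[i],
                "gene_b": genes[j],
                "rho": np.nan if flagged else float(rho[i, j]),
                "p": np.nan if flagged else float(pval[i, j]),
                "n": n,
                "constant_input": flagged,
            }
        )
    df = pd.DataFrame(rows)
    valid = df["p"].notna().to_numpy()
    q = np.full(len(df), np.nan)
    if valid.any():
        q[valid] = bh_adjust(df.loc[valid, "p"].to_numpy())
    df["q"] = q
    return df


def ligand_receptor_screen(
    records: pd.DataFrame,
    pairs: list[tuple[str, str]],
    rho_threshold: float = 0.7,
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """Apply the co-expression screen (rho > threshold AND q < threshold).

    ``records`` is a :func:`spearman_matrix` table; unknown pair members are
    skipped with a warning.
    """
    key = {}
    for row in records.itertuples(index=False):
        key[frozenset((row.gene_a, row.gene_b))] = row
    rows = []
    for ligand, receptor in pairs:
        rec = key.get(frozenset((ligand, receptor)))
        if rec is None:
            warnings.warn(f"pair {ligand}-{receptor} not among tested genes; skipped")
            continue
        passes = bool(
            np.isfinite(rec.rho)
            and np.isfinite(rec.q)
            and rec.rho > rho_threshold
            and rec.q < q_threshold
        )
        rows.append(
            {
                "ligand": ligand,
                "receptor": receptor,
                "rho": rec.rho,
                "p": rec.p,
                "q": rec.q,
                "n": rec.n,
                "passes_screen": passes,
            }
        )
    return pd.DataFrame(rows)


def immune_score_segments(adata: ad.AnnData) -> np.ndarray:
    """Composite immune score: mean log expression of the immune markers."""
    return geneset_score(adata, SEGMENT_IMMUNE)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """First-order partial Spearman correlation of x and y given z.

    All three vectors are rank-transformed (average ranks); the partial
    correlation is (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) with a
    two-sided p from the t distribution on n - 3 degrees of freedom.  A
    covariate perfectly correlated with either variable leaves the quantity
    undefined: (NaN, NaN) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == n and len(z) == n):
        raise ValueError("inputs must have equal length")
    if n < 4:
        raise ValueError("need n >= 4")
    if x.std() == 0 or y.std() == 0 or z.std() == 0:
        raise ValueError("inputs must be non-constant")
    rx, ry, rz = stats.rankdata(x), stats.rankdata(y), stats.rankdata(z)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-12:  # covariate (numerically) collinear with x or y
        warnings.warn("covariate collinear with an input; partial correlation undefined")
        return float("nan"), float("nan")
    pr = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    pr = float(np.clip(pr, -1.0, 1.0))
    if abs(pr) == 1.0:
        return pr, 0.0
    t = pr * np.sqrt((n - 3) / (1.0 - pr**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return pr, float(p)


def coexpression_modules(adata: ad.AnnData, genes: list[str], k: int = 3) -> pd.Series:
    """Complete-linkage hierarchical co-expression modules.

    Genes' expression profiles are standardized over segments, clustered
    agglomeratively on Euclidean distance, and the tree is cut into ``k``
    modules.  Genes are processed in lexicographic order and modules are
    renumbered by first appearance, so the assignment is deterministic and
    input-order invariant.
    """
    if k > len(genes):
        raise ValueError("k cannot exceed the number of genes")
    genes_sorted = sorted(genes)
    idx = [adata.var_names.get_loc(g) for g in genes_sorted]
    X = adata.X
    M = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    M = M[:, idx].T  # genes x segments
    sd = M.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    M = (M - M.mean(axis=1, keepdims=True)) / sd
    Z = linkage(M, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=genes_sorted, name="module")


def variance_partition(adata: ad.AnnData) -> dict[str, float]:
    """Share of expression variance explained by biology versus batch.

    PCA on gene-standardized profiles over segments; each principal
    component's score is regressed on tissue + compartment (biological) and,
    separately, on slide (batch); the reported fraction is the
    variance-weighted sum of the R-squares.  The two fractions come from
    separate regressions and need not sum with the residual to exactly one.
    """
    for col in ("tissue", "compartment", "slide"):
        if col not in adata.obs:
            raise ValueError(f"missing segment metadata column {col!r}")
        if adata.obs[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    nested = (
        adata.obs.groupby("slide", observed=True)["tissue"].nunique().max() == 1
    )
    if nested:
        warnings.warn("slide is nested in tissue; fractions are confounded")
    X = adata.X
    M = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    sd = M.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    M = (M - M.mean(axis=0, keepdims=True)) / sd
    n_comp = min(M.shape[0] - 1, M.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(M)
    weights = pca.explained_variance_ratio_
    weights = weights / weights.sum()

    def design(cols: list[str]) -> np.ndarray:
        d = pd.get_dummies(adata.obs[cols].astype(str), drop_first=True)
        return np.column_stack([np.ones(adata.n_obs), d.to_numpy(dtype=float)])

    def weighted_r2(D: np.ndarray) -> float:
        total = 0.0
        for i in range(scores.shape[1]):
            y = scores[:, i]
            coef, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ coef
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
            total += weights[i] * r2
        return float(total)

    bio = weighted_r2(design(["tissue", "compartment"]))
    batch = weighted_r2(design(["slide"]))
    return {
        "biological_fraction": bio,
        "batch_fraction": batch,
        "residual": float(max(0.0, 1.0 - bio - batch)),
    }
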