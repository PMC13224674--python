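"""Gene-set activity scores, group summaries, and ROC AUC.

A set's activity in a cell or segment is the plain (unweighted) mean of the
log-normalized expression of its member genes — no control-pool background
correction.  Ships the published marker signatures; the broader pathway sets
are small defaults built from genes the analysis works with and are not an
authoritative curation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt
from scipy import sparse as sp
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set members must be unique")


#: Published marker signatures.
SMOOTH_MUSCLE = GeneSet("smooth_muscle", ("MYH11", "ACTA2", "DES", "TAGLN"))
CYTOTOXICITY = GeneSet("cytotoxicity", ("GZMB", "PRF1", "GNLY"))
EXHAUSTION = GeneSet("exhaustion", ("CTLA4", "PDCD1", "LAG3", "HAVCR2", "TIGIT"))
SEGMENT_IMMUNE = GeneSet("segment_immune", ("CD68", "CD3D", "CD3E", "PTPRC", "CD4", "CD8A"))

#: Non-authoritative small pathway defaults for network construction.
DEFAULT_PATHWAYS: dict[str, GeneSet] = {
    s.name: s
    for s in (
        SMOOTH_MUSCLE,
        CYTOTOXICITY,
        EXHAUSTION,
        GeneSet("immune_response", ("CCL19", "CCR7", "PTPRC", "CD3D")),
        GeneSet("hormone_response", ("ESR1", "PGR")),
        GeneSet("ecm_organization", ("COL1A1", "COL3A1", "FN1")),
        GeneSet("tgfb_signaling", ("TGFB1", "TGFBR1")),
    )
}


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file."""
    raw = _gseapy_read_gmt(str(path))
    return [GeneSet(name, tuple(dict.fromkeys(genes))) for name, genes in raw.items()]


def geneset_score(adata: ad.AnnData, gene_set: GeneSet) -> np.ndarray:
    """Mean expression of the set's genes per unit (cell or segment).

    Operates on whatever is in ``X`` — pass log-normalized data.  Missing
    genes are dropped with a warning; a set with no present gene is an error.
    """
    present = [g for g in gene_set.genes if g in adata.var_names]
    if not present:
        raise KeyError(f"no gene of set {gene_set.name!r} present in matrix")
    missing = set(gene_set.genes) - set(present)
    if missing:
        warnings.warn(f"set {gene_set.name!r}: missing genes dropped: {sorted(missing)}")
    idx = [adata.var_names.get_loc(g) for g in present]
    X = adata.X[:, idx]
    if sp.issparse(X):
        return np.asarray(X.mean(axis=1)).ravel()
    return np.asarray(X).mean(axis=1)


def group_score_summary(scores: np.ndarray, groups) -> pd.DataFrame:
    """Per-group mean, SD, median and IQR of a score vector."""
    scores = np.asarray(scores, dtype=float)
    groups = pd.Series(np.asarray(groups), name="group")
    if len(scores) != len(groups):
        raise ValueError("scores and group labels must align")
    df = pd.DataFrame({"score": scores, "group": groups.to_numpy()})
    counts = df.groupby("group", observed=True)["score"].count()
    empty = counts[counts == 0]
    if len(empty):
        warnings.warn(f"empty groups omitted: {list(empty.index)}")
    out = df.groupby("group", observed=True)["score"].agg(
        mean="mean",
        sd=lambda s: s.std(ddof=1),
        median="median",
        iqr=lambda s: s.quantile(0.75) - s.quantile(0.25),
    )
    return out


def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney; ties count one half).

    ``labels`` are binary; the AUC is the probability that a random positive
    unit scores above a random negative one.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    ranks = stats.rankdata(values)
    r_pos = ranks[labels].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
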