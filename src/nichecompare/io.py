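"""Plain-text readers and writers for the simulated datasets.

Cell matrices travel as Matrix-Market (genes x cells) plus ``genes.tsv`` and
``cells.tsv``; segment matrices as ``counts.csv`` (genes x segments) plus
``segments.tsv``; truth tables as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse as sp

from .simulate import TruthTable


def write_cells(adata: ad.AnnData, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csc_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.DataFrame(index=adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", header=False
    )
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    return outdir


def read_cells(indir) -> ad.AnnData:
    indir = Path(indir)
    mat = scio.mmread(indir / "matrix.mtx").tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    return ad.AnnData(X=mat.T.tocsr(), obs=obs, var=pd.DataFrame(index=genes))


def write_segments(adata: ad.AnnData, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    pd.DataFrame(dense.T, index=adata.var_names, columns=adata.obs_names).to_csv(
        outdir / "counts.csv"
    )
    adata.obs.to_csv(outdir / "segments.tsv", sep="\t")
    return outdir


def read_segments(indir) -> ad.AnnData:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.csv", index_col=0)
    obs = pd.read_csv(indir / "segments.tsv", sep="\t", index_col=0)
    return ad.AnnData(
        X=counts.T.to_numpy(), obs=obs, var=pd.DataFrame(index=counts.index)
    )


def write_truth(truth: TruthTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return path


def read_truth(path) -> TruthTable:
    data = json.loads(Path(path).read_text())
    return TruthTable(**data)
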