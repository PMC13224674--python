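import anndata as ad
import numpy as np
import pandas as pd
import pytest

import nichecompare as nc


@pytest.fixture(scope="session")
def default_cells():
    """Desk-scale study: 24 patients (3/9/8/4), 500 cells each, 2,000 genes."""
    cells, truth = nc.simulate_cells(nc.SimConfig(), seed=7)
    return cells, truth


@pytest.fixture(scope="session")
def cells_norm(default_cells):
    cells, truth = default_cells
    kept, _ = nc.qc_filter_cells(cells)
    return nc.lognormalize(kept), truth


@pytest.fixture(scope="session")
def default_segments():
    """60-segment spatial design on a 400-gene panel."""
    segs, truth = nc.simulate_segments(nc.SimConfig(n_genes=400), seed=7)
    return segs, truth


def make_cells(counts, groups, patients=None, cell_types=None):
    """Small hand-built cell matrix (cells x genes) for edge-case tests."""
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "group": list(groups),
            "patient": list(patients) if patients is not None else [f"p{i}" for i in range(n)],
            "cell_type": list(cell_types) if cell_types is not None else ["T cells"] * n,
            "n_genes_detected": (counts > 0).sum(axis=1),
            "n_umi": counts.sum(axis=1),
            "mito_fraction": np.zeros(n),
        },
        index=[f"c{i}" for i in range(n)],
    )
    return ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )
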