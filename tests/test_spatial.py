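"""Segment QC, Q3 normalization, rank-based co-expression and partitioning."""

import anndata as ad
import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage

import nichecompare as nc


def _segs(values, genes=None, meta=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    obs = meta if meta is not None else pd.DataFrame(
        {
            "tissue": ["EuE"] * (n // 2) + ["EcP"] * (n - n // 2),
            "compartment": (["Stroma", "Epithelium", "Macrophages"] * n)[:n],
            "slide": (["S1", "S2"] * n)[:n],
        },
        index=[f"seg{i}" for i in range(n)],
    )
    return ad.AnnData(
        X=values,
        obs=obs,
        var=pd.DataFrame(index=genes or [f"g{j}" for j in range(g)]),
    )


class TestSegmentQC:
    def test_bruteforce_predicate_with_boundary(self):
        rng = np.random.default_rng(0)
        counts = (rng.random((20, 10)) < 0.4).astype(float) * rng.poisson(5, (20, 10))
        counts[0] = 0
        counts[1, :3] = 1
        counts[1, 3:] = 0  # exactly 30% detection: strict rule removes it
        a = _segs(counts)
        out = nc.qc_filter_segments(a, min_detection=0.30)
        rates = (counts > 0).mean(axis=1)
        assert list(out.obs_names) == [f"seg{i}" for i in range(20) if rates[i] > 0.30]

    def test_detection_rates_range(self, default_segments):
        segs, _ = default_segments
        r = nc.detection_rates(segs)
        assert ((0 <= r) & (r <= 1)).all()


class TestQ3Normalize:
    def test_single_segment_unchanged(self):
        a = _segs([[1, 2, 3, 4, 8]])
        out = nc.q3_normalize(a)
        assert np.allclose(out.X, a.X)

    def test_scaled_segments_collapse(self):
        base = np.array([1.0, 2, 3, 4, 8, 0, 5, 7])
        a = _segs(np.vstack([base, 3 * base]))
        out = nc.q3_normalize(a)
        assert np.allclose(out.X[0], out.X[1])

    def test_post_normalization_q3_equal_and_idempotent(self, default_segments):
        segs, _ = default_segments
        out = nc.q3_normalize(segs)
        q3 = [
            np.percentile(row[row > 0], 75)
            for row in np.asarray(out.X)
        ]
        assert np.allclose(q3, q3[0], rtol=1e-9)
        again = nc.q3_normalize(out)
        assert np.allclose(again.X, out.X, rtol=1e-9)

    def test_zero_q3_segment_excluded(self):
        a = _segs([[0, 0, 0], [1, 2, 3]])
        with pytest.warns(UserWarning):
            out = nc.q3_normalize(a)
        assert out.n_obs == 1


class TestHarmonize:
    def test_boundary_and_bruteforce(self, default_cells, default_segments):
        cells, _ = default_cells
        segs, _ = default_segments
        sub_c = cells[:800].copy()
        shared = nc.harmonize_genes(sub_c, segs, min_count=5, min_frac=0.10)
        Xc = np.asarray(sub_c.X.todense())
        Xs = np.asarray(segs.X)
        brute = sorted(
            set(
                g
                for i, g in enumerate(sub_c.var_names)
                if (Xc[:, i] > 5).sum() > 0.10 * len(Xc)
            )
            & set(
                g
                for i, g in enumerate(segs.var_names)
                if (Xs[:, i] > 5).sum() > 0.10 * len(Xs)
            )
        )
        assert shared == brute

    def test_boundary_count_excluded(self):
        # all units at exactly min_count: strict inequality excludes the gene
        cells = _segs(np.full((10, 1), 5.0), genes=["X1"])
        segs = _segs(np.full((10, 1), 50.0), genes=["X1"])
        cells.obs["patient"] = "p"
        with pytest.raises(ValueError):
            nc.harmonize_genes(cells, segs)


class TestSpearmanMatrix:
    def test_identical_genes_rho_one(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=20)
        a = _segs(np.column_stack([v, v, rng.normal(size=20)]), genes=["a", "b", "c"])
        rec = nc.spearman_matrix(a, ["a", "b", "c"])
        row = rec[(rec.gene_a == "a") & (rec.gene_b == "b")].iloc[0]
        assert row.rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(25, 2))
        a1 = _segs(M, genes=["a", "b"])
        M2 = M.copy()
        M2[:, 0] = np.exp(M2[:, 0])
        a2 = _segs(M2, genes=["a", "b"])
        r1 = nc.spearman_matrix(a1, ["a", "b"]).iloc[0]
        r2 = nc.spearman_matrix(a2, ["a", "b"]).iloc[0]
        assert r1.rho == pytest.approx(r2.rho)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(10, 4))
        a = _segs(M, genes=list("abcd"))
        rec = nc.spearman_matrix(a, list("abcd"))
        for row in rec.itertuples():
            i = "abcd".index(row.gene_a)
            j = "abcd".index(row.gene_b)
            ri = stats.rankdata(M[:, i])
            rj = stats.rankdata(M[:, j])
            oracle = np.corrcoef(ri, rj)[0, 1]
            assert row.rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_gene_flagged(self):
        a = _segs(np.column_stack([np.ones(10), np.arange(10)]), genes=["c", "v"])
        rec = nc.spearman_matrix(a, ["c", "v"])
        assert rec.iloc[0].constant_input
        assert np.isnan(rec.iloc[0].rho)

    def test_subset_selector(self, default_segments):
        segs, _ = default_segments
        lg = nc.log_segments(nc.q3_normalize(segs))
        stroma = (lg.obs["compartment"] == "Stroma").to_numpy()
        rec = nc.spearman_matrix(lg, ["CCL19", "CCR7"], subset=stroma)
        assert rec.iloc[0].n == int(stroma.sum())


class TestLRScreen:
    def test_rule_application(self):
        rec = pd.DataFrame(
            [
                {"gene_a": "L1", "gene_b": "R1", "rho": 0.71, "p": 1e-5, "q": 0.01, "n": 60},
                {"gene_a": "L2", "gene_b": "R2", "rho": 0.9, "p": 1e-12, "q": 1e-10, "n": 60},
                {"gene_a": "L3", "gene_b": "R3", "rho": 0.65, "p": 1e-9, "q": 1e-8, "n": 60},
            ]
        )
        out = nc.ligand_receptor_screen(
            rec, [("L1", "R1"), ("L2", "R2"), ("L3", "R3")]
        )
        assert list(out["passes_screen"]) == [False, True, False]

    def test_unknown_pair_warns(self):
        rec = pd.DataFrame(
            [{"gene_a": "A", "gene_b": "B", "rho": 0.9, "p": 1e-9, "q": 1e-8, "n": 60}]
        )
        with pytest.warns(UserWarning):
            out = nc.ligand_receptor_screen(rec, [("X", "Y")])
        assert len(out) == 0


class TestPartialSpearman:
    def test_identical_variables(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        pr, p = nc.partial_spearman(x, x.copy(), z)
        assert pr == pytest.approx(1.0)

    def test_independent_covariate_keeps_raw_rho(self):
        rng = np.random.default_rng(6)
        n = 4000
        u = rng.normal(size=n)
        x = u + 0.5 * rng.normal(size=n)
        y = u + 0.5 * rng.normal(size=n)
        z = rng.normal(size=n)
        raw = stats.spearmanr(x, y).statistic
        pr, _ = nc.partial_spearman(x, y, z)
        assert abs(pr - raw) < 0.03

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x, y, z = rng.normal(size=(3, 30))
            pr, _ = nc.partial_spearman(x, y, z)
            rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
            D = np.column_stack([np.ones(30), rz])
            ex = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
            ey = ry - D @ np.linalg.lstsq(D, ry, rcond=None)[0]
            oracle = ex @ ey / np.sqrt((ex @ ex) * (ey @ ey))
            assert pr == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(8)
        x, y, z = rng.normal(size=(3, 40))
        pr, p = nc.partial_spearman(x, y, z)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z",
            method="spearman",
        )
        assert pr == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_degenerate_inputs(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            nc.partial_spearman(x[:3], x[:3], x[:3])
        with pytest.raises(ValueError):
            nc.partial_spearman(x, np.ones(10), x)
        with pytest.warns(UserWarning):
            pr, p = nc.partial_spearman(x, x[::-1], x)
        assert np.isnan(pr)


class TestCoexpressionModules:
    def test_two_blocks_recovered(self):
        rng = np.random.default_rng(9)
        u, v = rng.normal(size=(2, 40))
        M = np.column_stack([u, u * 2 + 1, v, v * 3 - 2])
        a = _segs(M, genes=["a1", "a2", "b1", "b2"])
        modules = nc.coexpression_modules(a, ["a1", "a2", "b1", "b2"], k=2)
        assert modules["a1"] == modules["a2"]
        assert modules["b1"] == modules["b2"]
        assert modules["a1"] != modules["b1"]

    def test_k_equals_genes_singletons(self):
        rng = np.random.default_rng(10)
        a = _segs(rng.normal(size=(20, 4)), genes=list("abcd"))
        modules = nc.coexpression_modules(a, list("abcd"), k=4)
        assert modules.nunique() == 4

    def test_input_order_invariance(self):
        rng = np.random.default_rng(11)
        genes = [f"g{j}" for j in range(6)]
        a = _segs(rng.normal(size=(25, 6)), genes=genes)
        m1 = nc.coexpression_modules(a, genes, k=3)
        m2 = nc.coexpression_modules(a, genes[::-1], k=3)
        pd.testing.assert_series_equal(m1, m2)

    def test_linkage_heights_match_bruteforce(self):
        rng = np.random.default_rng(12)
        M = rng.normal(size=(15, 6))
        a = _segs(M, genes=[f"g{j}" for j in range(6)])
        Ms = (M - M.mean(0)) / M.std(0)
        Z = linkage(Ms.T, method="complete", metric="euclidean")
        # naive agglomeration: repeatedly merge the closest pair, complete linkage
        clusters = {i: [i] for i in range(6)}
        dist = {
            (i, j): np.linalg.norm(Ms[:, i] - Ms[:, j])
            for i in range(6)
            for j in range(i + 1, 6)
        }
        heights = []
        while len(clusters) > 1:
            keys = sorted(clusters)
            best, bd = None, np.inf
            for ai in range(len(keys)):
                for bi in range(ai + 1, len(keys)):
                    ca, cb = clusters[keys[ai]], clusters[keys[bi]]
                    d = max(
                        np.linalg.norm(Ms[:, x] - Ms[:, y]) for x in ca for y in cb
                    )
                    if d < bd:
                        best, bd = (keys[ai], keys[bi]), d
            heights.append(bd)
            a_, b_ = best
            clusters[a_] = clusters[a_] + clusters.pop(b_)
        assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-10)

    def test_k_too_large_rejected(self):
        a = _segs(np.random.default_rng(13).normal(size=(10, 3)), genes=list("abc"))
        with pytest.raises(ValueError):
            nc.coexpression_modules(a, list("abc"), k=4)


class TestVariancePartition:
    def test_tissue_determined_data(self):
        meta = pd.DataFrame(
            {
                "tissue": ["EuE"] * 15 + ["EcP"] * 15,
                "compartment": ["Stroma", "Epithelium", "Macrophages"] * 10,
                "slide": ["S1", "S2", "S3"] * 10,
            },
            index=[f"s{i}" for i in range(30)],
        )
        rng = np.random.default_rng(14)
        effect = rng.normal(size=(1, 40))
        X = np.where(meta["tissue"].to_numpy()[:, None] == "EuE", effect, -effect)
        a = _segs(X, meta=meta)
        vp = nc.variance_partition(a)
        assert vp["biological_fraction"] > 0.99

    def test_pure_noise_small_fractions(self):
        a = nc.planted_variance_segments(n_genes=200, bio_frac=0.0, batch_frac=0.0, seed=15)
        vp = nc.variance_partition(a)
        assert vp["biological_fraction"] < 0.1
        assert vp["batch_fraction"] < 0.1

    def test_planted_signal_recovered(self):
        a = nc.planted_variance_segments(n_genes=200, seed=16)
        vp = nc.variance_partition(a)
        assert abs(vp["biological_fraction"] - 0.609) < 0.1
        assert abs(vp["batch_fraction"] - 0.123) < 0.1

    def test_nested_design_warns(self):
        meta = pd.DataFrame(
            {
                "tissue": ["EuE"] * 10 + ["EcP"] * 10,
                "compartment": ["Stroma", "Epithelium"] * 10,
                "slide": ["S1"] * 10 + ["S2"] * 10,  # slide nested in tissue
            },
            index=[f"s{i}" for i in range(20)],
        )
        a = _segs(np.random.default_rng(17).normal(size=(20, 30)), meta=meta)
        with pytest.warns(UserWarning):
            nc.variance_partition(a)
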