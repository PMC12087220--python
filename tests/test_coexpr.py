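"""Weighted co-expression: soft threshold, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from toxbarcode import coexpr
from toxbarcode.coexpr import UNASSIGNED, CoexprParams, ModulePartition


def block_expression(n_block=40, n_noise=0, n_cells=200, within=0.9, seed=0):
    """Two blocks sharing a latent factor (pairwise correlation ~ `within`),
    plus independent noise genes."""
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=(2, n_cells))
    rows = [
        shared[b][None, :] * np.sqrt(within) + rng.normal(size=(n_block, n_cells)) * np.sqrt(1 - within)
        for b in range(2)
    ]
    if n_noise:
        rows.append(rng.normal(size=(n_noise, n_cells)))
    x = np.vstack(rows)
    genes = [f"g{i}" for i in range(x.shape[0])]
    truth = ["A"] * n_block + ["B"] * n_block + [UNASSIGNED] * n_noise
    return pd.DataFrame(x, index=genes), truth


class TestSoftThreshold:
    def test_singleton_power_is_chosen(self):
        expr, _ = block_expression()
        rep = coexpr.pick_soft_threshold(expr, CoexprParams(powers_tested=(6,)))
        assert rep.chosen_power == 6
        assert len(rep.table) == 1

    def test_matches_independent_fit(self):
        """R^2 table equals an independent straight-line fit on the binned
        log-log degree distribution (recomputed from scratch here)."""
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(60, 40)))
        rep = coexpr.pick_soft_threshold(expr, CoexprParams(powers_tested=(2, 4, 6)))
        c = np.corrcoef(expr.to_numpy())
        np.fill_diagonal(c, 0.0)
        for _, row in rep.table.iterrows():
            a = np.abs(c) ** row.power
            k = a.sum(axis=1)
            k = k[k > 0]
            counts, edges = np.histogram(k, bins=10)
            mids, freqs = [], []
            for i in range(10):
                hi = k < edges[i + 1] if i < 9 else k <= edges[i + 1]
                sel = k[(k >= edges[i]) & hi]
                if len(sel):
                    mids.append(sel.mean())
                    freqs.append(len(sel) / len(k))
            slope, intercept = np.polyfit(np.log10(mids), np.log10(freqs), 1)
            r = np.corrcoef(np.log10(mids), np.log10(freqs))[0, 1]
            expected = 0.0 if slope > 0 else r**2
            assert row.r2 == pytest.approx(expected, abs=1e-8)

    def test_fallback_warns_and_returns_argmax(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(40, 15)))
        params = CoexprParams(powers_tested=(1, 2), target_scale_free_r2=0.999)
        with pytest.warns(UserWarning, match="argmax"):
            rep = coexpr.pick_soft_threshold(expr, params)
        assert rep.chosen_power == int(rep.table.power.iloc[rep.table.r2.idxmax()])

    def test_constant_matrix_rejected(self):
        expr = pd.DataFrame(np.ones((40, 10)))
        with pytest.raises(ValueError, match="constant"):
            coexpr.pick_soft_threshold(expr)


class TestAdjacency:
    def test_limits_and_power(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        df = pd.DataFrame(
            {
                "a": base,
                "b": base,  # cor = 1
                "c": rng.normal(size=50),  # cor ~ 0
            }
        ).T
        adj = coexpr.adjacency(df, beta=6)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] < 0.01
        assert np.all(np.diag(adj) == 0.0)

    def test_negative_correlation_unsigned(self):
        # crafted pair with correlation exactly -0.5
        u = np.array([1.0, 0.0, -1.0, 0.0])
        v = np.array([0.0, 1.0, 0.0, -1.0])
        df = pd.DataFrame({"a": u, "b": -0.5 * u + np.sqrt(0.75) * v}).T
        adj = coexpr.adjacency(df, beta=2)
        assert adj.loc["a", "b"] == pytest.approx(0.25, abs=1e-12)

    def test_signed_transform(self):
        u = np.array([1.0, 0.0, -1.0, 0.0])
        df = pd.DataFrame({"a": u, "b": -u}).T
        adj = coexpr.adjacency(df, beta=2, signed=True)
        assert adj.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)


class TestTom:
    def test_empty_and_complete_graphs(self):
        z = pd.DataFrame(np.zeros((4, 4)))
        assert np.all(coexpr.tom(z).to_numpy()[~np.eye(4, dtype=bool)] == 0.0)
        ones = np.ones((5, 5)) - np.eye(5)
        assert np.allclose(coexpr.tom(pd.DataFrame(ones)).to_numpy(), 1.0)

    def test_triangle_example(self):
        """Three genes, all pairwise adjacencies 0.5:
        TOM_12 = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5."""
        a = pd.DataFrame(np.full((3, 3), 0.5) - 0.5 * np.eye(3))
        t = coexpr.tom(a)
        assert t.iloc[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_formula_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.random((10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            t = coexpr.tom(pd.DataFrame(a)).to_numpy()
            k = a.sum(axis=1)
            for i in range(10):
                for j in range(10):
                    if i == j:
                        assert t[i, j] == 1.0
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(10)) + a[i, j]
                    den = min(k[i], k[j]) + 1 - a[i, j]
                    assert t[i, j] == pytest.approx(num / den, abs=1e-12)
            assert np.all(t >= 0) and np.all(t <= 1 + 1e-12)

    def test_asymmetric_rejected(self):
        a = pd.DataFrame(np.triu(np.full((4, 4), 0.5), k=1))
        with pytest.raises(ValueError, match="symmetric"):
            coexpr.tom(a)


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        expr, truth = block_expression(n_block=40, n_cells=200, within=0.9)
        rep = coexpr.pick_soft_threshold(expr)
        t = coexpr.tom(coexpr.adjacency(expr, rep.chosen_power))
        part = coexpr.detect_modules(t)
        assert len(part.modules) == 2
        assert adjusted_rand_score(truth, part.assignment) == 1.0

    def test_uncorrelated_genes_unassigned(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(20, 100)))
        with pytest.warns(UserWarning, match="fewer genes"):
            part = coexpr.detect_modules(coexpr.tom(coexpr.adjacency(expr, 6)))
        assert (part.assignment == UNASSIGNED).all()

    def test_29_gene_block_below_minimum_size(self):
        """A correlated block of 29 genes stays unassigned: the minimum
        module size of 30 is a strict floor."""
        rng = np.random.default_rng(7)
        shared = rng.normal(size=200)
        block = shared[None, :] * np.sqrt(0.9) + rng.normal(size=(29, 200)) * np.sqrt(0.1)
        noise = rng.normal(size=(40, 200))
        expr = pd.DataFrame(np.vstack([block, noise]))
        part = coexpr.detect_modules(coexpr.tom(coexpr.adjacency(expr, 6)))
        assert (part.assignment.iloc[:29] == UNASSIGNED).all()


class TestEigengenes:
    def test_identical_profiles_give_kme_one(self):
        profile = np.sin(np.linspace(0, 3, 40))
        expr = pd.DataFrame(np.tile(profile, (35, 1)) * np.arange(1, 36)[:, None])
        part = ModulePartition(pd.Series(["M1"] * 35, index=expr.index))
        filled = coexpr.eigengenes_and_membership(expr, part)
        e = filled.eigengenes.loc["M1"].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(np.abs(e), np.abs(z), atol=1e-8)
        assert np.allclose(filled.kme["M1"], 1.0, atol=1e-10)
        assert e.std() == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_gene_has_zero_kme(self):
        n = 40
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        expr = pd.DataFrame(
            np.vstack([np.tile(np.sin(t), (30, 1)), np.cos(t)[None, :]]),
        )
        part = ModulePartition(pd.Series(["M1"] * 30 + [UNASSIGNED], index=expr.index))
        filled = coexpr.eigengenes_and_membership(expr, part)
        assert filled.kme["M1"].iloc[-1] == pytest.approx(0.0, abs=1e-10)

    def test_kme_matches_pearson_oracle(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(50, 30)))
        labels = pd.Series(["M1"] * 25 + ["M2"] * 25, index=expr.index)
        filled = coexpr.eigengenes_and_membership(expr, ModulePartition(labels))
        for m in filled.modules:
            e = filled.eigengenes.loc[m].to_numpy()
            for g in expr.index:
                r = scipy.stats.pearsonr(expr.loc[g].to_numpy(), e)[0]
                assert filled.kme.loc[g, m] == pytest.approx(r, abs=1e-10)

    def test_single_sample_rejected(self):
        expr = pd.DataFrame(np.ones((5, 1)))
        part = ModulePartition(pd.Series(["M1"] * 5, index=expr.index))
        with pytest.raises(ValueError, match="sample"):
            coexpr.eigengenes_and_membership(expr, part)


class TestMergeModules:
    def _split_block(self, cor_between, seed=0):
        """Two labelled modules whose eigengenes correlate ~cor_between."""
        rng = np.random.default_rng(seed)
        n_cells = 300
        e1 = rng.normal(size=n_cells)
        e2 = cor_between * e1 + np.sqrt(1 - cor_between**2) * rng.normal(size=n_cells)
        mk = lambda e: e[None, :] * np.sqrt(0.95) + rng.normal(size=(31, n_cells)) * np.sqrt(0.05)
        expr = pd.DataFrame(np.vstack([mk(e1), mk(e2)]))
        labels = pd.Series(["M1"] * 31 + ["M2"] * 31, index=expr.index)
        return expr, ModulePartition(labels)

    def test_highly_correlated_modules_merge(self):
        expr, part = self._split_block(0.95)
        merged = coexpr.merge_modules(expr, part, 0.2)
        assert len(merged.modules) == 1

    def test_moderately_correlated_modules_kept(self):
        expr, part = self._split_block(0.5)
        merged = coexpr.merge_modules(expr, part, 0.2)
        assert len(merged.modules) == 2

    def test_fixed_point_no_pair_below_cut(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(120, 80)))
        labels = pd.Series([f"M{1 + i // 30}" for i in range(120)], index=expr.index)
        merged = coexpr.merge_modules(expr, ModulePartition(labels), 0.2)
        mods = merged.modules
        if len(mods) > 1:
            E = merged.eigengenes.loc[mods].to_numpy()
            c = np.corrcoef(E)
            np.fill_diagonal(c, -1.0)
            assert (1.0 - c.max()) >= 0.2

    def test_merge_preserves_gene_union(self):
        expr, part = self._split_block(0.95)
        merged = coexpr.merge_modules(expr, part, 0.2)
        assigned = merged.assignment != UNASSIGNED
        assert assigned.all()
        assert merged.sizes().iloc[0] == 62


class TestModuleTrait:
    def test_identity_and_orthogonal(self):
        n = 30
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        eig = pd.DataFrame(
            {c: v for c, v in zip([f"s{i}" for i in range(n)], np.vstack([np.sin(t), np.cos(t)]).T)},
            index=["M1", "M2"],
        )
        trait = pd.Series(np.sin(t), index=eig.columns)
        res = coexpr.module_trait_correlation(eig, trait)
        assert res.loc["M1", "r"] == pytest.approx(1.0)
        assert abs(res.loc["M2", "r"]) < 1e-10

    def test_matches_pearsonr_oracle(self):
        rng = np.random.default_rng(10)
        eig = pd.DataFrame(rng.normal(size=(3, 25)), index=["M1", "M2", "M3"],
                           columns=[f"s{i}" for i in range(25)])
        trait = pd.Series(rng.normal(size=25), index=eig.columns)
        res = coexpr.module_trait_correlation(eig, trait)
        for m in eig.index:
            r, p = scipy.stats.pearsonr(eig.loc[m], trait)
            assert res.loc[m, "r"] == pytest.approx(r, abs=1e-10)
            assert res.loc[m, "p"] == pytest.approx(p, abs=1e-10)

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame(np.random.default_rng(0).normal(size=(1, 10)), index=["M1"])
        with pytest.raises(ValueError, match="variance"):
            coexpr.module_trait_correlation(eig, pd.Series(np.ones(10), index=eig.columns))


def test_syndata_group_modules_recovered_signed(family):
    """End-to-end module recovery on the synthetic world (toxin cells only,
    signed network: the two planted groups are anti-correlated by
    construction, which unsigned TOM cannot separate)."""
    from toxbarcode import expression as ex
    from toxbarcode import syndata

    fam = syndata.simulate_family(syndata.FamilySimParams(n_genes=80, seed=23))
    cells, labels, _ = syndata.simulate_cells(
        fam.regulome, syndata.CellSimParams(seed=23, n_background_genes=205)
    )
    filt = ex.filter_cells(cells)
    clusters = ex.cluster_cells(filt, seed=1)
    ann = ex.classify_toxin_cells(filt, clusters, ["LAMA3", "EPCAM"], fam.regulome.genes)
    tox = filt.subset_samples(list(ann.is_toxin_cell.index[ann.is_toxin_cell]))
    expr = ex.log1p_cpm(tox)
    expr = expr.loc[expr.std(axis=1) > 0]
    params = CoexprParams(signed=True)
    rep = coexpr.pick_soft_threshold(expr, params)
    t = coexpr.tom(coexpr.adjacency(expr, rep.chosen_power, signed=True))
    part = coexpr.detect_modules(t, params)
    part = coexpr.merge_modules(expr, part, params.merge_dissimilarity)
    truth = pd.Series(fam.regulome.group_of)
    ari = adjusted_rand_score(truth, part.assignment.reindex(truth.index))
    assert ari >= 0.8
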