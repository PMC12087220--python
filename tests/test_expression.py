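"""Cell QC, TMM normalization, clr divergence, clustering and Spearman."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from toxbarcode import expression as ex
from toxbarcode.containers import CountMatrix


def cm(values, kind="cell", genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return CountMatrix(values, genes, samples, kind)


class TestFilterCells:
    def test_boundary_999_removed_1000_kept(self):
        """'At least 1000 counts and at least 100 different genes' is an
        inclusive threshold: 999 total fails, exactly 1000 over exactly 100
        genes passes."""
        n_genes = 120
        below = np.zeros(n_genes, dtype=int)
        below[:100] = 9
        below[99] = 999 - 99 * 9  # 108 -> total 999 over 100 genes
        at = np.zeros(n_genes, dtype=int)
        at[:100] = 10  # total 1000 over exactly 100 genes
        counts = cm(np.stack([below, at], axis=1))
        assert below.sum() == 999 and at.sum() == 1000
        kept = ex.filter_cells(counts)
        assert kept.sample_ids == ["s1"]

    def test_gene_threshold_independent_of_counts(self):
        col = np.zeros(120, dtype=int)
        col[:99] = 100  # plenty of counts but only 99 genes
        kept = ex.filter_cells(cm(col[:, None]))
        assert kept.n_samples == 0

    def test_all_removed_warns_and_gene_set_unchanged(self):
        counts = cm(np.ones((5, 3), dtype=int))
        with pytest.warns(UserWarning, match="every cell"):
            kept = ex.filter_cells(counts)
        assert kept.n_samples == 0
        assert kept.gene_ids == counts.gene_ids

    def test_idempotent(self, cells_sim):
        once = ex.filter_cells(cells_sim[0])
        twice = ex.filter_cells(once)
        assert once.sample_ids == twice.sample_ids


class TestTmm:
    def test_pseudobulk_is_per_gene_sum(self):
        counts = cm([[1, 2], [3, 4]])
        pb = ex.pseudobulk(counts)
        assert pb.values[:, 0].tolist() == [3, 7]
        assert pb.sample_kind == "bulk"

    def test_identical_libraries_factor_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 200, size=(300, 1))
        table = pd.DataFrame(np.hstack([x, x]), columns=["a", "b"])
        f = ex.tmm_factors(table)
        assert np.allclose(f, 1.0)

    def test_pure_scaling_removed(self):
        """Library B = 3 x library A exactly: TMM-normalized CPMs match."""
        rng = np.random.default_rng(1)
        a = rng.integers(1, 500, size=(400, 1))
        table = pd.DataFrame(np.hstack([a, 3 * a]), columns=["a", "b"])
        f = ex.tmm_factors(table)
        lib = table.sum(axis=0)
        cpmat = table / (lib * f) * 1e6
        assert np.allclose(cpmat["a"], cpmat["b"], rtol=1e-9)

    def test_factor_geometric_mean_one_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(500, 4)), columns=list("abcd"))
        f = ex.tmm_factors(x)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        f2 = ex.tmm_factors(x * 7)
        assert np.allclose(f, f2, atol=1e-12)

    def test_edger_cross_check(self):
        """Frozen independent oracle: the same deterministic count table was
        exported to TSV and run through edgeR::calcNormFactors(method="TMM");
        the resulting factors are frozen below."""
        rng = np.random.default_rng(42)
        x = pd.DataFrame(
            rng.negative_binomial(5, 5 / 105, size=(300, 3)), columns=list("abc")
        )
        f = ex.tmm_factors(x)
        assert np.allclose(f.to_numpy(), EDGER_FACTORS, atol=1e-6)

    def test_zero_library_rejected(self):
        table = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            ex.tmm_factors(table)

    def test_pseudobulk_and_normalize_requires_shared_genes(self, cells_sim):
        bulk = cm([[5], [5]], kind="bulk")
        with pytest.raises(ValueError, match="gene index"):
            ex.pseudobulk_and_normalize(cells_sim[0], bulk)


# edgeR 4.0.16 calcNormFactors output on the table above; frozen so the test
# does not need R at run time
EDGER_FACTORS = [0.9863187, 1.0037646, 1.0100685]


class TestClrDivergence:
    def test_equal_composition_is_zero(self):
        assert np.allclose(ex.clr(np.ones(4)), 0.0)

    def test_clr_sums_to_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.random(50) * 100
            assert ex.clr(x).sum() == pytest.approx(0.0, abs=1e-8)

    def test_identity_flags_nothing(self):
        rng = np.random.default_rng(4)
        v = pd.Series(rng.random(200) * 50 + 1, index=[f"g{i}" for i in range(200)])
        rep = ex.clr_divergence(v, v.copy(), toxin_ids=["g0", "g1"])
        assert np.allclose(rep.residuals, 0.0, atol=1e-10)
        assert not any(rep.flags.values())

    def test_planted_outlier_flagged_null_rate_calibrated(self):
        """With N(0,1)-ish scatter around the identity line, a toxin planted
        five residual-sds off the line is flagged while ~1% of null genes
        fall outside their own 99% interval by construction."""
        rng = np.random.default_rng(5)
        n = 5000
        base = rng.normal(5, 2, size=n)
        noise = rng.normal(0, 1, size=n)
        genes = [f"g{i}" for i in range(n)] + ["tox"]
        bulk = pd.Series(np.exp(np.r_[base, 5.0]), index=genes)
        pseudo = pd.Series(np.exp(np.r_[base + noise, 5.0 + 5 * np.sqrt(2)]), index=genes)
        rep = ex.clr_divergence(pseudo, bulk, toxin_ids=["tox"])
        assert rep.flags["tox"]
        non_toxin = rep.residuals[:-1]
        outside = np.mean((non_toxin < rep.interval[0]) | (non_toxin > rep.interval[1]))
        assert outside == pytest.approx(0.01, abs=0.005)

    def test_flags_invariant_to_gene_order(self):
        rng = np.random.default_rng(6)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        bulk = pd.Series(rng.random(n) * 40 + 1, index=genes)
        pseudo = pd.Series(bulk.to_numpy() * np.exp(rng.normal(0, 0.2, n)), index=genes)
        toxins = genes[:20]
        rep1 = ex.clr_divergence(pseudo, bulk, toxins)
        perm = rng.permutation(n)
        rep2 = ex.clr_divergence(pseudo.iloc[perm], bulk.iloc[perm], toxins)
        assert rep1.flags == rep2.flags

    def test_small_null_rejected(self):
        v = pd.Series(np.arange(1.0, 13.0), index=[f"g{i}" for i in range(12)])
        with pytest.raises(ValueError, match="non-toxin"):
            ex.clr_divergence(v, v, toxin_ids=[f"g{i}" for i in range(5)])


class TestClusterCells:
    def _blobs(self, n_per=100, seed=0):
        """Two populations with disjoint high-expression gene sets (well
        separated after per-cell normalization)."""
        rng = np.random.default_rng(seed)
        x = rng.poisson(5, size=(30, 2 * n_per))
        x[:15, :n_per] += rng.poisson(100, size=(15, n_per))
        x[15:, n_per:] += rng.poisson(100, size=(15, n_per))
        return cm(x), np.r_[np.zeros(n_per), np.ones(n_per)]

    def test_two_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        counts, truth = self._blobs()
        labels = ex.cluster_cells(counts, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_cells_single_community(self):
        counts = cm(np.tile([[5], [3], [1]], (1, 30)))
        labels = ex.cluster_cells(counts, k_neighbors=5, seed=0)
        assert labels.nunique() == 1

    def test_deterministic_given_seed(self, cells_sim):
        filt = ex.filter_cells(cells_sim[0])
        l1 = ex.cluster_cells(filt, seed=7)
        l2 = ex.cluster_cells(filt, seed=7)
        assert l1.equals(l2)

    def test_too_many_neighbors_rejected(self):
        counts = cm(np.ones((5, 10), dtype=int))
        with pytest.raises(ValueError, match="k_neighbors"):
            ex.cluster_cells(counts, k_neighbors=10)


class TestClassifyToxinCells:
    def test_thresholds_satisfied(self):
        counts = cm(
            [[60, 70], [30, 20], [10, 10]], genes=["tox", "mk", "other"], samples=["c1", "c2"]
        )
        clusters = pd.Series([0, 0], index=["c1", "c2"])
        ann = ex.classify_toxin_cells(counts, clusters, ["mk"], ["tox"])
        assert ann.is_toxin_cell.all()
        assert ann.toxin_fraction.between(0, 1).all()

    def test_zero_toxin_expression_no_calls(self):
        counts = cm([[0, 0], [50, 50], [50, 50]], genes=["tox", "mk", "other"])
        clusters = pd.Series([0, 0], index=counts.sample_ids)
        ann = ex.classify_toxin_cells(counts, clusters, ["mk"], ["tox"])
        assert not ann.is_toxin_cell.any()

    def test_unknown_marker_listed(self):
        counts = cm(np.ones((3, 2), dtype=int))
        clusters = pd.Series([0, 0], index=counts.sample_ids)
        with pytest.raises(KeyError, match="LAMA3"):
            ex.classify_toxin_cells(counts, clusters, ["LAMA3"], ["g0"])

    def test_planted_secretory_cells_recovered(self, family, cells_sim):
        counts, labels, _ = cells_sim
        filt = ex.filter_cells(counts)
        clusters = ex.cluster_cells(filt, seed=1)
        ann = ex.classify_toxin_cells(
            filt, clusters, ["LAMA3", "EPCAM"], family.regulome.genes
        )
        secretory = labels.reindex(filt.sample_ids).str.startswith("secretory")
        assert ann.is_toxin_cell[secretory].mean() >= 0.95


class TestSpearman:
    def test_rank_identity_and_reversal(self):
        x = np.array([[1, 5, 20, 300], [2, 6, 21, 301], [300, 20, 5, 1]])
        pm = ex.spearman_coexpression(cm(x), ["g0", "g1", "g2"])
        assert pm.values[0, 1] == pytest.approx(1.0)
        assert pm.values[0, 2] == pytest.approx(-1.0)

    def test_three_point_example(self):
        """x=(1,2,3) vs y=(3,1,2): sum of squared rank differences is 6, so
        rho = 1 - 6*6/(3*8) = -0.5. Library sizes equalized so CPM keeps
        the orderings."""
        x = np.array([[1, 2, 3], [3, 1, 2], [6, 7, 5]])
        pm = ex.spearman_coexpression(cm(x), ["g0", "g1"])
        assert pm.values[0, 1] == pytest.approx(-0.5)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.integers(0, 100, size=(10, 20))
            counts = cm(x)
            pm = ex.spearman_coexpression(counts, counts.gene_ids)
            expr = ex.log1p_cpm(counts).to_numpy()
            ranks = np.apply_along_axis(scipy.stats.rankdata, 1, expr)
            oracle = np.corrcoef(ranks)
            assert np.allclose(pm.values, oracle, atol=1e-10)

    def test_constant_gene_missing_with_warning(self):
        # equal library sizes so the middle gene stays constant after CPM
        x = np.array([[1, 2, 3], [5, 5, 5], [6, 5, 4]])
        with pytest.warns(UserWarning, match="constant"):
            pm = ex.spearman_coexpression(cm(x), ["g0", "g1"])
        assert np.isnan(pm.values[0, 1])
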