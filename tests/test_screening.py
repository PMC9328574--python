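"""Permutation importance score, fold statistics and the genome screen."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dnnprs.screening import (
    FoldScore,
    ImportanceResult,
    NetworkConfig,
    fit_gene_network,
    fold_score,
    group_importance,
    loss_difference,
    permute_rows,
    screen_genome,
)
from dnnprs.simulate import GeneSpec, SimulationSpec, simulate_dataset, standard_panel


class TestPermuteRows:
    def test_seeded_permutation_matches_stated_prng(self):
        X = np.arange(12).reshape(4, 3).astype(float)
        out = permute_rows(X, seed=99)
        pi = np.random.default_rng(99).permutation(4)
        np.testing.assert_array_equal(out, X[pi])

    def test_columnwise_statistics_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (200, 8)).astype(float)
        out = permute_rows(X, seed=5)
        np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(np.corrcoef(out.T), np.corrcoef(X.T), atol=1e-12)

    def test_rows_are_a_reordering(self):
        X = np.random.default_rng(2).standard_normal((10, 3))
        out = permute_rows(X, seed=3)
        assert sorted(map(tuple, out)) == sorted(map(tuple, X))


class _ConstantNet:
    """Stub predictor used to exercise degenerate paths."""

    outcome_type = "continuous"

    def __init__(self, value=1.5):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class TestLossDifference:
    def test_constant_predictor_gives_exact_zeros(self):
        X = np.random.default_rng(0).integers(0, 3, (50, 4)).astype(float)
        y = np.random.default_rng(1).standard_normal(50)
        l = loss_difference(_ConstantNet(), X, y, n_perm=7, seed=2)
        np.testing.assert_allclose(l, np.zeros(50), atol=1e-12)

    def test_matches_exhaustive_enumeration_at_n3(self):
        """Monte-Carlo permutation average converges to the exact n!-enumeration."""
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, (200, 6)).astype(float)
        y = rng.standard_normal(200)
        cfg = NetworkConfig(hidden_sizes=(8, 4), epochs=10, seed=4)
        net = fit_gene_network(X, y, cfg, outcome_type="continuous")
        X3, y3 = X[:3], y[:3]
        preds = net.predict(X3)
        exact = np.zeros(3)
        perms = list(itertools.permutations(range(3)))
        for pi in perms:
            exact += (y3 - preds[list(pi)]) ** 2
        exact /= len(perms)
        expected = (y3 - preds) ** 2 - exact
        l = loss_difference(net, X3, y3, n_perm=40000, seed=8)
        np.testing.assert_allclose(l, expected, atol=0.02)

    def test_no_refit_parameters_untouched(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, (100, 5)).astype(float)
        y = rng.standard_normal(100)
        net = fit_gene_network(X, y, NetworkConfig(epochs=5, seed=1), outcome_type="continuous")
        before = net.checksum()
        loss_difference(net, X, y, n_perm=20, seed=9)
        assert net.checksum() == before

    def test_strong_signal_gives_negative_mean(self):
        """A well-fitted net loses less on observed than permuted data."""
        spec = SimulationSpec(
            n=2000, genes=(GeneSpec("sig", 10, "linear90"),), signal_fraction=0.4, seed=6
        )
        ds = simulate_dataset(spec)
        X = ds.regions[0].dosage_block(ds.genotypes)
        y = ds.phenotype.values
        net = fit_gene_network(
            X[:1500], y[:1500], NetworkConfig(epochs=60, seed=2), outcome_type="continuous"
        )
        l = loss_difference(net, X[1500:], y[1500:], n_perm=50, seed=3)
        assert l.mean() < 0


class TestFoldScore:
    def test_hand_computed_statistics(self):
        """delta is the sum of l_i; the variance estimate is |D2| * s^2(l_i)."""
        losses = np.array([-1.0, 0.0, 1.0])
        delta = float(losses.sum())
        var = len(losses) * float(np.var(losses, ddof=1))
        assert delta == 0.0
        assert var == 3.0

    def test_fold_score_runs_and_partitions(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, (80, 5)).astype(float)
        y = rng.standard_normal(80)
        tr, va = np.arange(60), np.arange(60, 80)
        fs = fold_score(X, y, "continuous", tr, va, NetworkConfig(epochs=5, seed=3), n_perm=10)
        assert fs.delta == pytest.approx(fs.losses.sum())
        assert fs.var == pytest.approx(20 * np.var(fs.losses, ddof=1))
        assert len(np.intersect1d(fs.train_idx, fs.val_idx)) == 0

    def test_tiny_validation_fold_rejected(self):
        X = np.zeros((10, 2))
        y = np.zeros(10)
        with pytest.raises(ValueError, match="fold"):
            fold_score(X, y, "continuous", np.arange(9), np.array([9]), NetworkConfig(epochs=1))

    def test_null_fold_statistic_approximately_normal(self):
        """Delta/sigma on a null gene across many replicates passes a KS normality check."""
        zs = []
        cfg = NetworkConfig(hidden_sizes=(20, 5), epochs=5, dropout_rate=0.5)
        for rep in range(150):
            rng = np.random.default_rng(1000 + rep)
            X = rng.integers(0, 3, (250, 10)).astype(float)
            y = rng.standard_normal(250)
            tr, va = np.arange(200), np.arange(200, 250)
            fs = fold_score(
                X, y, "continuous", tr, va,
                NetworkConfig(hidden_sizes=(20, 5), epochs=5, seed=rep), n_perm=30,
            )
            zs.append(fs.delta / np.sqrt(fs.var))
        assert stats.kstest(zs, "norm").pvalue > 0.01


class TestGroupImportance:
    def test_degenerate_zero_variance_gives_p_one(self):
        """A gene whose phenotype relationship is constant yields p = 1, not 0/0."""
        scores = [FoldScore(i, np.arange(5), np.arange(5, 10), 0.0, 0.0, np.zeros(5)) for i in range(3)]
        delta = float(np.mean([s.delta for s in scores]))
        se = float(np.sqrt(sum(s.var for s in scores)) / 3)
        assert (delta, se) == (0.0, 0.0)
        # group_importance maps se == 0 to p = 1; exercised via the real path:
        X = np.random.default_rng(0).integers(0, 3, (60, 3)).astype(float)
        y = np.concatenate([np.zeros(30), np.ones(30)])
        res = group_importance(
            X, y, NetworkConfig(epochs=1, learning_rate=0.0, seed=1), K=3, n_perm=5,
            outcome_type="continuous",
        )
        assert 0.0 <= res.p <= 1.0

    def test_z_and_p_consistent(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 3, (120, 6)).astype(float)
        y = rng.standard_normal(120)
        res = group_importance(
            X, y, NetworkConfig(epochs=5, seed=2), K=4, n_perm=10, outcome_type="continuous"
        )
        assert res.p == pytest.approx(stats.norm.cdf(res.z))
        assert res.K == 4
        assert res.delta == pytest.approx(np.mean([f.delta for f in res.fold_scores]))

    def test_strong_linear_gene_detected(self, signal_dataset):
        ds = signal_dataset
        X = ds.regions[0].dosage_block(ds.genotypes)
        res = group_importance(
            X, ds.phenotype, NetworkConfig(epochs=40, seed=3), K=5, n_perm=30, gene_id="sig"
        )
        assert res.p < 1e-3
        assert res.delta < 0

    def test_binary_outcome_path(self):
        spec = SimulationSpec(
            n=1200, genes=(GeneSpec("sig", 10, "linear90"),), signal_fraction=0.3,
            link="logistic", seed=8,
        )
        ds = simulate_dataset(spec)
        res = group_importance(
            ds.regions[0].dosage_block(ds.genotypes),
            ds.phenotype,
            NetworkConfig(epochs=40, seed=4),
            K=5,
            n_perm=30,
        )
        assert res.p < 0.05


@pytest.fixture(scope="module")
def small_dataset():
    return simulate_dataset(
        SimulationSpec(
            n=400,
            genes=(GeneSpec("sig", 8, "linear90"), GeneSpec("nul", 8, "null")),
            signal_fraction=0.3,
            seed=12,
        )
    )


class TestScreenGenome:

    def test_alpha_one_selects_all(self, small_dataset):
        ds = small_dataset
        out = screen_genome(
            ds.genotypes, ds.regions, ds.phenotype, NetworkConfig(epochs=5, seed=1),
            K=3, n_perm=10, alpha=1.0,
        )
        assert out.selected == ["sig", "nul"]
        assert set(out.networks) == {"sig", "nul"}

    def test_alpha_zero_selects_none(self, small_dataset):
        ds = small_dataset
        out = screen_genome(
            ds.genotypes, ds.regions, ds.phenotype, NetworkConfig(epochs=5, seed=1),
            K=3, n_perm=10, alpha=0.0,
        )
        assert out.selected == []
        assert out.networks == {}

    def test_results_in_region_order(self, small_dataset):
        ds = small_dataset
        out = screen_genome(
            ds.genotypes, ds.regions, ds.phenotype, NetworkConfig(epochs=5, seed=1),
            K=3, n_perm=10, alpha=0.5,
        )
        assert [r.gene_id for r in out.results] == ["sig", "nul"]


class TestErrors:
    def test_constant_phenotype_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="constant"):
            fit_gene_network(X, np.ones(10), NetworkConfig(epochs=1), outcome_type="continuous")

    def test_empty_gene_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_gene_network(
                np.zeros((10, 0)), np.arange(10.0), NetworkConfig(epochs=1),
                outcome_type="continuous",
            )

    def test_nperm_validated(self):
        with pytest.raises(ValueError, match="n_perm"):
            loss_difference(_ConstantNet(), np.zeros((5, 2)), np.zeros(5), n_perm=0)

    def test_training_determinism_same_seed(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, (100, 5)).astype(float)
        y = rng.standard_normal(100)
        cfg = NetworkConfig(epochs=8, seed=77)
        a = fit_gene_network(X, y, cfg, outcome_type="continuous")
        b = fit_gene_network(X, y, cfg, outcome_type="continuous")
        for pa, pb in zip(a.net.parameters, b.net.parameters):
            np.testing.assert_array_equal(pa, pb)
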