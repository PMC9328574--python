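"""Transfer architecture: parameter accounting, freeze contract, prediction."""

import numpy as np
import pytest

from dnnprs.background import compute_grm, cross_grm, fit_gblup
from dnnprs.io import GenotypeMatrix, Phenotype, Variant
from dnnprs.screening import NetworkConfig, fit_gene_network
from dnnprs.simulate import GeneSpec, SimulationSpec, simulate_dataset
from dnnprs.transfer import (
    TransferConfig,
    build_transfer_network,
    fit,
    load_model,
    predict,
    predict_components,
    run_pipeline,
    save_model,
)


def _gene_nets(p=4, n=200, n_k=12, seed=0, outcome="continuous"):
    rng = np.random.default_rng(seed)
    nets, blocks = [], []
    y = rng.standard_normal(n) if outcome == "continuous" else rng.integers(0, 2, n).astype(float)
    for k in range(p):
        X = rng.integers(0, 3, (n, n_k)).astype(float)
        nets.append(
            fit_gene_network(
                X, y, NetworkConfig(epochs=3, seed=k), outcome_type=outcome, gene_id=f"g{k}"
            )
        )
        blocks.append(X)
    return nets, blocks, y


class TestParameterAccounting:
    def test_analytic_trainable_count_four_genes(self):
        """4 genes x width-10 hidden, stacked (100, 10): 5122 trainable weights."""
        nets, _, _ = _gene_nets(p=4)
        model = build_transfer_network(nets, None, TransferConfig(seed=1), "continuous")
        expected = (40 * 100 + 100) + (100 * 10 + 10) + (10 * 1 + 1) + 1
        assert expected == 5122
        assert model.trainable_parameter_count() == expected
        assert model.frozen_parameter_count() == sum(
            g.net.n_hidden_parameters for g in nets
        )

    def test_optimal_count_is_transfer_plus_frozen(self):
        nets, _, _ = _gene_nets(p=3)
        t = build_transfer_network(nets, None, TransferConfig(mode="transfer", seed=1), "continuous")
        o = build_transfer_network(nets, None, TransferConfig(mode="optimal", seed=1), "continuous")
        assert o.trainable_parameter_count() == (
            t.trainable_parameter_count() + t.frozen_parameter_count()
        )
        assert o.frozen_parameter_count() == 0

    def test_transfer_strictly_smaller_for_any_p(self):
        for p in (1, 2, 5):
            nets, _, _ = _gene_nets(p=p)
            t = build_transfer_network(nets, None, TransferConfig(seed=1), "continuous")
            o = build_transfer_network(nets, None, TransferConfig(mode="optimal", seed=1), "continuous")
            assert t.trainable_parameter_count() < o.trainable_parameter_count()

    def test_empty_selection_reduces_to_weighted_background(self):
        model = build_transfer_network([], None, TransferConfig(seed=1), "continuous")
        assert model.p == 0
        assert model.trainable_parameter_count() == 2  # gamma0 + intercept
        h0 = np.linspace(-1, 1, 11)
        preds = predict(model, [], h0)
        np.testing.assert_allclose(preds, model.gamma0[0] * h0 + model.intercept[0])


class TestFreezeContract:
    def test_transfer_mode_never_mutates_theta(self):
        nets, blocks, y = _gene_nets(p=2)
        model = build_transfer_network(nets, None, TransferConfig(epochs=5, seed=3), "continuous")
        before = model.theta_checksums()
        fit(model, blocks, np.zeros(len(y)), y)
        assert model.theta_checksums() == before

    def test_optimal_mode_updates_theta(self):
        nets, blocks, y = _gene_nets(p=2)
        model = build_transfer_network(
            nets, None, TransferConfig(epochs=5, mode="optimal", seed=3), "continuous"
        )
        # non-zero head so gradients reach the gene layers immediately
        model.stacks[0].weights[-1][...] = 0.1
        before = model.theta_checksums()
        fit(model, blocks, np.zeros(len(y)), y)
        assert model.theta_checksums() != before


class TestPrediction:
    def test_additive_decomposition(self):
        nets, blocks, y = _gene_nets(p=3)
        h0 = np.random.default_rng(5).standard_normal(len(y))
        model = build_transfer_network(nets, None, TransferConfig(epochs=3, seed=2), "continuous")
        fit(model, blocks, h0, y)
        gene_part, bg_part = predict_components(model, blocks, h0)
        np.testing.assert_allclose(gene_part + bg_part, predict(model, blocks, h0), atol=1e-6)
        np.testing.assert_allclose(bg_part, model.gamma0[0] * h0, atol=1e-10)

    def test_binary_outputs_are_probabilities(self):
        nets, blocks, y = _gene_nets(p=2, outcome="binary")
        h0 = np.random.default_rng(1).standard_normal(len(y))
        model = build_transfer_network(nets, None, TransferConfig(epochs=3, seed=2), "binary")
        fit(model, blocks, h0, y)
        rng = np.random.default_rng(7)
        new_blocks = [rng.integers(0, 3, b.shape).astype(float) for b in blocks]
        p = predict(model, new_blocks, rng.standard_normal(len(y)))
        assert np.all((p >= 0) & (p <= 1))

    def test_repeat_prediction_is_deterministic(self):
        nets, blocks, y = _gene_nets(p=2)
        h0 = np.zeros(len(y))
        model = build_transfer_network(nets, None, TransferConfig(epochs=2, seed=2), "continuous")
        fit(model, blocks, h0, y)
        np.testing.assert_array_equal(predict(model, blocks, h0), predict(model, blocks, h0))

    def test_wrong_block_count_rejected(self):
        nets, blocks, y = _gene_nets(p=2)
        model = build_transfer_network(nets, None, TransferConfig(seed=1), "continuous")
        with pytest.raises(ValueError, match="gene blocks"):
            predict(model, blocks[:1], np.zeros(len(y)))

    def test_within_genes_scope_builds_private_stacks(self):
        nets, blocks, y = _gene_nets(p=3)
        model = build_transfer_network(
            nets, None,
            TransferConfig(interaction_scope="within_genes_only", stacked_hidden_sizes=(20, 5), seed=2),
            "continuous",
        )
        assert len(model.stacks) == 3
        fit(model, blocks, np.zeros(len(y)), y)
        assert np.isfinite(predict(model, blocks, np.zeros(len(y)))).all()


class TestGBLUPLimit:
    def test_ablated_gene_stack_reproduces_gblup_predictions(self):
        """With the stacked layers silenced, held-out predictions are an affine map
        of the standalone gBLUP prediction (identical Pearson correlation)."""
        spec = SimulationSpec(
            n=600, genes=(GeneSpec("a", 10, "linear90"), GeneSpec("b", 10, "null")),
            signal_fraction=0.25, seed=3,
        )
        ds = simulate_dataset(spec)
        tr, te = np.arange(450), np.arange(450, 600)
        gm_tr = GenotypeMatrix(
            [ds.genotypes.samples[i] for i in tr], list(ds.genotypes.variants),
            ds.genotypes.dosages[tr],
        )
        gm_te = GenotypeMatrix(
            [ds.genotypes.samples[i] for i in te], list(ds.genotypes.variants),
            ds.genotypes.dosages[te],
        )
        y = ds.phenotype.values
        grm = compute_grm(gm_tr)
        bg = fit_gblup(grm, y[tr])
        h0_te = bg.predict(cross_grm(gm_te, grm))

        nets = [
            fit_gene_network(
                r.dosage_block(gm_tr), y[tr], NetworkConfig(epochs=3, seed=1),
                outcome_type="continuous", gene_id=r.gene_id,
            )
            for r in ds.regions
        ]
        model = build_transfer_network(nets, bg, TransferConfig(epochs=3, seed=2), "continuous")
        fit(model, [r.dosage_block(gm_tr) for r in ds.regions], bg.h0_train, y[tr])
        # silence the gene stack: gamma_1 = 0
        for s in model.stacks:
            for p in s.parameters:
                p[...] = 0.0
        preds = predict(model, [r.dosage_block(gm_te) for r in ds.regions], h0_te)
        np.testing.assert_allclose(preds, model.gamma0[0] * h0_te, atol=1e-10)
        r_model = np.corrcoef(preds, y[te])[0, 1]
        r_gblup = np.corrcoef(h0_te, y[te])[0, 1]
        assert abs(abs(r_model) - abs(r_gblup)) < 1e-3


class TestPipelineAndArtifacts:
    def test_pipeline_null_dataset_r_near_zero(self):
        """With no genetic signal anywhere, held-out accuracy hovers around zero."""
        rs = []
        for rep in range(5):
            spec = SimulationSpec(
                n=400,
                genes=(GeneSpec("n1", 10, "null"), GeneSpec("n2", 10, "null")),
                switches=(0, 0, 0, 0),
                seed=100 + rep,
            )
            ds = simulate_dataset(spec)
            res = run_pipeline(
                ds, NetworkConfig(epochs=5, seed=1), TransferConfig(epochs=5, seed=2),
                alpha=0.001, K=3, n_perm=10, seed=rep,
            )
            rs.append(res.metrics["r"])
        assert abs(np.mean(rs)) < 3 * np.std(rs, ddof=1) / np.sqrt(len(rs)) + 0.05

    def test_pipeline_signal_dataset_beats_null_and_artifact_round_trips(self, tmp_path):
        spec = SimulationSpec(
            n=600,
            genes=(GeneSpec("sig", 10, "linear90"), GeneSpec("nul", 10, "null")),
            signal_fraction=0.35, seed=9,
        )
        ds = simulate_dataset(spec)
        res = run_pipeline(
            ds, NetworkConfig(epochs=150, seed=1), TransferConfig(epochs=50, seed=2),
            alpha=0.01, K=4, n_perm=20, seed=3,
        )
        assert "sig" in res.screen.selected
        assert res.metrics["r"] > 0.2
        # artifact round trip: saved model reproduces in-memory predictions
        sel_regions = [r for r in ds.regions if r.gene_id in res.screen.selected]
        gm_tr = GenotypeMatrix(
            [ds.genotypes.samples[i] for i in res.train_idx],
            list(ds.genotypes.variants),
            ds.genotypes.dosages[res.train_idx],
        )
        save_model(res.model, sel_regions, gm_tr, tmp_path / "model")
        loaded, manifest = load_model(tmp_path / "model")
        blocks_te = [
            ds.genotypes.dosages[res.test_idx][:, r.variant_indices] for r in sel_regions
        ]
        h0_te = res.background_test
        np.testing.assert_allclose(
            predict(loaded, blocks_te, h0_te), res.predictions, atol=1e-10
        )
        assert manifest["genes"][0]["gene_id"] in res.screen.selected
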