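"""Transfer-learning prediction network with a gBLUP background node.

The prediction model is additive on the linear-predictor scale:

    E(Y | X) = g(f_1^h(X_1), ..., f_p^h(X_p); gamma_1) + gamma_0 * h0'

where f_k^h are the last-hidden-layer transforms of the per-gene screening
networks (parameters theta_k frozen in transfer mode), g is a stack of newly
added fully-connected layers with parameters gamma_1, and h0' is the per-
subject gBLUP genetic value entering through a single scalar weight gamma_0.
For binary outcomes the sum passes through a logistic transform, keeping the
two components additive on one scale.

Two training modes share the architecture: ``transfer`` updates only
(gamma_0, gamma_1); ``optimal`` additionally backpropagates into the per-gene
hidden layers, re-estimating theta. Two wiring variants are supported:
``between_genes`` concatenates all gene hidden outputs into one stack (gene
interplay allowed), ``within_genes_only`` gives each gene a private stack
whose scalar outputs are summed (no between-gene interactions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._seeds import derive_rng, derive_seed
from .background import BackgroundModel, compute_grm, cross_grm, fit_gblup
from .io import GenotypeMatrix, Phenotype
from .nn import Adam, FeedForward, auto_batch_size, sigmoid
from .screening import GeneNetwork, NetworkConfig, ScreenResult, screen_genome

logger = logging.getLogger(__name__)

__all__ = [
    "TransferConfig",
    "TransferModel",
    "build_transfer_network",
    "fit",
    "predict",
    "predict_components",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class TransferConfig:
    stacked_hidden_sizes: tuple[int, ...] = (100, 10)
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int | None = None
    mode: str = "transfer"  # transfer | optimal
    interaction_scope: str = "between_genes"  # between_genes | within_genes_only
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stacked_hidden_sizes", tuple(self.stacked_hidden_sizes))
        if any(w <= 0 for w in self.stacked_hidden_sizes):
            raise ValueError("stacked widths must be positive")
        if self.mode not in ("transfer", "optimal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.interaction_scope not in ("between_genes", "within_genes_only"):
            raise ValueError(f"unknown interaction_scope {self.interaction_scope!r}")


@dataclass
class TransferModel:
    gene_ids: list[str]
    gene_nets: list[GeneNetwork]
    stacks: list[FeedForward]  # one shared stack, or one per gene (within scope)
    gamma0: np.ndarray  # scalar background weight, shape (1,)
    intercept: np.ndarray  # used only when no genes are selected, shape (1,)
    background: BackgroundModel | None
    outcome_type: str
    cfg: TransferConfig

    @property
    def p(self) -> int:
        return len(self.gene_nets)

    def trainable_parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for s in self.stacks:
            params.extend(s.parameters)
        if self.cfg.mode == "optimal":
            for gnet in self.gene_nets:
                params.extend(gnet.net.parameters[:-2])  # hidden layers only
        params.append(self.gamma0)
        if self.p == 0:
            params.append(self.intercept)
        return params

    def frozen_parameters(self) -> list[np.ndarray]:
        if self.cfg.mode == "optimal":
            return []
        return [p for gnet in self.gene_nets for p in gnet.net.parameters[:-2]]

    def trainable_parameter_count(self) -> int:
        return sum(p.size for p in self.trainable_parameters())

    def frozen_parameter_count(self) -> int:
        return sum(p.size for p in self.frozen_parameters())

    def theta_checksums(self) -> list[float]:
        return [g.checksum() for g in self.gene_nets]


def build_transfer_network(
    gene_nets: list[GeneNetwork],
    background: BackgroundModel | None,
    cfg: TransferConfig,
    outcome_type: str | None = None,
) -> TransferModel:
    """Assemble the stacked architecture over frozen gene networks.

    With no selected genes the model degenerates to the scalar-weighted
    background (plus an intercept).
    """
    if outcome_type is None:
        if not gene_nets:
            raise ValueError("outcome_type required when no gene networks are given")
        outcome_type = gene_nets[0].outcome_type
    stacks: list[FeedForward] = []
    if gene_nets:
        widths = [g.hidden_width for g in gene_nets]
        if cfg.interaction_scope == "between_genes":
            sizes = [sum(widths), *cfg.stacked_hidden_sizes, 1]
            stacks = [FeedForward(sizes, seed=derive_seed(cfg.seed, "stack"))]
        else:
            stacks = [
                FeedForward([w, *cfg.stacked_hidden_sizes, 1], seed=derive_seed(cfg.seed, "stack", k))
                for k, w in enumerate(widths)
            ]
        for s in stacks:
            # zero output head: the untrained model starts at its gBLUP limit
            s.weights[-1][...] = 0.0
            s.biases[-1][...] = 0.0
    return TransferModel(
        gene_ids=[g.gene_id for g in gene_nets],
        gene_nets=list(gene_nets),
        stacks=stacks,
        gamma0=np.ones(1),  # gBLUP pass-through at initialisation
        intercept=np.zeros(1),
        background=background,
        outcome_type=outcome_type,
        cfg=cfg,
    )


def _forward(
    model: TransferModel,
    blocks: list[np.ndarray],
    h0: np.ndarray,
    need_caches: bool = False,
    train: bool = False,
    drop_rng: np.random.Generator | None = None,
):
    """Linear-predictor forward pass; optionally keep caches for backprop.

    ``train`` activates the gene subnets' dropout layers; used only when those
    layers are being retrained (optimal mode), since the retrained architecture
    keeps the dropout regularisation it was screened with.
    """
    gene_caches = []
    stack_caches = []
    gene_part = np.zeros(len(h0))
    if model.p:
        hiddens = []
        for gnet, X in zip(model.gene_nets, blocks):
            h, cache = gnet.net.hidden_forward(
                gnet._standardise(X), train=train, drop_rng=drop_rng
            )
            hiddens.append(h)
            gene_caches.append(cache)
        if model.cfg.interaction_scope == "between_genes":
            F = np.hstack(hiddens)
            out, c = model.stacks[0].forward(F)
            gene_part = out
            stack_caches.append(c)
        else:
            for s, h in zip(model.stacks, hiddens):
                out, c = s.forward(h)
                gene_part = gene_part + out
                stack_caches.append(c)
    eta = gene_part + model.gamma0[0] * h0
    if model.p == 0:
        eta = eta + model.intercept[0]
    if need_caches:
        return eta, gene_part, gene_caches, stack_caches
    return eta, gene_part


def fit(
    model: TransferModel,
    gene_blocks: list[np.ndarray],
    h0: np.ndarray,
    y: np.ndarray | Phenotype,
) -> TransferModel:
    """Train the stacked layers and background weight (plus theta in optimal mode).

    Adam, MSE loss for continuous outcomes, cross entropy for binary; minibatch
    order is seeded; frozen parameters are untouched in transfer mode.
    """
    if isinstance(y, Phenotype):
        y = y.values
    y = np.asarray(y, dtype=float)
    cfg = model.cfg
    n = len(y)
    bs = cfg.batch_size or auto_batch_size(n)
    rng = derive_rng(cfg.seed, "fit")
    params = model.trainable_parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    optimal = cfg.mode == "optimal"
    widths = [g.hidden_width for g in model.gene_nets]
    for _epoch in range(cfg.epochs):
        order = np.arange(n) if bs >= n else rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            blocks_b = [X[idx] for X in gene_blocks]
            h0_b = h0[idx]
            eta, _, gene_caches, stack_caches = _forward(
                model, blocks_b, h0_b, need_caches=True, train=optimal, drop_rng=rng
            )
            if not np.all(np.isfinite(eta)):
                raise RuntimeError("divergent training: non-finite predictions")
            m = len(idx)
            if model.outcome_type == "continuous":
                gout = 2.0 * (eta - y[idx]) / m
            else:
                gout = (sigmoid(eta) - y[idx]) / m
            grads: list[np.ndarray] = []
            if model.p:
                if cfg.interaction_scope == "between_genes":
                    s_grads, gF = model.stacks[0].backward(stack_caches[0], gout)
                    grads.extend(s_grads)
                    gene_grads_in = np.split(gF, np.cumsum(widths)[:-1], axis=1)
                else:
                    gene_grads_in = []
                    for s, c in zip(model.stacks, stack_caches):
                        s_grads, gh = s.backward(c, gout)
                        grads.extend(s_grads)
                        gene_grads_in.append(gh)
                if optimal:
                    for gnet, cache, gh in zip(model.gene_nets, gene_caches, gene_grads_in):
                        g_grads, _ = gnet.net.backward(cache, gh)
                        grads.extend(g_grads)
            grads.append(np.array([np.sum(gout * h0_b)]))
            if model.p == 0:
                grads.append(np.array([np.sum(gout)]))
            opt.step(grads)
    return model


def predict_components(
    model: TransferModel, gene_blocks: list[np.ndarray], h0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(gene-stack output, weighted background output) on the linear scale."""
    eta, gene_part = _forward(model, gene_blocks, h0)
    return gene_part, eta - gene_part


def predict(model: TransferModel, gene_blocks: list[np.ndarray], h0: np.ndarray) -> np.ndarray:
    """Predictions: real-valued for continuous outcomes, probabilities for binary."""
    if len(gene_blocks) != model.p:
        raise ValueError(f"expected {model.p} gene blocks, got {len(gene_blocks)}")
    for X, gnet in zip(gene_blocks, model.gene_nets):
        if X.shape[1] != len(gnet.input_mean):
            raise ValueError(f"gene {gnet.gene_id}: expected {len(gnet.input_mean)} variant columns")
    eta, _ = _forward(model, gene_blocks, h0)
    return sigmoid(eta) if model.outcome_type == "binary" else eta


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    screen: ScreenResult
    model: TransferModel
    background: BackgroundModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    predictions: np.ndarray
    background_test: np.ndarray
    metrics: dict[str, float]


def run_pipeline_modes(
    dataset,
    screen_cfg: NetworkConfig,
    transfer_cfgs: dict[str, TransferConfig],
    alpha: float = 0.001,
    K: int = 20,
    n_perm: int = 100,
    test_fraction: float = 0.25,
    seed: int = 0,
    refit_epochs: int | None = None,
) -> dict[str, PipelineResult]:
    """Run screening and background once, then fit one model per named config.

    Used to compare training modes (transfer vs optimal) on an identical
    split, selection and background fit.
    """
    from .evaluation import auc as _auc
    from .evaluation import pearson as _pearson
    from .io import GenotypeMatrix

    genotypes: GenotypeMatrix = dataset.genotypes
    phenotype: Phenotype = dataset.phenotype
    regions = dataset.regions
    n = genotypes.n_samples
    rng = derive_rng(seed, "split")
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])

    def subset(idx):
        return GenotypeMatrix(
            samples=[genotypes.samples[i] for i in idx],
            variants=list(genotypes.variants),
            dosages=genotypes.dosages[idx],
        )

    gm_train, gm_test = subset(train_idx), subset(test_idx)
    y_train = Phenotype(phenotype.values[train_idx], phenotype.outcome_type)
    y_test = phenotype.values[test_idx]

    screen = screen_genome(
        gm_train, regions, y_train, screen_cfg, K=K, n_perm=n_perm, alpha=alpha,
        refit_epochs=refit_epochs,
    )

    grm = compute_grm(gm_train)
    bg = fit_gblup(grm, y_train)
    h0_train = bg.h0_train  # cross-fitted: honest background strength in training
    h0_test = bg.predict(cross_grm(gm_test, grm))

    selected_regions = [r for r in regions if r.gene_id in screen.selected]
    blocks_train = [r.dosage_block(gm_train) for r in selected_regions]
    blocks_test = [r.dosage_block(gm_test) for r in selected_regions]

    results: dict[str, PipelineResult] = {}
    for name, transfer_cfg in transfer_cfgs.items():
        gene_nets = [
            _clone_gene_network(screen.networks[r.gene_id]) for r in selected_regions
        ]
        model = build_transfer_network(
            gene_nets, bg, transfer_cfg, outcome_type=phenotype.outcome_type
        )
        fit(model, blocks_train, h0_train, y_train)
        preds = predict(model, blocks_test, h0_test)
        metrics: dict[str, float] = {"n_selected": float(len(gene_nets))}
        if phenotype.outcome_type == "continuous":
            metrics["r"] = _pearson(y_test, preds) if np.ptp(preds) > 0 else 0.0
            metrics["r_background"] = _pearson(y_test, h0_test) if np.ptp(h0_test) > 0 else 0.0
        else:
            metrics["auc"] = _auc(y_test, preds)
            metrics["auc_background"] = _auc(y_test, h0_test)
        results[name] = PipelineResult(
            screen, model, bg, train_idx, test_idx, preds, h0_test, metrics
        )
    return results


def _clone_gene_network(gnet: GeneNetwork) -> GeneNetwork:
    """Deep-copy a gene network so optimal-mode retraining cannot leak across models."""
    net = FeedForward(list(gnet.net.sizes), seed=0, dropout_rate=gnet.net.dropout_rate)
    for p, q in zip(net.parameters, gnet.net.parameters):
        p[...] = q
    return GeneNetwork(
        gnet.gene_id, net, gnet.outcome_type,
        gnet.input_mean.copy(), gnet.input_scale.copy(), gnet.config,
    )


def run_pipeline(
    dataset,
    screen_cfg: NetworkConfig,
    transfer_cfg: TransferConfig,
    alpha: float = 0.001,
    K: int = 20,
    n_perm: int = 100,
    test_fraction: float = 0.25,
    seed: int = 0,
    refit_epochs: int | None = None,
) -> PipelineResult:
    """Screen genes, fit the background and the transfer model, score held-out data.

    ``dataset`` needs ``genotypes``, ``regions`` and ``phenotype`` attributes
    (a SimulatedDataset, or any object shaped like one). The held-out split,
    screening, gBLUP fit and network training all use only training rows.
    """
    return run_pipeline_modes(
        dataset,
        screen_cfg,
        {"model": transfer_cfg},
        alpha=alpha,
        K=K,
        n_perm=n_perm,
        test_fraction=test_fraction,
        seed=seed,
        refit_epochs=refit_epochs,
    )["model"]


# ---------------------------------------------------------------------------
# Model artifacts
# ---------------------------------------------------------------------------


def save_model(
    model: TransferModel,
    selected_regions,
    genotypes: GenotypeMatrix,
    out_dir,
) -> None:
    """Serialise the fitted model as a directory: manifest.json + weights.npz.

    The manifest records the architecture, modes, and the variant schema (per
    selected gene and for the background GRM) so predictions on new cohorts can
    align columns by variant id.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bg = model.background
    if bg is None or bg.grm.W is None:
        raise ValueError("model has no background with stored training W; cannot serialise")
    by_id = {r.gene_id: r for r in selected_regions}
    manifest = {
        "format": "dnnprs-transfer-model/1",
        "outcome_type": model.outcome_type,
        "mode": model.cfg.mode,
        "interaction_scope": model.cfg.interaction_scope,
        "stacked_hidden_sizes": list(model.cfg.stacked_hidden_sizes),
        "seed": model.cfg.seed,
        "genes": [
            {
                "gene_id": g.gene_id,
                "hidden_sizes": list(g.config.hidden_sizes),
                "dropout_rate": g.config.dropout_rate,
                "variant_ids": [
                    genotypes.variants[j].id for j in by_id[g.gene_id].variant_indices
                ],
            }
            for g in model.gene_nets
        ],
        "background": {
            "sigma_g2": bg.sigma_g2,
            "sigma_e2": bg.sigma_e2,
            "mu": bg.mu,
            "variant_ids": [genotypes.variants[j].id for j in bg.grm.kept_columns],
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    arrays: dict[str, np.ndarray] = {
        "gamma0": model.gamma0,
        "intercept": model.intercept,
        "bg_alpha": bg.alpha,
        "bg_W": bg.grm.W,
        "bg_freqs": bg.grm.freqs,
    }
    for s_idx, s in enumerate(model.stacks):
        for p_idx, p in enumerate(s.parameters):
            arrays[f"stack{s_idx}_p{p_idx}"] = p
    for g in model.gene_nets:
        for p_idx, p in enumerate(g.net.parameters):
            arrays[f"gene_{g.gene_id}_p{p_idx}"] = p
        arrays[f"gene_{g.gene_id}_mean"] = g.input_mean
        arrays[f"gene_{g.gene_id}_scale"] = g.input_scale
    np.savez(out / "weights.npz", **arrays)


def load_model(model_dir):
    """Load a serialised model; returns (TransferModel, manifest dict)."""
    import json
    from pathlib import Path

    from .background import GRM

    out = Path(model_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    arrays = np.load(out / "weights.npz")
    cfg = TransferConfig(
        stacked_hidden_sizes=tuple(manifest["stacked_hidden_sizes"]),
        mode=manifest["mode"],
        interaction_scope=manifest["interaction_scope"],
        seed=manifest["seed"],
    )
    gene_nets = []
    for g in manifest["genes"]:
        n_in = len(g["variant_ids"])
        net = FeedForward([n_in, *g["hidden_sizes"], 1], seed=0, dropout_rate=g["dropout_rate"])
        for p_idx, p in enumerate(net.parameters):
            p[...] = arrays[f"gene_{g['gene_id']}_p{p_idx}"]
        gene_nets.append(
            GeneNetwork(
                g["gene_id"],
                net,
                manifest["outcome_type"],
                arrays[f"gene_{g['gene_id']}_mean"],
                arrays[f"gene_{g['gene_id']}_scale"],
                NetworkConfig(hidden_sizes=tuple(g["hidden_sizes"]), dropout_rate=g["dropout_rate"]),
            )
        )
    bg_info = manifest["background"]
    W = arrays["bg_W"]
    grm = GRM(
        matrix=W @ W.T / W.shape[1],
        n_variants=W.shape[1],
        freqs=arrays["bg_freqs"],
        kept_columns=np.arange(W.shape[1]),
        W=W,
    )
    blups = bg_info["sigma_g2"] * (grm.matrix @ arrays["bg_alpha"])
    bg = BackgroundModel(
        sigma_g2=bg_info["sigma_g2"],
        sigma_e2=bg_info["sigma_e2"],
        mu=bg_info["mu"],
        blups=blups,
        h0_train=blups,  # loaded artifacts are used for prediction only
        alpha=arrays["bg_alpha"],
        grm=grm,
    )
    model = build_transfer_network(gene_nets, bg, cfg, outcome_type=manifest["outcome_type"])
    for s_idx, s in enumerate(model.stacks):
        for p_idx, p in enumerate(s.parameters):
            p[...] = arrays[f"stack{s_idx}_p{p_idx}"]
    model.gamma0[...] = arrays["gamma0"]
    model.intercept[...] = arrays["intercept"]
    return model, manifest
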