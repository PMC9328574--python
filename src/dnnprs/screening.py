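"""Gene-level screening via permutation-based group feature importance.

For each gene, a small multilayer perceptron is fitted to the phenotype from
that gene's dosages alone. Its predictive importance is the sum, over
held-out subjects, of the loss on the observed data minus the expected loss
when the gene's rows are randomly permuted across subjects:

    delta = sum_{i in D2} [ L(y_i, f(X_i)) - E L(y_i, f(X'_i)) ]

Row permutation breaks the genotype-phenotype link while preserving every
within-gene property (allele frequencies, LD), and the fitted network is
*reused* on permuted rows — no refitting — so the score costs only forward
passes. A predictive gene drives ``delta`` below zero; a null gene leaves it
centred at zero with an asymptotically normal distribution, estimated
empirically from the per-subject loss differences.

Chance splits are averaged out with K-fold cross-validation: per fold the
network trains on D1 and the score and its variance are evaluated on the
disjoint D2, and the fold statistics combine into a one-sided z-test of
H0: delta >= 0 (gene not predictive) against H1: delta < 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm
from sklearn.model_selection import KFold

from ._seeds import derive_seed
from .io import GenotypeMatrix, Phenotype
from .nn import FeedForward, per_sample_loss, train_network

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "GeneNetwork",
    "FoldScore",
    "ImportanceResult",
    "ScreenResult",
    "fit_gene_network",
    "permute_rows",
    "loss_difference",
    "fold_score",
    "group_importance",
    "screen_genome",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training settings for the per-gene networks."""

    hidden_sizes: tuple[int, ...] = (50, 10)
    dropout_rate: float = 0.5
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None: full batch up to 1024 rows, else 256
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if any(w <= 0 for w in self.hidden_sizes) or not self.hidden_sizes:
            raise ValueError("hidden_sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class GeneNetwork:
    """A fitted per-gene MLP with standardisation frozen at training time.

    ``transform`` (the last-hidden-layer map) and ``predict`` are
    deterministic: dropout is active only while training.
    """

    gene_id: str
    net: FeedForward
    outcome_type: str
    input_mean: np.ndarray
    input_scale: np.ndarray
    config: NetworkConfig

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.input_mean) / self.input_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear-head output (conditional mean / logit), shape (n,)."""
        return self.net.predict(self._standardise(X))

    def last_hidden(self, X: np.ndarray) -> np.ndarray:
        """The last-hidden-layer activation f_k^h(X_k; theta_k), shape (n, width)."""
        return self.net.last_hidden(self._standardise(X))

    @property
    def hidden_width(self) -> int:
        return self.net.sizes[-2]

    def checksum(self) -> float:
        return self.net.checksum()


@dataclass
class FoldScore:
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    delta: float
    var: float
    losses: np.ndarray  # per-subject loss differences l_i on the validation set


@dataclass
class ImportanceResult:
    gene_id: str
    n_variants: int
    fold_scores: list[FoldScore]
    delta: float
    se: float
    z: float
    p: float

    @property
    def K(self) -> int:
        return len(self.fold_scores)


@dataclass
class ScreenResult:
    results: list[ImportanceResult]
    selected: list[str]
    networks: dict[str, GeneNetwork]
    alpha: float


def fit_gene_network(
    X_k: np.ndarray,
    y: Phenotype | np.ndarray,
    cfg: NetworkConfig,
    outcome_type: str | None = None,
    gene_id: str = "gene",
) -> GeneNetwork:
    """Train one gene's MLP (dropout after the first hidden layer, Adam)."""
    if isinstance(y, Phenotype):
        outcome_type = y.outcome_type
        y = y.values
    if outcome_type is None:
        raise ValueError("outcome_type required when y is a plain array")
    X_k = np.asarray(X_k, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_k.ndim != 2 or X_k.shape[1] == 0:
        raise ValueError(f"gene {gene_id}: empty dosage block")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(y) == 0:
        raise ValueError(f"gene {gene_id}: constant phenotype, nothing to fit")
    mean = X_k.mean(axis=0)
    scale = X_k.std(axis=0)
    scale[scale < 1e-12] = 1.0
    net = FeedForward(
        [X_k.shape[1], *cfg.hidden_sizes, 1],
        seed=derive_seed(cfg.seed, "init", gene_id),
        dropout_rate=cfg.dropout_rate,
    )
    train_network(
        net,
        (X_k - mean) / scale,
        y,
        outcome_type,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        seed=derive_seed(cfg.seed, "train", gene_id),
    )
    return GeneNetwork(gene_id, net, outcome_type, mean, scale, cfg)


def permute_rows(X_k: np.ndarray, seed: int) -> np.ndarray:
    """Uniformly permute subject rows; columns (and hence LD) untouched."""
    rng = np.random.default_rng(seed)
    return np.asarray(X_k)[rng.permutation(len(X_k))]


def loss_difference(
    net: GeneNetwork,
    X_k: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject loss differences l_i on validation rows.

    The permutation expectation is a Monte-Carlo average over ``n_perm``
    independent row permutations of the validation block; the fitted network
    is evaluated as-is (no refit).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X_k = np.asarray(X_k, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = net.predict(X_k)  # row-wise model: permuting rows permutes predictions
    obs = per_sample_loss(preds, y, net.outcome_type)
    rng = np.random.default_rng(seed)
    perm_sum = np.zeros_like(obs)
    for _ in range(n_perm):
        pi = rng.permutation(len(y))
        perm_sum += per_sample_loss(preds[pi], y, net.outcome_type)
    return obs - perm_sum / n_perm


def fold_score(
    X_k: np.ndarray,
    y: np.ndarray,
    outcome_type: str,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: NetworkConfig,
    n_perm: int = 100,
    fold: int = 0,
    gene_id: str = "gene",
) -> FoldScore:
    """Fit on D1, score on D2: delta = sum l_i, var = |D2| * s^2(l_i)."""
    if len(val_idx) < 2:
        raise ValueError("validation fold too small (< 2 subjects)")
    net = fit_gene_network(
        X_k[train_idx],
        y[train_idx],
        replace(cfg, seed=derive_seed(cfg.seed, "fold", fold)),
        outcome_type=outcome_type,
        gene_id=gene_id,
    )
    losses = loss_difference(
        net,
        X_k[val_idx],
        y[val_idx],
        n_perm=n_perm,
        seed=derive_seed(cfg.seed, "perm", gene_id, fold),
    )
    delta = float(np.sum(losses))
    var = float(len(val_idx) * np.var(losses, ddof=1))
    return FoldScore(fold, train_idx, val_idx, delta, var, losses)


def group_importance(
    X_k: np.ndarray,
    y: Phenotype | np.ndarray,
    cfg: NetworkConfig,
    K: int = 20,
    n_perm: int = 100,
    outcome_type: str | None = None,
    gene_id: str = "gene",
) -> ImportanceResult:
    """K-fold aggregated importance score and its one-sided test.

    delta_k = mean of the fold scores, se^2 = (1/K^2) * sum of fold variances,
    z = delta_k / se, p = lower-tail standard-normal probability. A degenerate
    se of zero yields p = 1 (no predictive evidence).
    """
    if isinstance(y, Phenotype):
        outcome_type = y.outcome_type
        y = y.values
    if outcome_type is None:
        raise ValueError("outcome_type required when y is a plain array")
    X_k = np.asarray(X_k, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < 2 * K:
        raise ValueError(f"n={n} too small for K={K} folds")
    kf = KFold(n_splits=K, shuffle=True, random_state=derive_seed(cfg.seed, "folds", gene_id))
    scores = [
        fold_score(X_k, y, outcome_type, tr, va, cfg, n_perm=n_perm, fold=i, gene_id=gene_id)
        for i, (tr, va) in enumerate(kf.split(X_k))
    ]
    delta = float(np.mean([s.delta for s in scores]))
    se = float(np.sqrt(sum(s.var for s in scores)) / K)
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = delta / se
        p = float(norm.cdf(z))
    return ImportanceResult(gene_id, X_k.shape[1], scores, delta, se, z, p)


def screen_genome(
    genotypes: GenotypeMatrix,
    regions,
    phenotype: Phenotype,
    cfg: NetworkConfig,
    K: int = 20,
    n_perm: int = 100,
    alpha: float = 0.001,
    refit_epochs: int | None = None,
) -> ScreenResult:
    """Score every region; select p < alpha; refit one network per selection.

    The refit network (full training data, same architecture, a fixed derived
    seed) is the pre-trained model carried into the transfer architecture;
    ``refit_epochs`` lets it train longer than the fold networks, whose length
    only needs to support the calibrated test.
    """
    results: list[ImportanceResult] = []
    networks: dict[str, GeneNetwork] = {}
    selected: list[str] = []
    for region in regions:
        X_k = region.dosage_block(genotypes)
        res = group_importance(
            X_k,
            phenotype,
            replace(cfg, seed=derive_seed(cfg.seed, "screen", region.gene_id)),
            K=K,
            n_perm=n_perm,
            gene_id=region.gene_id,
        )
        results.append(res)
        if res.p < alpha:
            selected.append(region.gene_id)
            refit_cfg = replace(
                cfg,
                seed=derive_seed(cfg.seed, "refit", region.gene_id),
                epochs=refit_epochs or cfg.epochs,
            )
            networks[region.gene_id] = fit_gene_network(X_k, phenotype, refit_cfg, gene_id=region.gene_id)
    logger.info("screened %d regions, selected %d at alpha=%g", len(results), len(selected), alpha)
    return ScreenResult(results, selected, networks, alpha)
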