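"""Metrics and the Monte-Carlo experiment harness.

Prediction accuracy is summarised by the Pearson correlation between observed
and predicted values (continuous traits) and the area under the ROC curve
(binary traits). The experiment drivers re-run the gene-screening test over
many independently simulated datasets to estimate its type-I error on null
genes and its power per causal-gene role, with binomial Monte-Carlo standard
errors. A one-degree-of-freedom regression on the per-gene dosage sum is
included as a linear comparison test for the power runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._seeds import derive_seed
from .screening import NetworkConfig, group_importance
from .simulate import SimulationSpec, simulate_dataset

__all__ = [
    "pearson",
    "auc",
    "ExperimentReport",
    "typeI_error_experiment",
    "power_experiment",
    "linear_sum_score_pvalue",
    "linear_ftest_pvalue",
]


def pearson(y_true, y_pred) -> float:
    """Product-moment correlation; errors on constant or too-short inputs."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def auc(y_true, scores) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted half)."""
    y_true = np.asarray(y_true, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


@dataclass
class ExperimentReport:
    scenario: str
    n_replicates: int
    seeds: list[int]
    table: pd.DataFrame  # rows: (gene role or label) x alpha; rejection rate + SE
    pvalues: dict[str, np.ndarray] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @staticmethod
    def proportion_se(rate: float, reps: int) -> float:
        return float(np.sqrt(rate * (1.0 - rate) / reps))


def _rejection_table(pvals: dict[str, np.ndarray], alphas, reps: int) -> pd.DataFrame:
    rows = []
    for label, p in pvals.items():
        for a in alphas:
            rate = float(np.mean(p < a))
            rows.append(
                {
                    "label": label,
                    "alpha": a,
                    "rejection_rate": rate,
                    "se": ExperimentReport.proportion_se(rate, reps),
                }
            )
    return pd.DataFrame(rows)


def typeI_error_experiment(
    spec: SimulationSpec,
    alphas=(0.05, 0.01),
    reps: int = 500,
    cfg: NetworkConfig | None = None,
    K: int = 5,
    n_perm: int = 100,
    seed: int = 0,
    max_null_genes: int = 1,
) -> ExperimentReport:
    """Rejection rate of the screening test on null genes over ``reps`` datasets.

    Each replicate simulates a fresh dataset from ``spec`` (reseeded), runs the
    K-fold importance test on up to ``max_null_genes`` null genes, and records
    the one-sided p-values.
    """
    cfg = cfg or NetworkConfig()
    null_ids = [g.gene_id for g in spec.genes if g.role == "null"]
    if not null_ids:
        raise ValueError("spec contains no null gene")
    null_ids = null_ids[:max_null_genes]
    pvals: list[float] = []
    seeds = []
    from dataclasses import replace as _replace

    for r in range(reps):
        rep_seed = derive_seed(seed, "rep", r)
        seeds.append(rep_seed)
        ds = simulate_dataset(_replace(spec, seed=rep_seed))
        by_id = {reg.gene_id: reg for reg in ds.regions}
        for gid in null_ids:
            res = group_importance(
                by_id[gid].dosage_block(ds.genotypes),
                ds.phenotype,
                _replace(cfg, seed=derive_seed(seed, "cfg", r, gid)),
                K=K,
                n_perm=n_perm,
                gene_id=gid,
            )
            pvals.append(res.p)
    p = np.array(pvals)
    report = ExperimentReport(
        scenario=f"typeI_{spec.link}",
        n_replicates=len(p),
        seeds=seeds,
        table=_rejection_table({"null": p}, alphas, len(p)),
        pvalues={"null": p},
        config={"K": K, "n_perm": n_perm, "epochs": cfg.epochs, "n": spec.n},
    )
    return report


def linear_sum_score_pvalue(X_k: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value of the 1-df regression of y on the gene's dosage sum."""
    s = np.asarray(X_k, dtype=float).sum(axis=1)
    if np.ptp(s) == 0:
        return 1.0
    return float(stats.pearsonr(s, np.asarray(y, dtype=float)).pvalue)


def linear_ftest_pvalue(X_k: np.ndarray, y: np.ndarray) -> float:
    """Gene-level linear-model F-test: y ~ all variant dosages jointly.

    The canonical linear set-based comparison: full power against any additive
    per-variant signal, diluted over n_k degrees of freedom, and blind to
    effects orthogonal to the linear span of the dosages.
    """
    X_k = np.asarray(X_k, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = np.column_stack([np.ones(n), X_k])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    k = rank - 1  # model df excluding the intercept
    if k < 1 or n - rank < 1:
        return 1.0
    rss1 = float(np.sum((y - design @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    f = ((rss0 - rss1) / k) / (rss1 / (n - rank))
    return float(stats.f.sf(f, k, n - rank))


def power_experiment(
    spec: SimulationSpec,
    alphas=(0.05,),
    reps: int = 50,
    cfg: NetworkConfig | None = None,
    K: int = 5,
    n_perm: int = 100,
    seed: int = 0,
    include_linear_oracle: bool = True,
) -> ExperimentReport:
    """Per-role rejection rates on causal genes, with an optional linear-test arm."""
    cfg = cfg or NetworkConfig()
    causal = [g for g in spec.genes if g.role != "null"]
    if not causal:
        raise ValueError("spec contains no causal gene")
    pvals: dict[str, list[float]] = {g.role: [] for g in causal}
    if include_linear_oracle:
        pvals.update({f"{g.role}_sumscore": [] for g in causal})
        pvals.update({f"{g.role}_ftest": [] for g in causal})
    seeds = []
    from dataclasses import replace as _replace

    for r in range(reps):
        rep_seed = derive_seed(seed, "rep", r)
        seeds.append(rep_seed)
        ds = simulate_dataset(_replace(spec, seed=rep_seed))
        by_id = {reg.gene_id: reg for reg in ds.regions}
        for g in causal:
            X_k = by_id[g.gene_id].dosage_block(ds.genotypes)
            res = group_importance(
                X_k,
                ds.phenotype,
                _replace(cfg, seed=derive_seed(seed, "cfg", r, g.gene_id)),
                K=K,
                n_perm=n_perm,
                gene_id=g.gene_id,
            )
            pvals[g.role].append(res.p)
            if include_linear_oracle:
                pvals[f"{g.role}_sumscore"].append(
                    linear_sum_score_pvalue(X_k, ds.phenotype.values)
                )
                pvals[f"{g.role}_ftest"].append(
                    linear_ftest_pvalue(X_k, ds.phenotype.values)
                )
    arrays = {k: np.array(v) for k, v in pvals.items()}
    return ExperimentReport(
        scenario=f"power_{spec.link}",
        n_replicates=reps,
        seeds=seeds,
        table=_rejection_table(arrays, alphas, reps),
        pvalues=arrays,
        config={"K": K, "n_perm": n_perm, "epochs": cfg.epochs, "n": spec.n},
    )
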