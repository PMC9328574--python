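"""Genomic BLUP: the infinitesimal-effects background.

The background node of the prediction network is a per-subject genetic value
from a mixed model y = mu + g + e with g ~ N(0, sigma_g^2 G), where G is the
genomic relationship matrix from standardised dosages, G = W W' / m with
W_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)).

Variance components are estimated by profile REML: a single eigendecomposition
of G reduces the restricted likelihood to a bounded one-dimensional function of
the heritability h = sigma_g^2 / (sigma_g^2 + sigma_e^2), maximised
numerically; the total variance has a closed-form profile. BLUPs for training
samples and predictions for held-out samples (via the cross-relationship with
training samples) then follow from the usual mixed-model algebra. Held-out
predictions never touch held-out phenotypes.

Binary outcomes are handled on the observed 0/1 scale (linear mixed model),
the standard observed-scale GREML practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .io import GenotypeMatrix, Phenotype

logger = logging.getLogger(__name__)

__all__ = ["GRM", "BackgroundModel", "compute_grm", "cross_grm", "fit_gblup", "read_gcta_grm"]


@dataclass
class GRM:
    """Genomic relationship matrix plus the standardisation it was built with."""

    matrix: np.ndarray
    n_variants: int
    freqs: np.ndarray  # alt-allele frequencies of the retained variants
    kept_columns: np.ndarray  # column indices into the source dosage matrix
    W: np.ndarray | None = None  # standardised training dosages (for cross-GRMs)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BackgroundModel:
    """Fitted gBLUP model: variance components and prediction machinery.

    ``blups`` are the in-sample genetic values for training subjects;
    ``h0_train`` are their leave-one-out cross-fitted counterparts (each
    subject's value predicted without its own phenotype), which is what the
    transfer network consumes as the background node during training — an
    in-sample BLUP is over-optimistic about the background's predictive value
    and would starve the gene stack of signal. ``alpha`` is V^{-1}(y - mu),
    from which a new sample's value is sigma_g^2 * G_cross @ alpha.
    """

    sigma_g2: float
    sigma_e2: float
    mu: float
    blups: np.ndarray
    h0_train: np.ndarray
    alpha: np.ndarray
    grm: GRM

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0

    def predict(self, grm_cross: np.ndarray) -> np.ndarray:
        """Genetic values for new samples from their cross-GRM rows."""
        return self.sigma_g2 * grm_cross @ self.alpha


def _standardise(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dos = genotypes.dosages
    if np.isnan(dos).any():
        raise ValueError("impute missing genotypes before computing the GRM")
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all variants are monomorphic; GRM undefined")
    if (~poly).any():
        logger.warning("dropping %d monomorphic variant(s) from the GRM", int((~poly).sum()))
    kept = np.flatnonzero(poly)
    pk = p[kept]
    W = (dos[:, kept] - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    return W, pk, kept


def compute_grm(genotypes: GenotypeMatrix, keep_W: bool = True) -> GRM:
    """G = W W' / m from standardised dosages; monomorphic columns dropped."""
    if genotypes.n_samples < 2:
        raise ValueError("need at least 2 samples")
    W, pk, kept = _standardise(genotypes)
    m = W.shape[1]
    return GRM(W @ W.T / m, m, pk, kept, W=W if keep_W else None)


def cross_grm(genotypes_new: GenotypeMatrix, grm: GRM) -> np.ndarray:
    """Relationships of new samples (rows) with the training samples.

    New dosages are standardised with the *training* allele frequencies.
    """
    if grm.W is None:
        raise ValueError("GRM was built without keep_W; cannot form cross-relationships")
    dos = genotypes_new.dosages[:, grm.kept_columns]
    if np.isnan(dos).any():
        raise ValueError("impute missing genotypes before computing the cross-GRM")
    p = grm.freqs
    W_new = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return W_new @ grm.W.T / grm.n_variants


def fit_gblup(grm: GRM, y: Phenotype | np.ndarray, tol: float = 1e-10) -> BackgroundModel:
    """Estimate (sigma_g^2, sigma_e^2) by profile REML and compute BLUPs."""
    if isinstance(y, Phenotype):
        y = y.values
    y = np.asarray(y, dtype=float)
    n = grm.n
    if len(y) != n:
        raise ValueError(f"phenotype length {len(y)} != GRM size {n}")
    d, U = np.linalg.eigh(grm.matrix)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)

    def neg_restricted_ll(h: float) -> float:
        v = h * d + (1.0 - h)  # eigenvalues of V / sigma_t^2
        quad_mu = np.sum(ones_t**2 / v)
        mu = np.sum(ones_t * yt / v) / quad_mu
        r = yt - mu * ones_t
        rss = np.sum(r**2 / v)
        sigma_t2 = rss / (n - 1)
        return 0.5 * ((n - 1) * np.log(sigma_t2) + np.sum(np.log(v)) + np.log(quad_mu))

    res = minimize_scalar(
        neg_restricted_ll, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(f"REML optimisation failed: {res.message}")
    h = float(res.x)
    v = h * d + (1.0 - h)
    quad_mu = np.sum(ones_t**2 / v)
    mu = float(np.sum(ones_t * yt / v) / quad_mu)
    r = yt - mu * ones_t
    sigma_t2 = float(np.sum(r**2 / v) / (n - 1))
    sigma_g2 = h * sigma_t2
    sigma_e2 = (1.0 - h) * sigma_t2
    # alpha = V^{-1}(y - mu);  BLUP g_hat = sigma_g^2 G alpha
    alpha = U @ (r / (sigma_t2 * v))
    blups = sigma_g2 * (grm.matrix @ alpha)
    # leave-one-out cross-fitted values (Gaussian-process LOO identity):
    # h0_i = (y_i - mu) - alpha_i / [V^{-1}]_ii
    vinv_diag = (U**2) @ (1.0 / (sigma_t2 * v))
    h0_train = (y - mu) - alpha / vinv_diag
    return BackgroundModel(sigma_g2, sigma_e2, mu, blups, h0_train, alpha, grm)


# ---------------------------------------------------------------------------
# GCTA binary GRM import / BLUP export
# ---------------------------------------------------------------------------


def read_gcta_grm(prefix: str | Path) -> GRM:
    """Read a GCTA binary GRM (``.grm.bin``/``.grm.N.bin``/``.grm.id``)."""
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    vals = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(float)
    if vals.size != n * (n + 1) // 2:
        raise ValueError("GRM bin length does not match id count")
    G = np.zeros((n, n))
    iu = np.tril_indices(n)
    G[iu] = vals
    G = G + G.T - np.diag(np.diag(G))
    nbin = Path(prefix + ".grm.N.bin")
    m = int(np.fromfile(nbin, dtype=np.float32)[0]) if nbin.exists() else 0
    return GRM(G, m, np.empty(0), np.empty(0, dtype=int), W=None)


def write_blups(model: BackgroundModel, samples, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tblup\n")
        for s, g in zip(samples, model.blups):
            fh.write(f"{s}\t{float(g)!r}\n")
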