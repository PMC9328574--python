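"""Synthetic genotype/phenotype generation.

Genotypes are drawn from a Gaussian-copula haplotype model: within each gene,
two latent haplotype vectors follow a multivariate normal with AR(1)
correlation ``ld_decay**|i-j|``, thresholded at each variant's minor-allele
frequency, and summed to a {0,1,2} dosage. Genes are mutually independent.
This surrogate preserves the one property the screening statistic exploits in
real panels: within-gene LD structure that is invariant under row permutation.

Phenotypes follow a four-term mean model over designated causal genes —

* ``linear90`` / ``linear10``: additive effects on a random 90% / 10% causal
  subset of the gene's variants with N(0, sigma_k^2) weights,
* ``interaction``: a squared dosage-sum term (pairwise products),
* ``cosine``: cosine of the dosage sum (radians, unscaled),

each gated by an indicator switch, with either Gaussian noise added to the
mean (continuous trait) or a Bernoulli draw through a logistic link (binary
trait). Per-gene effect magnitudes are parameterised by target signal
fractions — the share of outcome variance each active term contributes — since
that is the quantity the downstream power and prediction experiments control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from ._seeds import derive_rng
from .io import GeneRegion, GenotypeMatrix, Phenotype, Variant
from .nn import sigmoid

__all__ = [
    "GeneSpec",
    "EffectScales",
    "SimulationSpec",
    "GeneTruth",
    "SimulatedDataset",
    "standard_panel",
    "make_disease_model",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "add_noise_genes",
    "evaluate_mean_model",
]

ROLES = ("linear90", "linear10", "interaction", "cosine", "null")
ROLE_SWITCH = {"linear90": 0, "linear10": 1, "interaction": 2, "cosine": 3}
LOGISTIC_VAR = np.pi**2 / 3.0  # residual variance of the logistic link


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    n_k: int
    role: str = "null"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown gene role {self.role!r}")
        if self.n_k < 1:
            raise ValueError("n_k must be >= 1")


@dataclass(frozen=True)
class EffectScales:
    """Raw effect magnitudes, used when no signal fraction is requested."""

    sigma1: float = 0.5  # sd of per-variant weights, 90%-causal linear gene
    sigma2: float = 0.5  # sd of per-variant weights, 10%-causal linear gene
    beta3: float = 0.1  # coefficient on the squared dosage sum
    beta4: float = 1.0  # coefficient on the cosine term


@dataclass(frozen=True)
class SimulationSpec:
    n: int
    genes: tuple[GeneSpec, ...]
    switches: tuple[int, int, int, int] = (1, 1, 1, 1)
    causal_fractions: tuple[float, float] = (0.9, 0.1)  # linear90, linear10
    effect_scales: EffectScales = field(default_factory=EffectScales)
    signal_fraction: float | None = 0.1  # per active causal gene; None = raw scales
    noise_sd: float = 1.0
    link: str = "gaussian"  # gaussian | logistic
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.n < 2:
            raise ValueError("n must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.link not in ("gaussian", "logistic"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "gaussian" and self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 for the gaussian link")
        if any(not 0.0 < f <= 1.0 for f in self.causal_fractions):
            raise ValueError("causal fractions must be in (0, 1]")

    def active_roles(self) -> list[str]:
        return [r for r, j in ROLE_SWITCH.items() if self.switches[j]]


@dataclass(frozen=True)
class GeneTruth:
    """Per-gene ground truth: causal status and the term's exact coefficients.

    The gene's contribution to the mean is
    ``scale * (raw_term - center)`` where ``raw_term`` is the role's formula
    applied to the stored ``phi``/``betas`` (linear roles) or the dosage sum
    (nonlinear roles).
    """

    gene_id: str
    role: str
    causal: bool
    variant_causal: np.ndarray
    phi: np.ndarray | None = None
    betas: np.ndarray | None = None
    scale: float = 1.0
    center: float = 0.0


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    regions: list[GeneRegion]
    phenotype: Phenotype
    truth: list[GeneTruth]
    mu: np.ndarray
    spec: SimulationSpec


def standard_panel(
    n: int,
    n_noise: int = 6,
    n_k: int = 20,
    link: str = "gaussian",
    seed: int = 0,
    signal_fraction: float | None = 0.1,
    switches: tuple[int, int, int, int] = (1, 1, 1, 1),
    **kwargs,
) -> SimulationSpec:
    """The study panel: four causal genes (one per role) plus noise genes."""
    genes = [
        GeneSpec("g1_linear90", n_k, "linear90"),
        GeneSpec("g2_linear10", n_k, "linear10"),
        GeneSpec("g3_interaction", n_k, "interaction"),
        GeneSpec("g4_cosine", n_k, "cosine"),
    ] + [GeneSpec(f"noise{i + 1}", n_k, "null") for i in range(n_noise)]
    return SimulationSpec(
        n=n,
        genes=tuple(genes),
        link=link,
        seed=seed,
        signal_fraction=signal_fraction,
        switches=switches,
        **kwargs,
    )


def make_disease_model(scenario: str, spec: SimulationSpec) -> SimulationSpec:
    """Set the indicator switches for a named disease model.

    S1: linear effects only; S2: non-linear effects only; S3: both.
    """
    table = {"S1": (1, 1, 0, 0), "S2": (0, 0, 1, 1), "S3": (1, 1, 1, 1)}
    if scenario not in table:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(table)}")
    return replace(spec, switches=table[scenario])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _simulate_gene_dosages(
    n: int, n_k: int, maf_range: tuple[float, float], ld_decay: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage block (n x n_k) and the per-variant MAFs used."""
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_k)
    thresholds = norm.ppf(mafs)
    if ld_decay > 0:
        idx = np.arange(n_k)
        corr = ld_decay ** np.abs(idx[:, None] - idx[None, :])
        chol = np.linalg.cholesky(corr)
    else:
        chol = None
    dos = np.zeros((n, n_k))
    for _hap in range(2):
        z = rng.standard_normal((n, n_k))
        if chol is not None:
            z = z @ chol.T
        dos += z < thresholds
    return dos, mafs


def simulate_genotypes(spec: SimulationSpec) -> tuple[GenotypeMatrix, list[GeneRegion]]:
    """Draw the full genotype panel; genes are independent, seeded per gene."""
    blocks: list[np.ndarray] = []
    variants: list[Variant] = []
    regions: list[GeneRegion] = []
    col = 0
    for g_idx, gene in enumerate(spec.genes):
        rng = derive_rng(spec.seed, "geno", gene.gene_id)
        dos, _ = _simulate_gene_dosages(spec.n, gene.n_k, spec.maf_range, spec.ld_decay, rng)
        blocks.append(dos)
        base = (g_idx + 1) * 100_000
        for j in range(gene.n_k):
            variants.append(
                Variant(id=f"{gene.gene_id}_v{j + 1}", chrom="1", pos=base + j * 10)
            )
        regions.append(
            GeneRegion(gene_id=gene.gene_id, variant_indices=np.arange(col, col + gene.n_k))
        )
        col += gene.n_k
    samples = [f"S{i + 1}" for i in range(spec.n)]
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=np.hstack(blocks))
    return gm, regions


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------


def _raw_term(role: str, X: np.ndarray, truth_phi, truth_betas, scales: EffectScales) -> np.ndarray:
    if role in ("linear90", "linear10"):
        return X[:, truth_phi] @ truth_betas
    if role == "interaction":
        return scales.beta3 * X.sum(axis=1) ** 2
    if role == "cosine":
        return scales.beta4 * np.cos(X.sum(axis=1))
    raise ValueError(role)


def evaluate_mean_model(
    genotypes: GenotypeMatrix, regions: list[GeneRegion], truth: list[GeneTruth],
    scales: EffectScales = EffectScales(),
) -> np.ndarray:
    """Recompute the latent mean from stored ground truth (term by term)."""
    mu = np.zeros(genotypes.n_samples)
    by_id = {r.gene_id: r for r in regions}
    for t in truth:
        if not t.causal:
            continue
        X = by_id[t.gene_id].dosage_block(genotypes)
        raw = _raw_term(t.role, X, t.phi, t.betas, scales)
        mu += t.scale * (raw - t.center)
    return mu


def simulate_phenotype(
    genotypes: GenotypeMatrix, regions: list[GeneRegion], spec: SimulationSpec
) -> tuple[Phenotype, np.ndarray, list[GeneTruth]]:
    """Generate the outcome per the four-term mean model and the chosen link."""
    by_id = {r.gene_id: r for r in regions}
    for gene in spec.genes:
        j = ROLE_SWITCH.get(gene.role)
        if j is not None and spec.switches[j] and gene.gene_id not in by_id:
            raise ValueError(f"role {gene.role} requires region {gene.gene_id} in regions")
    scales = spec.effect_scales
    frac_lin = dict(zip(("linear90", "linear10"), spec.causal_fractions))

    raw_terms: list[tuple[GeneSpec, np.ndarray, np.ndarray | None, np.ndarray | None]] = []
    truth: list[GeneTruth] = []
    for gene in spec.genes:
        j = ROLE_SWITCH.get(gene.role)
        active = j is not None and bool(spec.switches[j])
        if not active:
            truth.append(
                GeneTruth(gene.gene_id, gene.role, False, np.zeros(gene.n_k, dtype=bool))
            )
            continue
        X = by_id[gene.gene_id].dosage_block(genotypes)
        phi = betas = None
        if gene.role in ("linear90", "linear10"):
            frac = frac_lin[gene.role]
            n_causal = max(1, int(round(frac * gene.n_k)))
            rng_phi = derive_rng(spec.seed, "phi", gene.gene_id)
            phi = np.sort(rng_phi.choice(gene.n_k, size=n_causal, replace=False))
            rng_beta = derive_rng(spec.seed, "beta", gene.gene_id)
            sigma = scales.sigma1 if gene.role == "linear90" else scales.sigma2
            betas = rng_beta.normal(0.0, sigma, size=n_causal)
        raw = _raw_term(gene.role, X, phi, betas, scales)
        raw_terms.append((gene, raw, phi, betas))

    n_active = len(raw_terms)
    mu = np.zeros(spec.n)
    if spec.signal_fraction is not None and n_active:
        total_frac = spec.signal_fraction * n_active
        if total_frac >= 1.0:
            raise ValueError("total signal fraction must be < 1")
        resid_var = spec.noise_sd**2 if spec.link == "gaussian" else LOGISTIC_VAR
        var_y = resid_var / (1.0 - total_frac)
        target = spec.signal_fraction * var_y
    for gene, raw, phi, betas in raw_terms:
        if spec.signal_fraction is not None:
            center = float(np.mean(raw))
            v = float(np.var(raw))
            scale = np.sqrt(target / v) if v > 0 else 0.0
        else:
            center, scale = 0.0, 1.0
        mask = np.zeros(gene.n_k, dtype=bool)
        if phi is not None:
            mask[phi] = True
        else:
            mask[:] = True
        truth.append(
            GeneTruth(gene.gene_id, gene.role, True, mask, phi, betas, scale, center)
        )
        mu += scale * (raw - center)
    # restore spec gene order in truth
    order = {g.gene_id: i for i, g in enumerate(spec.genes)}
    truth.sort(key=lambda t: order[t.gene_id])

    rng_noise = derive_rng(spec.seed, "outcome")
    if spec.link == "gaussian":
        y = mu + rng_noise.normal(0.0, spec.noise_sd, size=spec.n)
        pheno = Phenotype(values=y, outcome_type="continuous")
    else:
        p = sigmoid(mu)
        y = (rng_noise.random(spec.n) < p).astype(float)
        pheno = Phenotype(values=y, outcome_type="binary")
    return pheno, mu, truth


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Genotypes, regions, phenotype and ground truth, all from ``spec.seed``."""
    gm, regions = simulate_genotypes(spec)
    pheno, mu, truth = simulate_phenotype(gm, regions, spec)
    return SimulatedDataset(gm, regions, pheno, truth, mu, spec)


def add_noise_genes(dataset: SimulatedDataset, count: int) -> SimulatedDataset:
    """Append ``count`` null genes, generated independently of the phenotype."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return dataset
    spec = dataset.spec
    existing = {g.gene_id for g in spec.genes}
    n_k = spec.genes[-1].n_k if spec.genes else 20
    new_specs = []
    i = 0
    while len(new_specs) < count:
        i += 1
        gid = f"extra_noise{i}"
        if gid not in existing:
            new_specs.append(GeneSpec(gid, n_k, "null"))
    blocks = [dataset.genotypes.dosages]
    variants = list(dataset.genotypes.variants)
    regions = list(dataset.regions)
    truth = list(dataset.truth)
    col = dataset.genotypes.n_variants
    base_offset = (len(spec.genes) + 1) * 100_000
    for k, gene in enumerate(new_specs):
        rng = derive_rng(spec.seed, "geno", gene.gene_id)
        dos, _ = _simulate_gene_dosages(spec.n, gene.n_k, spec.maf_range, spec.ld_decay, rng)
        blocks.append(dos)
        base = base_offset + k * 100_000
        for j in range(gene.n_k):
            variants.append(Variant(id=f"{gene.gene_id}_v{j + 1}", chrom="1", pos=base + j * 10))
        regions.append(GeneRegion(gene.gene_id, np.arange(col, col + gene.n_k)))
        truth.append(GeneTruth(gene.gene_id, "null", False, np.zeros(gene.n_k, dtype=bool)))
        col += gene.n_k
    gm = GenotypeMatrix(
        samples=list(dataset.genotypes.samples), variants=variants, dosages=np.hstack(blocks)
    )
    new_spec = replace(spec, genes=tuple(list(spec.genes) + new_specs))
    return SimulatedDataset(gm, regions, dataset.phenotype, truth, dataset.mu, new_spec)
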