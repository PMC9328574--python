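# Methods

`dnnprs` implements a two-stage framework for building polygenic risk scores
(PRS) from high-dimensional genotype data: a gene-level screening test built
on a permutation-based group feature importance score, followed by a
transfer-learning prediction network that combines the screened genes'
pretrained subnetworks with a genomic-BLUP background.

## 1. Gene-level screening (DNN-screen)

For each gene region *k* with dosage block X_k (n subjects × n_k variants) a
small multilayer perceptron f_k is fitted to the outcome from that gene alone.
The gene's predictive importance on held-out subjects D2 is

    Δ_k = Σ_{i∈D2} l_i,   l_i = L(y_i, f_k(X_ik)) − E[ L(y_i, f_k(X'_ik)) ],

where X' is the dosage block with subject rows randomly permuted and L is
squared error (continuous traits) or cross entropy (binary traits). Row
permutation destroys any genotype–phenotype association while leaving every
within-gene property — allele frequencies, linkage disequilibrium — exactly
intact, and the permuted data are scored with the *already fitted* network, so
no refitting is ever required. A predictive gene makes the observed loss
systematically smaller than the permuted loss, pushing Δ_k negative.

The permutation expectation is approximated by averaging over `n_perm`
independent row permutations (default 100); this is pure forward evaluation
and costs a few milliseconds per fold.

**Test statistic.** A single train/validation split is subject to chance, so
the score is aggregated over a K-fold partition: per fold the network trains
on D1 and yields Δ_ik and an empirical variance σ_ik² = |D2|·s²(l_i) on the
disjoint D2. The overall statistic

    Δ_k = (1/K) Σ_i Δ_ik,   se² = (1/K²) Σ_i σ_ik²,   z = Δ_k / se

is treated as standard normal under H0: Δ_k ≥ 0 (gene not predictive), and
the reported p-value is the lower-tail probability. The fold statistics are
combined as if independent — exactly the variance formula above — and a
degenerate se = 0 (e.g. a constant network) maps to p = 1. K defaults to 20;
the simulation harnesses here use K = 5, which pilot calibration at desk
scale showed to be equally well calibrated at a fifth of the cost.

Averaging the permutation term over shared permutations couples the l_i
across subjects (each prediction is used exactly once per permutation), a
negative dependence the iid variance estimator ignores. The null z-statistic
is therefore mildly under-dispersed (simulated sd ≈ 0.85-0.9), making the
test slightly conservative at nominal levels — e.g. rejection ≈ 0.02-0.03 at
the 5% level for a continuous outcome at n = 1000 — while the overall
p-value distribution stays close to uniform. Fewer permutations make this
worse, not better, so the default of 100 stands.

**Per-gene network.** Two hidden ReLU layers of 50 and 10 units, a linear
output head (a logistic transform is applied outside for binary traits),
inverted dropout with rate 0.5 after the first hidden layer, Adam at learning
rate 10⁻³, 100 epochs by default; full-batch updates for ≤1024 training rows,
minibatches of 256 otherwise. Inputs are standardised per variant using
training-set statistics. The engine is a compact numpy implementation with
analytic backpropagation, verified against finite differences in the test
suite. All stochastic stages — weight initialisation, dropout masks,
minibatch order, fold partition, permutations — consume named child seeds
derived from one master seed (crc32-tagged `SeedSequence` fan-out), so any
stage can be replayed in isolation and all results are bitwise reproducible.

**Selection.** Genes with p < α (default 0.001, the threshold recommended for
whole-exome-scale panels of ~20 000 regions) are selected, and one network per
selected gene is refitted on the full training split with a fixed derived
seed; that refit network is the pretrained model carried into the prediction
stage. (The K fold-networks are discarded; carrying one refit model forward
keeps a single f_k per gene.)

## 2. Prediction model (DNN-transfer)

The prediction network is additive on the linear-predictor scale:

    E(Y|X) = g(f_1^h(X_1;θ_1), …, f_p^h(X_p;θ_p); γ_1) + γ_0 · h0′

* f_k^h — the last-hidden-layer transform (width 10) of gene k's pretrained
  network; θ_k frozen in transfer mode.
* g — newly added fully-connected stack, hidden widths (100, 10), trained.
* h0′ — the background node: a per-subject gBLUP genetic value capturing the
  infinitesimal additive effects of *all* variants, entering through the
  single scalar weight γ_0 (trained jointly with γ_1 by gradient descent).

For binary outcomes the sum passes through a logistic link so both components
live on one scale. Two wiring variants exist: `between_genes` (default)
concatenates all gene hidden layers into one stack, allowing gene interplay;
`within_genes_only` gives each gene a private stack whose scalar outputs are
summed, for the no-between-gene-interaction structure.

**Modes.** `transfer` trains only (γ_0, γ_1) — for p genes of width 10 and
the default stack this is (10p·100+100) + (100·10+10) + 11 + 1 trainable
weights (5122 at p = 4) — while θ stays bitwise frozen. `optimal` retrains
everything (θ included) as the fully tuned comparison; its trainable count is
the transfer count plus the frozen θ count. In optimal mode the per-gene
dropout layers stay active during retraining, because the architecture being
retrained is the screened architecture, dropout included.

**Initialisation at the gBLUP limit.** The stack's output layer is zero-
initialised and γ_0 starts at 1, so the untrained model *is* the gBLUP
predictor and the gene component grows only where the gradient finds signal.
With a randomly initialised head, the stack's initial output is noise of
order one, which measurably degrades early joint training.

**Cross-fitted background.** For held-out subjects h0′ is predicted from
training data via the cross-relationship matrix, never touching held-out
phenotypes. For *training* subjects the network consumes the leave-one-out
cross-fitted value (closed form from the mixed-model algebra,
h0_i = (y_i − μ) − α_i/[V⁻¹]_ii) rather than the in-sample BLUP. The
in-sample BLUP partially refits each subject's own phenotype; feeding it to
the joint optimisation both overstates the background's predictive value and
absorbs the gene signal in-sample, starving the stacked layers. Cross-fitting
makes the training-time background exactly as strong as the test-time one.
This is the same no-leakage principle that forces held-out h0′ to come from
training data only.

## 3. gBLUP background

The genomic relationship matrix is G = W W′/m with
W_ij = (x_ij − 2p_j)/√(2p_j(1−p_j)); monomorphic variants are dropped with a
warning. Variance components of y = μ + g + e, g ~ N(0, σ_g² G) are estimated
by profile REML: one eigendecomposition of G reduces the restricted
likelihood to a bounded scalar function of the heritability
h = σ_g²/(σ_g²+σ_e²), maximised by Brent search on (10⁻⁶, 1−10⁻⁶); the total
variance and the GLS mean have closed-form profiles. This is exact, has no
convergence failures at the sample sizes targeted here, and replaces the
usual average-information iteration. BLUPs, LOO values and held-out
predictions all derive from the same factorisation. Binary outcomes are
handled on the observed 0/1 scale (standard observed-scale GREML practice).
The GRM is computed from all variants passing filters, not only screened
genes.

## 4. Synthetic data

The simulator emulates the study design end to end without any external data.

**Genotypes.** Within each gene, two latent haplotype vectors are drawn from
a multivariate normal with AR(1) correlation ld_decay^|i−j| (default 0.5),
thresholded at each variant's minor-allele frequency (drawn uniformly from
(0.05, 0.5)), and summed into {0,1,2} dosages. Genes are mutually
independent. This Gaussian-copula surrogate preserves the one property the
screening statistic exploits — within-gene LD that survives row permutation —
but not long-range LD, population structure, relatedness or rare variants,
so passing tests speak to the method's behaviour under block-structured
common-variant panels, not to every property of real cohorts.

**Phenotypes.** The latent mean combines four gene effects, each gated by an
indicator switch I_1..I_4:

    μ_i = I_1 Σβ_j1 X_1ij·1(j∈Φ_1) + I_2 Σβ_j2 X_2ij·1(j∈Φ_2)
        + I_3 β_3 (Σ_j X_3ij)² + I_4 β_4 cos(Σ_j X_4ij)

with Φ_1 and Φ_2 covering 90% and 10% of the variants of their genes
(re-drawn per dataset), β ~ N(0, σ_k²) per causal variant, the cosine taken
in radians on the raw dosage sum, and disease models S1 (linear only:
I = 1,1,0,0), S2 (non-linear only: 0,0,1,1), S3 (all). Continuous outcomes
add N(0, σ²) noise; binary outcomes are Bernoulli through a logistic link.

**Effect magnitudes.** Per-gene effect sizes are parameterised by a *signal
fraction*: each active term is centred and rescaled so its variance is a
target share of the outcome variance (latent-scale variance π²/3 under the
logistic link). The default is 0.10 per causal gene; the prediction
experiments use 0.15 and the power study 0.035, chosen once in pilot runs so
that a desk-scale cohort (n = 2000) yields mid-range accuracies and interior
power where method differences are visible, and frozen thereafter.
Calibration (type-I error) results do not depend on this knob, since null
genes carry no term. Raw coefficients (σ_1, σ_2, β_3, β_4) can be supplied
instead by disabling the signal-fraction mode.

**MAF spectrum and the cosine effect.** The power study draws MAFs uniformly
from (0.01, 0.2), a low-frequency-dominated panel of the kind gene-based
exome tests target; the prediction studies use the common-variant default
(0.05, 0.5). The choice matters for the cosine gene: when common-variant
MAFs spread the dosage sum across several cosine periods, the target is a
high-frequency single-index function that gradient descent cannot recover
(spectral bias) — the network fails even on noiseless data; when MAFs are
very low the sum is nearly confined to one monotone stretch of the cosine
and a linear test detects it. The (0.01, 0.2) window, where the sum spans
roughly one to two periods, is the regime in which a small MLP genuinely
outperforms linear set tests on cosine effects.

## 5. Evaluation harness and problem sizes

Type-I error is estimated by re-simulating the full dataset and re-running
the K-fold test on a null gene across independent replicates; power per
causal-gene role the same way, with a one-degree-of-freedom regression of y
on the gene's dosage sum as the linear comparison test. Accuracy metrics are
the Pearson correlation (continuous) and the Mann–Whitney AUC (binary).
Monte-Carlo standard errors use the binomial formula.

The power runs report two linear comparison tests: the 1-df dosage-sum
regression and the gene-level multi-df linear F-test. The F-test is the
meaningful surrogate for a linear set-based method: the sum-score test is
nearly the optimal test for the squared-dosage-sum effect (see Limitations)
and so overstates what a generic linear screen would achieve.

The packaged experiment defaults are desk-scale: 500 calibration replicates
at n = 1000 (K = 5, 30 epochs, 100 permutations per fold), 50 power
replicates at n = 2000 (100 epochs), and 20 transfer-vs-optimal plus 10
noise-robustness replicates at n = 2000 with 20-variant genes (fold networks
30 epochs, selected-gene refits 400 epochs, stacked layers 100 epochs).
These sizes were fixed when the experiments were designed; the full-scale
design (5000 replicates, K = 20) is reachable through the same APIs by
raising the corresponding arguments.

## 6. Numerical choices and degenerate inputs

* Missing dosages: per-variant mean imputation; an all-missing variant is an
  error naming the variant.
* Region intervals: 1-based, closed on both ends (GFF3 convention); BED
  converted at parse time; a variant on an end coordinate is included; a
  variant in overlapping regions goes to the first region in annotation
  order (warning logged) so no signal is double-counted.
* se = 0 in the screening test → p = 1 (declared non-predictive) rather than
  0/0.
* Constant phenotype, empty gene, single-class AUC, constant-vector Pearson:
  explicit errors.
* REML heritability is box-constrained to (10⁻⁶, 1−10⁻⁶); GRM eigenvalues
  clipped at 0.
* ReLU derivative at exactly 0 is taken as 0.

## 7. Known limitations

* The fold statistics are combined as if independent; the induced mild
  miscalibration is part of the method and is what the calibration suite
  measures.
* Screening is gene-marginal: genes predictive only through between-gene
  interactions can be missed (the transfer stack can model interplay only
  among *selected* genes).
* The copula genotype model has no rare variants, no population
  stratification and no cryptic relatedness; gBLUP's observed-scale binary
  treatment ignores prevalence rescaling.
* The cosine-effect gene is intrinsically hard at small n; with desk-scale
  settings its detection power is modest, and prediction fixtures should not
  assume it is always selected.
* The squared-dosage-sum "interaction" effect is predominantly linear in the
  dosages: for non-negative dosages corr(ΣX, (ΣX)²) exceeds ~0.85 in any
  realistic MAF regime (and x² = x exactly for 0/1 dosages), so linear tests
  aligned with the sum detect it essentially whenever the network does. A
  power advantage for the network on this effect type should not be expected
  against a well-aligned linear comparison; the advantage the screening test
  offers is over effects outside the linear span, such as the cosine term,
  and over misweighted set tests.
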