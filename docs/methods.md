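# Methods

## Model

All predictors are Gaussian kernel mixed models

    y = μ1 + Σ_m u_m + ε,   u_m ~ N(0, σ²_m K_m),   ε ~ N(0, σ²_e I),

with one or two kernels K_m over the n lines. The kernels are:

* **G** (VanRaden, method 1): `G = WWᵀ / (2 Σ_j p̂_j(1−p̂_j))`, `W = X − 2P̂`,
  with sample allele frequencies `p̂_j = mean(x_·j)/2`. Columns of W are
  centred, so G's rows and columns sum to zero and its mean diagonal is
  ≈ 1 for typical allele-frequency spectra. Computing G requires at
  least one marker with 0 < p̂_j < 1; otherwise the denominator is zero
  and the computation errors.
* **GA = AAᵀ** from a binary adjacency matrix A. The kernel is the exact
  covariance implied by iid N(0, σ²_gA) per-edge effects; it is PSD for
  any A (xᵀAAᵀx = ‖Aᵀx‖²) and its diagonal equals each line's
  out-degree (k for every line in a KNN graph). GA enters the model
  **unscaled**; a `scale` option dividing by the mean diagonal exists
  for sensitivity analysis only.

### Graph construction

Pairwise similarity is the allele-matching proportion
`s(i,i′) = (1/p) Σ_j (1 − 0.5|x_ij − x_i′j|)` (each marker contributes
1, 0.5 or 0 for integer dosages; the function is well defined for
mean-imputed fractional dosages too). Although sometimes called a
genomic "correlation", it is a matching score in [0, 1], not Pearson's
r; we implement the explicit formula.

* **Thresholding**: τ_c is the empirical quantile (default level 0.65)
  of the n(n−1)/2 strictly-lower-triangle similarities, computed with
  linear interpolation (numpy's default, identical to R's `quantile`
  type 7, the environment in which the method was originally run).
  Edges use the ≥ comparison, so ties at τ_c are connected. Symmetric.
* **KNN**: each line connects to the k = 10 others with smallest
  `d = 1 − s`, self excluded. Ties in distance are broken by ascending
  line index (a stable argsort), making the graph reproducible; the
  adjacency is left asymmetric, as the construction implies — GA = AAᵀ
  is symmetric regardless.

## Fitting

### Gibbs sampler (`BayesKernelBLUP`)

Each kernel is eigendecomposed, K = Γ Λ Γᵀ, with eigenvalues below
1e-10 dropped (KNN-derived GA is often singular); the random effect is
sampled in eigen-coordinates u = Γδ, δ_j ~ N(0, σ²_m λ_j), giving
independent scalar full conditionals. The intercept has a flat prior;
every variance has a scaled-inverse-χ² prior with df = 5 and scale
elicited so the prior mode assigns R2 = 0.5 of the phenotypic variance
to the kernel terms (split equally between kernels, each divided by its
mean diagonal so the elicitation is scale-free) and 1 − R2 to the
residual — the customary default for Bayesian GBLUP software. Lines
with missing phenotype are imputed from their full conditional
(μ + Σu + noise) each iteration; this is exactly the NA-coding
convention by which test lines are predicted, and the posterior mean of
μ + Σu at those lines is the reported prediction.

Defaults: 10 000 iterations, 2 000 burn-in, thinning 5, explicit seed.
These comfortably exceed typical defaults for stable posterior means at
n of a few hundred; the per-iteration cost is O(n·rank) per kernel.

### REML oracle (`REMLKernelBLUP`)

The restricted likelihood (intercept profiled out by GLS) is maximised
over log-variances by Nelder–Mead; BLUPs follow the closed form
ĝ_m = σ̂²_m K_m[:, train] V⁻¹ (y_train − μ̂1), which extends predictions
to unobserved lines through the full kernel rows. For phenotypes with
(numerically) zero variance the fit short-circuits to the intercept
with variances at a 1e-12 floor. The REML route is deterministic and
algebraically independent of the sampler, so the two cross-validate
each other; reported heritability is
ĥ² = Σ_m σ̂²_m·meandiag(K_m) / (Σ_m σ̂²_m·meandiag(K_m) + σ̂²_e).

### Route choice in tests

The sampler and the oracle agree in test-set accuracy to well within
0.05 APC on single-kernel problems (checked explicitly). For the
five-model ordering comparisons the test suite uses the REML route:
those checks concern the *kernel structure*, and the deterministic fit
removes Monte-Carlo noise. One genuine Bayes/REML difference is worth
knowing: with two marker-derived kernels (G and a KNN GA) and df = 5
priors, the posterior keeps σ²_GA away from zero even when the network
carries no signal, splitting genotype signal between the kernels; at
n ≈ 200–300 this depresses the combined model's mean APC by roughly
0.05–0.1 relative to conventional GBLUP, an effect that shrinks as n
grows and that REML (which estimates σ²_GA ≈ 0) does not show.

## Evaluation protocol

`make_cv_plan` draws 10 independent random partitions, each assigning
round(0.2·n) lines to testing; partitions are fresh draws, not folds,
and one plan is shared across models so comparisons are paired. Kernels
are built once per dataset from the markers (available for all lines)
and reused across partitions. Metrics per partition:

* **APC** — sample Pearson correlation (undefined under zero variance;
  such partitions are flagged missing and excluded from means, with a
  warning);
* **NRMSE** — RMSE divided by the **sample** (ddof = 1) SD of the
  observed test values; for the constant-mean predictor this equals
  √((m−1)/m), and for the least-squares linear predictor
  √(1−r²)·√((m−1)/m);
* **MAAPE** — mean of arctan|(y−ŷ)/y|, bounded in [0, π/2]; a zero
  observation contributes π/2 (unless the prediction is also exactly
  zero, a removable 0/0 treated as 0);
* **Best20** — with m = ⌈0.2·|test|⌉, the percentage of the m best
  observed lines present among the m best predicted; "best" defaults to
  largest, with a per-trait smaller-is-better override for scores like
  disease severity.

## Synthetic data generator

`simulate_markers` draws, per marker, a MAF q_j ~ Uniform(0.1, 0.5) and
per line a dosage ~ Binomial(2, q_j): Hardy–Weinberg proportions,
independent markers, no population structure. An optional AR(1) latent
Gaussian mode (`ld_rho`) correlates adjacent markers; no test requires
it. `simulate_phenotypes` then draws y = μ + g + gA + ε with
g ~ N(0, σ²_g·G/meandiag(G)) and gA ~ N(0, σ²_net·GA/meandiag(GA));
the mean-diagonal normalisation happens **inside the generator only**,
so the targets h2_g and h2_net are interpretable as variance fractions
while the analysis pipeline still receives unscaled kernels. The
residual variance is fixed at 1 and the genetic variances solve
σ² = h²/(1 − h2_g − h2_net).

**Default sizes.** n_lines = 300 and n_markers = 300. With independent
markers the marker count *is* the effective number of independent
chromosome segments M_e, and expected GBLUP accuracy is approximately
√(N h² / (N h² + M_e)) for N training lines. Real breeding panels carry
tens of thousands of markers but, through linkage disequilibrium, only
a few hundred effective segments; M_e = 300 emulates that regime
(expected APC ≈ 0.45 at N = 240, h² = 0.5, matching what dense
real-data panels achieve) without simulating LD itself. Consequently,
what passing tests show is that the estimators recover the structure
they assume; they do not exercise LD decay, population stratification,
family structure, or genotype–environment interaction, all present in
real data.

## Numerical choices

* Kernel eigenvalue floor 1e-10 (rank truncation); PSD validation
  rejects kernels with eigenvalues below −1e-8 (relative to the largest).
* Similarity matrices are symmetrised ((S+Sᵀ)/2) and clipped to [0, 1]
  to absorb floating-point round-off; G is symmetrised the same way.
* Kernel CSV export uses shortest round-trip float repr and is re-read
  with `float_precision="round_trip"`, giving bit-exact round trips.
* Benchmark reproducibility: each fit's sampler seed derives from the
  global seed and a CRC32 of (trait, env, model label, partition), so
  runs are bit-for-bit repeatable regardless of Python hash
  randomisation.
* Missing dosages default to per-marker mean imputation before any
  kernel computation (markers observed nowhere are dropped); VCF input
  takes alternate-allele counts and skips multiallelic sites.

## Problem sizes in tests and the acceptance script

Test and acceptance runs use n = 150–300 lines, 300 markers, 10
partitions, and 10–20 replicate simulations; the Gibbs sampler runs its
default 10 000 iterations where it is the object under test and shorter
chains where it is scaffolding. These sizes give each stochastic check
a comfortable margin relative to its Monte-Carlo noise.

## Known limitations

* Single trait, single environment per fit; no G×E kernels.
* At most two kernels; no marker-effect (BayesA/B/Lasso) priors.
* The adjacency matrix is treated as fixed and known; no uncertainty in
  graph construction is propagated.
* The Bayes/REML combined-model discrepancy described above means the
  Bayesian combined model at small n is mildly conservative relative to
  conventional GBLUP when the network kernel is uninformative.
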