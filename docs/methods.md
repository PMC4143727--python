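# Methods

## Model

The trait is modelled as y<sub>i</sub> | z<sub>i</sub>, v<sub>i</sub> ~
N(v<sub>i</sub>ᵀη + z<sub>i</sub>ᵀβ, τ²), i = 1..n, with a spike-and-slab
prior on each SNP effect, β_j | θ_j ~ θ_j N(0, σ²) + (1 − θ_j) δ₀, and
η ~ N(0, σ² I_q) on the covariate coefficients. β and η are integrated out
analytically, so the sampler only ever sees the marginal likelihood
y | Z, θ ~ N(0, Σ(θ)) with Σ(θ) = τ² I + σ² V Vᵀ + σ² Z_A Z_Aᵀ, Z_A the
active columns. The gene hierarchy places γ_g ~ Bernoulli(α) on gene
activity and θ_j | γ ~ Bernoulli(logit⁻¹(ξ₀ + ξ₁ s_j / n_j)) with
s_j = Σ_{g∋j} (2γ_g − 1): active covering genes raise a SNP's prior inclusion
odds, inactive ones depress them, and the effect of a gene is diluted by the
total number of genes covering the SNP.

Assumptions worth stating explicitly: unrelated individuals (no kinship
correction), a quantitative trait with Gaussian residuals on a known scale,
fixed residual variance τ², and LD that is adequately captured by a per-block
sample correlation matrix.

## Latent-genotype preprocessing

Observed dosages are treated as a categorised liability: U ~ N(0, C) with the
category of X_ij determined by where U_ij falls relative to the normal
quantiles of the genotype-category probabilities. The preprocessing is the
conditional-mean approximation Û_ij = E[U_ij | X_ij] (a three-point mapping
per SNP, conditioning on the marginal category only — joint conditioning on
all SNPs of an individual is exponentially hard and not attempted), followed
by per-block decorrelation.

Two decorrelation modes are implemented because they answer different
questions. `inverse` applies Ẑ_i = C⁻¹Û_i rowwise — note that if U ~ N(0, C)
then C⁻¹U ~ N(0, C⁻¹), so this removes correlation only approximately and
does not yield unit variances. `inv_sqrt` applies the symmetric root
C^(−1/2), which is the actual whitening transform (output covariance I).
`inverse` is the default; `inv_sqrt` is the statistically cleaner choice and
is the one validated by the whitening diagnostic. Both are exposed in the
pipeline config.

Category probabilities default to the Hardy–Weinberg expansion of the MAF;
an `empirical` mode uses observed genotype frequencies instead, which
guarantees every observed category positive mass when a SNP is far from HWE.

The sample correlation is shrunk toward the identity,
C = (1−λ)R + λI with λ = 0.1 by default: within a block p can exceed n, the
raw R is then singular, and a ridge toward independence is the minimal fix
that keeps the Cholesky solvers stable. λ is a config value; λ = 0 reproduces
the unshrunk estimator.

## Sampler

One sweep updates, in fixed order: every θ_j (ascending) by an exact Gibbs
draw from odds(θ_j=1) = [p_j/(1−p_j)]·exp(ℓ₁−ℓ₀); every γ_g (ascending) from
its exact full conditional (γ only enters the priors of covered SNPs); ξ₀ and
ξ₁ by independent Gaussian random-walk MH steps (default step 0.25; proposals
outside the uniform supports are rejected outright; realised acceptance
depends on p and is logged per block); and α by an exact conjugate draw from
Beta(a + Σγ, b + G − Σγ). An `mh` mode for α (logit-scale random walk with
Jacobian correction) targets the same full conditional and is retained for
completeness; the conjugate draw is the default because the full conditional
is available in closed form. The fixed order plus a single seeded generator
makes every run bit-reproducible; per-block seeds are derived by hashing
(master seed, block index), so block results do not depend on processing
order.

Likelihood evaluations go through cached Gram matrices: with W = [V, Z_A],
log N(y; 0, τ²I + σ²WWᵀ) is computed from the capacitance matrix
M = I + (σ²/τ²)WᵀW whose blocks are slices of the precomputed ZᵀZ, ZᵀV, VᵀV,
Zᵀy, Vᵀy. A single-site θ update is then one Cholesky factorisation of a
(q+|A|)-dimensional matrix — effectively free while the posterior is sparse —
and is exactly equal to a from-scratch dense evaluation (tested to 1e−6), so
no incremental-update drift can occur.

Initialisation is the empty model (θ = 0, γ = 0), ξ's at their support
midpoints, α at its prior mean. Convergence is monitored with Geweke
z-scores (early 10% vs late 50% window means) on ξ₀, ξ₁, α and Σθ; |z| > 3
triggers a logged warning. This is a pragmatic stand-in for a full
convergence analysis, not a guarantee.

## Parameters that matter

| parameter | default | units/scale | rationale |
|---|---|---|---|
| τ² | 300 | trait variance | matches a systolic-blood-pressure scale; set to ≈ Var(y residual) for other traits (the simulator uses 1.0) |
| σ² | 1.0 | effect variance | never pinned down by theory here; τ²/σ² acts as the selection penalty |
| ξ₀ bounds | (−6, −2) | log-odds | baseline SNP inclusion ≈ 0.0025–0.12 |
| ξ₁ bounds | (0, 5) | log-odds | non-negative boost; 5 saturates the hierarchy |
| α prior | Beta(0.75, 49.25) | probability | mean 0.015 ≈ 5 active genes per 336 blocks; the Beta parameters themselves are a package choice |
| shrinkage λ | 0.1 | — | keeps C positive definite when p ≳ n |
| gap threshold | 15,000,000 bp | bp | only genuinely unlinked stretches split blocks by default; dense chips need a much smaller value, so this is always explicit config |
| sweeps / burn-in | 2000 / 500 | sweeps | adequate mixing at block scale (p ≤ ~100); the exact-posterior validation uses 50,000 |

## Synthetic data

The generator produces exactly what the model assumes: liabilities
U ~ N(0, C) (independent, AR(1), or block-exchangeable C), thresholded at the
HWE quantiles of each SNP's MAF into dosages; gene annotations as SNP-index
intervals emitted as consistent BED/bp coordinates (SNP j at (j+1)·1000 bp);
and a trait linear in the standardised causal dosages plus N(0, τ²) noise.
The per-SNP effect for a target heritability h² with k causal SNPs is
β = sqrt(h²τ²/((1−h²)k)).

The reference design is n = 200, p = 50, MAF ~ U(0.1, 0.5), ten genes of
five SNPs, two causal genes containing five causal SNPs (3 + 2), h² = 0.3 on
a unit-noise scale. The trait acts through standardised observed dosages by
default (what a real GWAS measures); a `latent` signal mode drives the trait
with the true liability instead, for isolating the value of the
preprocessing.

What the simulator does **not** emulate: haplotype/coalescent LD structure,
population stratification, relatedness, genotyping error, missingness
mechanisms, or non-Gaussian traits. Passing the recovery experiments
therefore shows correctness of the inference under the model's own
assumptions, not performance on real cohort data.

## Numerical choices

- Likelihoods are computed in log space throughout; Bernoulli odds are
  combined on the logit scale, so θ updates cannot overflow.
- Truncated-normal means use tail-stable mass evaluation (survival functions
  for right tails); a category with zero probability raises an error naming
  the SNP rather than returning NaN.
- SNPs with n_j = 0 (covered by no gene) get the baseline prior
  logit⁻¹(ξ₀): the boost is gene-mediated, so no covering genes means no
  boost, and the s_j/n_j division is never evaluated at 0/0.
- Centroid ties at PPA = 0.5 resolve to non-selection (the indicator is a
  strict inequality); the minimiser is non-unique there and the brute-force
  oracle reports the full tie set.
- PPA rank ties in reports break by ascending genomic position.
- Dense (n×n Cholesky) and capacitance (low-rank) likelihood routes are both
  implemented and agree to 1e−8; `auto` picks by active-set size.

## Validation problem sizes

The exact-posterior check enumerates all 2⁴·2² states of an n = 20, p = 4,
G = 2 instance and compares 50,000-sweep sampler PPAs (observed max error
≈ 0.004). Recovery experiments run 20 independent seeds of the reference
design at 1500 sweeps each. The whitening diagnostic uses n = 10⁴ AR(1)
ρ = 0.8 liabilities with p = 10. These sizes were chosen so the full
validation completes in minutes on a single core while keeping Monte-Carlo
error well below the decision thresholds.

## Known limitations

- The top-k recovery of all causal SNPs is power-limited: at h² = 0.3 spread
  over five SNPs with n = 200, the weakest causal signal is sometimes
  indistinguishable from the best of 45 nulls — the model outperforms
  marginal-correlation ranking on the same data but cannot manufacture
  information the data lack.
- τ² is fixed, not estimated; a badly mis-set τ² distorts selection.
- Per-block independent fitting ignores cross-block LD and shares no
  hyperparameter information across blocks (each block learns its own
  ξ₀, ξ₁, α).
- The `inverse` decorrelation mode does not fully whiten (see above); the
  whitening guarantee applies to `inv_sqrt` only.
- Genes spanning a block boundary are treated as separate per-block gene
  instances.
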