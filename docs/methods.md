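# Methods

## Model

For one genetic variant *g* (0/1/2 counts or dosages; any real covariate is
accepted) and *d* phenotypes, each partition γ = (U, D, I) of the trait
indices defines a probability model through two conditional-independence
statements: Y_U ⊥ g, and Y_I ⊥ g | (Y_D, Y_U). All models are derived from
just two explicitly specified distributions — the global null (all traits
in U) and the full alternative (all traits in D) — by requiring that the
pieces not involving *g* agree with the null and the piece involving *g*
agree with the full alternative. The Bayes factor of γ against the global
null then reduces to a ratio of two regressions of Y_D: on (intercept,
Y_U, g) versus on (intercept, Y_U). Indirectly associated traits cancel
from the ratio, which is why "indirect" carries no extra evidence against
the null — it is a statement about mediation, not additional signal.

## Marginal likelihood and the limiting Bayes factor

The regression block is Bayesian multivariate regression: Y = XB + E, rows
of E iid N(0, Σ), Σ ~ InvWishart(λI, m), B | Σ ~ MatrixNormal(0, K, Σ)
with K diagonal. Integrating (B, Σ) gives a matrix-t marginal computed in
`log_marginal_bmvr` purely via Cholesky log-determinants:

```
log p(Y|X) = −(nd/2) log π + log Γ_d((n+m)/2) − log Γ_d(m/2)
           + (dm/2) log λ − (d/2) log|I + K XᵀX| − ((n+m)/2) log|S|,
S = λI + YᵀY − YᵀX (K⁻¹ + XᵀX)⁻¹ XᵀY.
```

The diagonal K couples the prior on each coefficient row to Σ, so a variant
that raises one trait is a priori more likely to raise (not lower) a
positively correlated trait.

Routine analysis uses the limiting prior: intercept and Y_U-coefficient
scales σ_b → ∞, inverse-Wishart scale λ → 0 and degrees of freedom m → 0
(for d = 1 this is the classical flat-intercept, p(σ²) ∝ 1/σ² limit).
Writing ν = σ_a² g̃ᵀg̃, with g̃ the OLS residuals of g on (intercept, Y_U),
and Λ_γ the maximized Gaussian likelihood ratio for Y_D on (intercept,
Y_U, g) vs (intercept, Y_U):

```
ln BF_γ = ((n − d_D)/2) ln(1 + ν) − (n/2) ln(1 + ν Λ_γ^(−2/n)).
```

This identity is exact (no asymptotics) and is verified in the tests by two
independent code routes: block-solves on the sufficient statistics versus
OLS fits on the raw data. It implies affine invariance in the phenotype
coordinates, monotonicity in Λ_γ, and — when σ_a is chosen per SNP as
c/‖g̃‖ — exact rank agreement between BF and Λ across SNPs. Because only
(n, gᵀg, gᵀY, YᵀY) after mean-centering enter, the engine's entire data
interface is the `SufficientStats` triple.

The degrees-of-freedom convention deserves a note: the m → 0 limit is taken
jointly with λ → 0, and the σ_b → ∞ limit keeps the full n in the exponent
(the normalizing constants of the proper priors cancel between the two
models before the limit). Bayes-factor ratios therefore remain well defined
for any m ≥ 0 even though a proper inverse-Wishart needs m > d − 1; the
absolute marginal likelihood (`log_marginal_bmvr`) enforces propriety and
is validated against dense-grid quadrature (d = 1) and prior-draw Monte
Carlo (d = 2).

## Priors

* **Partitions.** The default exchangeable prior draws the number of
  associated traits p uniformly on 1..d given non-null, |D| uniformly on
  1..p given p, and all partitions with those counts equally likely. Under
  it E[p] = (d+1)/2 and the prior probability any given trait is associated
  is (d+1)/(2d). π₀, the null mass, is a separate knob (default 0.5; in a
  genome scan it should reflect the expected fraction of truly associated
  SNPs and mostly shifts p_null, not the ranking).
* **Effect scale.** σ_a is the prior SD of genotype effects in residual-SD
  units, shared across traits; results are averaged over the grid
  {0.05, 0.1, 0.2, 0.4, 0.8} with uniform weights by default. The mixture
  of small and large values keeps prior mass on small effects without
  ruling out large ones. Sharing one σ_a across traits is a known
  restriction of the conjugate prior.
* **Empirical Bayes.** On a set of associated SNPs, mixture weights over
  (partition, σ_a) cells maximize Π_i Σ_c w_c BF_i(c) by EM
  (responsibilities ∝ w·BF; M-step = mean responsibility). Convergence:
  relative log-likelihood change < 1e−8 or 2,000 iterations; 4 starts
  (uniform + flat-Dirichlet draws, seeded); weights floored at 1e−12 to
  keep the index space stable. Weights fitted on SNPs selected for strong
  association are biased towards larger effects and richer partitions;
  they are intended for classifying those same SNPs, not as unbiased
  genome-wide frequencies.

## Summary-statistic approximations

With standardized phenotypes, per-SNP Z-scores z, minor allele frequency f
and sample size n:

* gᵀg ≈ 2nf(1−f) (Hardy–Weinberg genotype variance);
* YᵀY ≈ nR, with R the correlation matrix of Z-scores across putative null
  SNPs (all |z_j| below a threshold, default 2.0) — under the null the
  Z-score correlation equals the phenotype correlation. Truncating at
  |z| < 2 shrinks off-diagonal entries a few percent; this bias is accepted
  as in standard practice. Non-PSD estimates are repaired by eigenvalue
  clipping and rescaling to unit diagonal.
* gᵀy_j = z_j sqrt(gᵀg · yᵀy_jj / (n − 2 + z_j²)), obtained by inverting
  z = (gᵀy/√(gᵀg))/s with s² the residual variance on n − 2 df. The
  (n − 2 + z²) denominator keeps the inversion exact at large |z|; at large
  n it reduces to z√(gᵀg).

Measured accuracy (acceptance script, n = 1,000, 200 SNPs): median
per-partition |Δlog₁₀BF| ≈ 0.005, shrinking with n. Missing phenotype data
are handled by pairwise-complete cross-products (each trait centered on its
own observed rows, moments rescaled to a common sample size) with the
per-SNP n set to the smallest per-trait count — adequate for modest,
missing-at-random gaps, and exact when nothing is missing.

## Genome scan

Stage 1 screens each SNP with the multivariate statistic zᵀR⁻¹z (χ² on d
df) and the d univariate z_j² (χ² on 1 df), keeping SNPs whose smallest
p-value is below a threshold (default 1e−4, configurable — it trades
compute for a bounded risk of missing diffuse signals no single test
detects). Stage 2 computes all partition BFs on the survivors. Ranked
results are de-duplicated by greedily dropping any SNP within 500 kb of a
higher-ranked SNP on the same chromosome (ties broken by chromosome, then
position) — a proxy for linkage disequilibrium, not an LD-aware method.
Permutation p-values for BF_av use the add-one estimator
(1 + #{perm ≥ obs})/(n_perm + 1), permuting the genotype against phenotype
rows; only gᵀY changes under permutation, so the null draws are computed
in one vectorized batch.

## Synthetic data

The generators reproduce the study designs the statistics are evaluated on;
all are seeded, and identical seeds give identical output.

* **Bivariate** (n = 1,000, MAF 0.2, g ~ Binomial(2, f)): Y_j = b_j g + e_j
  with corr(e₁, e₂) = ρ ∈ {0.4, 0.7}. The second trait's coefficient picks
  the scenario: b₂ = 0 (unassociated), b₂ = ρb₁ (the unique value making Y₂
  independent of g given Y₁ — indirect), or a genuinely direct b₂. The
  default direct effect is b₂ = −b₁ with b₁ = 0.25: with same-sign equal
  effects and ρ = 0.7, b₂ ≈ ρb₁ and the direct design becomes nearly
  indistinguishable from the indirect one, degenerating the comparisons;
  opposite-sign effects (common in practice, e.g. a variant raising
  triglycerides while lowering HDL) keep the three scenarios mutually
  distinguishable.
* **Five-trait scenarios** (n = 1,000, effect 0.15 SD/allele — chosen for
  mid-range power so statistic orderings are resolvable at 1,000
  replicates): (1) independent traits, one associated; (2) one direct
  trait loading 0.4 on four mutually independent unassociated traits;
  (3) one direct trait plus four noisy copies with noise-SD ratios
  {0.5, 1, 2, 4} (indirect); (4) two direct, one indirect (their average
  plus noise), two unassociated-but-correlated; (5) two direct, three
  correlated unassociated; (6) a latent factor carrying the genotype
  effect, all five traits factor-plus-noise (all direct). Matched null
  datasets zero every genotype effect while keeping the error covariance.
* **Summary records**: null SNPs draw z ~ N(0, R); an associated SNP draws
  a partition from a specified mixture and receives mean shift
  `effect_scale` (random shared sign) on its direct traits, the
  conditional-mean image R_ID R_DD⁻¹ μ_D on indirect traits, zero on U;
  MAF ~ Uniform(0.05, 0.5).

What the generators do **not** emulate: linkage disequilibrium between
SNPs, non-Gaussian phenotypes, genotype effects on trait (co)variances,
study-level heterogeneity in meta-analysis, or genomic-control artifacts.
Passing tests therefore certify the statistical machinery under its own
model assumptions, not robustness to those real-data complications.

## Replicate counts and problem sizes

Power comparisons run 1,000 alternative + 1,000 null replicates per
scenario and the bivariate BF comparisons 100 replicates per (scenario, ρ);
calibration checks use 2,000 null SNPs for the χ² screen and 200 datasets ×
999 permutations for the permutation test. The EM recovery study plants a
(0.6, 0.3, 0.1) mixture across 5,000 SNPs with |z| ≈ 8 at per-SNP
n = 50,000 (meta-analysis scale): at small per-SNP n the dimension penalty
(½)log(1 + σ_a²gᵀg) is small enough that the richest component absorbs
responsibility from single-trait components — a property of the mixture
likelihood, not an estimation failure — so clean weight recovery requires
the large-n regime the design targets.

## Numerical choices

* All determinants via Cholesky; symmetric matrices symmetrized
  ((M + Mᵀ)/2) and jittered up to 1e−10 × trace before failing.
* The Wilks ratio is clipped to (0, 1]; mixture sums use log-sum-exp
  throughout, so BF_av never overflows.
* p_null is computed from BF_av by Bayes' rule and asserted (1e−10) equal
  to the normalized partition-table null mass on every call.
* Exhaustive enumeration is refused for d > 15 (3^d growth) rather than
  silently sampled.
* Degenerate inputs raise typed errors: zero-variance or Y_U-collinear
  genotypes (`DegenerateCovariateError`), rank-deficient designs
  (`CollinearityError`), too few null SNPs for the correlation estimate
  (`InsufficientNullSnpsError`).

## Known limitations

Phenotypes are modeled as multivariate normal within genotype classes;
binary or heavy-tailed traits are out of scope. Partitions are assumed
exchangeable a priori; ordered or structured traits would warrant a custom
prior (supported via explicit weight maps). The direct-vs-indirect
distinction is sensitive to measurement error: a noisily measured direct
trait can masquerade as indirect. Distance pruning is not LD-aware. For
d ≳ 10 the inverse-Wishart prior under-regularizes Σ and enumeration cost
grows as 3^d.
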