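# Methods

## The decomposition model

Let L be a latent exposure liability with SNP heritability h²_E, C a
continuous confounder phenotype with heritability h²_C, and y_k a set of
quantitative outcome measures in an independent cohort.  Per-variant
causal effects (a_j, c_j) on liability and confounder are drawn from a
bivariate normal with correlation r_g — the standard definition of
genetic correlation as the correlation of per-variant effects — and each
vector is rescaled so the genetic-score variance equals the configured h²
exactly.  Outcomes load on the standardized genetic scores:

    y_k = β_direct · S_E + β_shared · S_C + g_k + ε_k

with S_E, S_C the standardized exposure/confounder genetic scores, g_k an
outcome-specific polygenic background that tops total outcome
heritability up to `h2_outcome`, and residuals ε correlated across
outcomes (equicorrelated 0.5 by default).  β_direct is in outcome SD per
liability-score SD; β_shared in outcome SD per confounder-score SD.  With
the default signs (β_direct = −0.3, β_shared = +0.5, r_g = −0.53) the
shared path *inflates* the marginal inverse exposure–outcome association,
which is exactly the structure the multivariable regression (MVR) is
meant to disentangle.  The criterion configuration used by the
calibration experiments sets β_shared = −0.5 instead; recovery is
agnostic to the sign.

### Estimands on the estimator's scale

The MVR regresses marginal outcome effects on marginal exposure lnORs and
confounder effects.  Under the liability-threshold model with case/control
ascertainment, the per-allele lnOR linearizes to λ·cov(x_j, L)/var(x_j)
with λ = φ(t)(1/K + 1/(1−K)) (t the liability threshold at prevalence K):
the slope of case log-odds per liability unit in the ascertained sample.
Hence the true MVR coefficients are

    θ_E = β_direct / (sd(G_E) · λ)     [outcome SD per log-odds]
    θ_C = β_shared / sd(G_C)           [outcome SD per confounder unit]

`SimTruth` carries both, computed from the exact block-diagonal dosage
covariance, so parameter recovery is tested on the estimator's own scale
without any fitted conversion.

## The synthetic genome

Variants sit in LD blocks laid out > 500 kb apart (clumping windows never
straddle blocks); each block spans < 500 kb.  Haplotype alleles are
thresholded correlated Gaussians (a Gaussian copula).  Because
dichotomization attenuates correlation, the latent within-block
correlation is calibrated numerically (vectorized bisection on the
equal-threshold bivariate normal CDF, written with Owen's T function) so
that the realized *dosage* correlation equals `within_block_r`.  Variants
within a block share their allele frequency, as variants in tight LD do;
this also makes any target correlation attainable.  Effect sizes are
drawn independently of allele frequency, so GWAS standard errors are
uncorrelated with predictor leverage and the unweighted OLS standard
errors of the MVR remain calibrated across the frequency range.

What the generator does *not* emulate: realistic human LD maps and
long-range LD, imputation error (INFO is a simulated tag used only to
exercise the filter), population structure and stratification (the two
"principal components" are genotype-independent covariates), assortative
mating, and winner's-curse regimes of severely underpowered discovery
GWAS.  Passing tests therefore show the statistical machinery is correct
under the stated model, not that real-data artefacts are handled.

## Discovery GWAS modes

`individual` mode simulates every GWAS participant: a population is
generated, individuals above the (1−K) liability quantile become eligible
cases, n_cases/n_controls are drawn, and per-variant logistic regressions
are run (vectorized Newton on the six per-dosage-level sufficient
statistics — the exact MLE, cross-checked against statsmodels).  The
confounder GWAS is closed-form per-variant linear regression.  `summary`
mode (default) draws estimates directly from their asymptotic
distribution around the exact marginal effects; the two modes are
cross-validated in the test suite.  Summary mode is what makes
consortium-scale sample sizes (default 20,183/35,191 cases/controls and a
326,041-person confounder GWAS, 5,919-child cohort, K = 0.05, h²_E = 0.26,
h²_C = 0.11, r_g = −0.53) tractable on a laptop.

## Scaled-genome consequences

The synthetic genome carries all heritability in 3,000 variants, which
concentrates per-variant power enormously relative to a multi-million-SNP
genome.  Consequences to keep in mind when reading outputs:

* polygenic scores are far more predictive (R² ≈ 20% of an outcome) than
  the ≤ 2% typical of real studies at these sample sizes;
* instrument counts reflect the scaled genome, not real GWAS yield;
* the effective number of tests for the equicorrelated 13-measure battery
  comes out near 5–7 depending on the realized correlations (the Li–Ji
  spectrum is discontinuous at integer eigenvalues).

The *decomposition* properties — unbiasedness of the conditional slopes,
SE calibration, heterogeneity behaviour — are scale-free and are what the
acceptance experiments test.

## Calibration experiments

`recovery_config` defines the study conditions for estimator-calibration
runs: a paired-block genome (4,000 variants in 2,000 blocks at dosage
r = 0.7, so greedy clumping at r² < 0.25 always removes one mate and the
surviving ~1,900 subthreshold instruments are mutually independent), a
5,000-person cohort, and discovery sample sizes large enough (2M/2M
cases/controls, 20M confounder GWAS as *effective* sizes in summary mode)
that instrument-level measurement error is negligible — instrument
reliability > 0.99.  Unweighted OLS MVR treats the regressors as
error-free; at realistic discovery sizes regression dilution attenuates
both components (we measured ~7% at a 300k-case-equivalent design), a
known limitation shared with the real analysis.  The calibration regime
isolates the estimator's own statistical properties: across 200
replicates both components are recovered within 2 reported SEs in ≥ 90%
of runs and 95% CI coverage sits in the low-to-mid 90s; with
β_direct = 0 the conditional exposure slope rejects at the nominal 5%
although the *marginal* association is strongly non-null.

Replicate experiments hold the variant panel and the 2,000-person LD
reference panel fixed (as a fixed reference panel would be in practice)
and redraw effects and data.

## Numerical and procedural choices

* **Rank transform**: OLS residualization on sex and two principal
  components, then rank-based inverse-normal with the Blom offset (3/8),
  ties by average rank; per-measure ranking on available values.
* **Effective tests**: Li–Ji estimator on the eigenvalue spectrum
  (MatSpD's recommended output); Nyholt available via `method="nyholt"`.
  Eigenvalues are rounded at 1e-10 before the floor so integer spectra
  land in the right bin.  The experiment-wide threshold is FWER/M_eff,
  reported at 3 significant figures alongside full precision.
* **Harmonization**: variants matched on identifier with allele
  verification (robust to mixed imputation panels); swapped alleles flip
  the effect sign and eaf; strand-complement matches are accepted for
  non-ambiguous pairs; palindromic (A/T, C/G) variants are dropped by
  default with an opt-in frequency-based rescue (|eaf − 0.5| > 0.1 and
  concordant).  Rows with non-positive SE, invalid alleles/frequencies,
  or P grossly inconsistent with (β/se)² are dropped with a logged count.
* **Clumping**: PLINK-style greedy, P ascending, ties by (chr, pos);
  missing LD entries count as r² = 0 with a logged tally (strict mode
  available).  Filters use strict inequalities (INFO = 0.8 exactly is
  excluded) and the frequency filter acts on MAF.
* **Instrument strength**: per-variant F = (β/se)² and the mean are
  reported as diagnostics only; no F-based filtering is applied.
* **MVR**: unweighted OLS (an inverse-variance-weighted option exists but
  is non-default); constrained (through-origin) intercept by default,
  justified by the free-intercept check; "fully standardized" is
  operationalized as scaling each effect vector to unit variance
  *without centering* in constrained mode (centering would break the
  origin), with centering in free-intercept mode.  Collinearity guard at
  |r| > 0.999 — the exposure and confounder effect vectors are correlated
  by construction (≈ r_g) but far from collinear.  Plain OLS SEs assume
  error-free regressors and independent residuals across instruments;
  both hold in the calibration regime by design.
* **Meta-regression**: V_ij = r_ij·se_i·se_j (same-cohort estimate
  covariance approximation), single variance component τ²I, REML by
  bounded scalar maximization (xatol 1e-10) with an explicit snap to the
  τ² = 0 boundary when the restricted likelihood is non-increasing at the
  origin; GLS coefficients with Wald normal tests; Q at the τ² = 0 GLS
  fit with df = n − rank(X).  The composite verbal-IQ measure is excluded
  from the all-outcomes pool.  Two-estimate pools (the spelling domain)
  are permitted: τ² then has a single residual degree of freedom, which
  is what the real design requires.  Cross-checked against R's metafor
  (agreement to ~1e-5, bounded by metafor's own convergence criterion).
* **Polygenic scores**: weights risk-oriented, scoring set clumped with
  the same r² < 0.25 / ±500 kb rule, default threshold P < 0.1 with the
  sweep {5e-8, 0.0015, 0.01, 0.05, 0.1, 0.5, 1}; missing dosages
  mean-imputed to 2·EAF; allele orientation reconciled against the
  cohort's dosage convention.  Association fits refuse n < 30.

## Degenerate inputs

Constant score vectors, zero-variance effect vectors, all-0/all-1
missingness indicators, separable logistic data, non-positive-definite
correlation matrices, empty instrument sets and zero-overlap scoring sets
all raise explicit errors naming the problem; an empty *filter* result is
a warning, not an error, so threshold sweeps degrade gracefully.

## Known limitations

Regression dilution at realistic discovery sample sizes (above); no
weighting of the MVR by outcome-side standard errors (plain OLS, matching
the design it implements); single global missingness indicator rather
than per-measure patterns; the moderator contrasts in the bundled study
are null by construction because all outcomes share the same generating
effects — the contrast machinery is validated in its own power
simulations instead.
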