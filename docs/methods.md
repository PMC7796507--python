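# Methods

## Model

Two binary conditions (here labelled hypertension and diabetes) are
observed on individuals nested in districts.  Conditional on district
random effects, outcomes Y_ijk are independent Bernoulli(pi_ijk) with

    logit pi_ijk = alpha_k + beta_k' x_ij + [gamma_k U_j] + U_jk + eps_jk

where the bracketed shared term is present only in the shared-component
variant.  The two diseases may use different covariate columns
(`ModelSpec.covariates1/2`).  Assumptions worth keeping in mind:

* the shared and specific fields are a-priori independent — interactions
  between the latent surfaces are not modelled;
* covariate effects are constant across districts;
* heterogeneity eps_jk is always disease-specific (two vectors), in both
  model variants;
* the model is symmetric in the two diseases apart from the reciprocal
  risk gradients.

### Identifiability

The ICAR (intrinsic Besag) prior penalises squared differences across
adjacency edges and is improper: it is invariant to a constant shift per
connected component.  Identification is by per-component sum-to-zero
constraints, with the Laplacian rank deficiency J − C appearing in the
log-density exponent, ((J − C)/2)·log tau − (tau/2)·Σ_edges (u_j − u_l)².
The scale confounding between the shared field and its loadings is removed
by tying gamma_1 = exp(log_delta), gamma_2 = exp(−log_delta); log_delta
gets a Normal(0, 0.5) prior, so the a-priori ratio gamma_1/gamma_2 is
centred on 1 with ~95% mass in (1/7, 7).  Declared isolated districts form
their own components and keep field value 0 (the ICAR prior carries no
information for them).

### Priors

All configurable through `PriorSpec`; defaults are the weakly-informative
conventions of BUGS-era hierarchical disease mapping:

| parameter | prior | default |
| --- | --- | --- |
| alpha_k, beta_k | Normal(0, sd) | sd = 10 |
| log_delta | Normal(0, sd) | sd = 0.5 |
| all precisions (ICAR and iid) | Gamma(shape, rate) | (0.5, 0.0005) |

## Inference

`run_chain` is an adaptive Metropolis-within-Gibbs sampler (compiled with
numba; one chain ≈ 20 s for 20,000 iterations at J = 52, n ≈ 2,800 on one
CPU):

1. blockwise random-walk Metropolis on (alpha_k, beta_k), target
   acceptance 0.234;
2. single-site random-walk sweeps over U, U_1, U_2, eps_1, eps_2, target
   acceptance 0.44;
3. after each structured-field sweep the field is re-centred and the
   subtracted mean transferred into alpha_k (times gamma_k for the shared
   field) so the likelihood is unchanged *exactly* — this transfer is only
   exact on a connected graph, hence `run_chain` requires one (the ICAR
   primitives themselves handle disconnected graphs);
4. random-walk Metropolis on log_delta;
5. conjugate Gibbs for every precision: Gamma(shape + (J−C)/2,
   rate + penalty/2) for ICAR fields, Gamma(shape + J/2, rate + Σu²/2)
   for heterogeneity.

Step sizes adapt every 50 iterations during burn-in by a decaying
log-scale adjustment (±min(0.5, 2/√w) at window w) and are frozen
afterwards, preserving detailed balance for the retained draws.
Initialisation: intercepts at the empirical logit of each prevalence,
everything else at zero, precisions at 10.  Chains differ only through
seeds derived deterministically from the user seed; runs are bitwise
reproducible.

Defaults (2 chains × 20,000 iterations, burn-in 10,000, thin 10) give
roughly 2,000 retained draws — adequate effective sample sizes for the
field and coefficient blocks at the survey scale in rehearsal runs; the
intercepts mix slowest because they trade off against the fields.

### DIC

Dbar is the posterior mean deviance (−2 log-likelihood); Dhat plugs in the
*posterior mean of the per-person linear predictors* rather than the mean
of each parameter block — the linear predictor is identified under the
re-centring moves while individual blocks are only jointly identified.
pD = Dbar − Dhat, DIC = Dbar + pD, lower is better.

### Fraction explained

Per retained draw and disease, f_k = Var_j(gamma_k U_j) /
Var_j(gamma_k U_j + U_jk + eps_jk), with empirical (population) variances
across districts; reported as median and 2.5/97.5 percentiles.  The
denominator includes heterogeneity by default (`include_eps=False`
restricts to structured terms).  The ratio is *not* clipped: empirical
covariance between the fields of one draw can push it slightly above 1,
and clipping would bias the posterior summary.

## Covariate screening

`fit_logistic` is plain IRLS/Newton with convergence at max |score| <
1e−8 or relative log-likelihood change < 1e−10 (cap 100 iterations);
quasi-separation is flagged when some |beta| exceeds 15 with the
likelihood still rising.  `backward_eliminate` drops, one per refit, the
non-forced covariate (or declared categorical block, via a Wald
chi-square) with the largest p-value above the threshold (default 0.1);
forced covariates model the a-priori demographic adjustments.  Wald tests
are the default criterion (no nested refits per candidate); a
likelihood-ratio criterion is available (`criterion="lr"`).  A drop that
induces separation is rolled back and the covariate retained with a
warning.  The procedure is deterministic given inputs and column order.

## Synthetic cohorts

The generator runs the model forward and is the ground truth for every
end-to-end test.  What it emulates:

* **Geography**: a 4 × 13 rook lattice for the 52 districts, partitioned
  along a snake path into 9 contiguous provinces carrying the real
  provincial sample totals (522, 216, 528, 450, 142, 318, 93, 175, 317;
  n = 2,761); district totals are not published, so each province's total
  is split uniformly-multinomially over its districts.
* **Covariates**, independent apart from one latent wealth factor behind
  the 12 asset indicators: age log-normal (median 56, quartiles ≈ 44/72,
  truncated to 18–95 y), 66.9% female, 68.1% urban, schooling ≈ 10 y
  median, BMI log-normal (≈3% underweight, ≈42% obese), waist-to-height
  ≈ 0.60, behavioural binaries at survey-like rates.
* **Outcome intercepts** calibrated by solving
  E[expit(alpha + Z)] = target (Gauss–Hermite quadrature, Z normal with
  the covariate + latent-field variance, covariate moments from a large
  fixed-seed reference sample) so marginal prevalences land near 23.2%
  and 12.2%.
* **Blood-pressure readings** drawn consistently with the simulated
  hypertension outcome (85% measured-high, 15% treated/self-reported);
  the three readings average exactly to the person mean, so
  re-classification reproduces the outcome.

Scenario defaults (chosen once as the study conditions): `sage-like`
sd(U) = 0.5, sd(U_k) = 0.3, sd(eps) = 0.2, log delta = log 1.3;
`strong-shared` sd(U) = 1.0, sd(U_k) = 0.15, sd(eps) = 0.10;
`no-shared` U ≡ 0; `null` everything latent and all beta = 0.  Field
standard deviations are converted to ICAR precisions through the average
diagonal of the Laplacian pseudo-inverse.  Covariate effects (log-odds):
age 0.30/0.35 per decade, female 0.40/0.30, urban −0.25/0.20 — moderate,
epidemiologically plausible magnitudes.

What the generator does **not** emulate — hence what passing tests do not
show about real survey data: complex sampling design and
post-stratification weights, correlated covariates (beyond the wealth
factor), item missingness, measurement error in self-report, real
district adjacency (any edge list can be supplied), or province-level
random effects (the model is district-only).

## Numerical choices

* Log-likelihoods are evaluated on the linear-predictor scale
  (y·eta − log1p(exp eta)) and are overflow-safe for |eta| up to ~700.
* Percentages in descriptive tables round half-up to 1 decimal.
* BMI bins are left-closed and disjoint: [18.5, 25), [25, 30), [30, ∞).
* Wealth-index PCA standardises columns (correlation-matrix PCA), drops
  constant columns with a warning, and fixes the sign so the asset with
  the largest absolute loading loads positively; tertiles cut at the
  33.33/66.67 empirical percentiles.
* Credible intervals are equal-tailed percentiles throughout.
* Complete-case handling is per fitted model; rows failing type coercion
  at ingest are dropped with a logged count.
* Split-R-hat and ESS are delegated to ArviZ (rank-normalised split R-hat,
  Geyer-truncated autocorrelation ESS); R-hat is reported unavailable for
  single chains.

## Problem sizes used by the test suite

Recovery checks run the strong-shared scenario at J = 52, n ≈ 2,800 with
2 chains × 20,000 iterations over 5 seeds; model-selection checks run 10
replicates at J = 25, n = 1,500 with 8,000 iterations.  These sizes give
stable pass/fail behaviour for the assertions made (coverage ≥ 80%, field
correlation ≥ 0.6, DIC ordering in ≥ 8/10) while keeping the default test
run in the minutes range.

## Known limitations

* Exactly two diseases; no asymmetric shared formulations and no
  spatio-temporal extension.
* `run_chain` requires a connected adjacency graph (see re-centring
  above).
* No survey weights anywhere in the likelihood.
* DIC is the only model-comparison score implemented.
* The intercept/field trade-off mixes slowly on small graphs; short
  demonstration runs can show R-hat > 1.1 on alpha blocks even when the
  surfaces of interest are stable.
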