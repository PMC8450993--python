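# Methods

This note documents the statistical machinery in `sf12impute`: the
synthetic-cohort model, the missingness (amputation) simulator, the
seven imputation engines, the concordance metric, and the numerical and
design choices behind each.

## Instrument model

Twelve items, six per subscale. Response formats: 2-level (ROLPH2,
ROLPH3, ROLEM2, ROLEM3), 3-level (PFI2, PFI4), 5-level (GHP1, PAIN2),
6-level (VITAL2, SOC2, MHI3, MHI4). Category scores are equally spaced
on [0, 100] (2-level → {0,100}; 3-level → {0,50,100}; 5-level →
{0,25,…}; 6-level → {0,20,…}); only the 0–100 range of the recode is
fixed by the instrument definition, and equal spacing is the
conventional item recode that puts every format on one metric. Subscale
scores are unweighted means of available item scores (norm-based
T-score weighting is out of scope). Missing cells are NaN in memory and
empty fields in CSV.

## Synthetic cohorts

The generator stands in for clinical and population samples that cannot
be redistributed. Per respondent *j*:

* age ~ truncated normal (clinical: M 49.74, SD 11.34, range 20–87;
  normative: M 45.62, SD 15.87, range 17–79); gender ~ Bernoulli
  (45% / 51% female); highest education multinomial over {none, SSC,
  UEQ} (clinical 65/18/17%, normative 43/20/37%).
* latent health: (phys, ment) bivariate standard normal with
  correlation 0.5, shifted by `age_health_slope · z(age)` (default
  −0.3: older ⇒ worse health on both factors) and rescaled to unit
  variance. The shared age shift raises the phys–ment correlation
  slightly above 0.5, which is intended.
* item propensity: `y_i = λ_i·factor(i) + δ·g_pair(i) + ε_i`, with the
  residual scaled so Var(y_i) = 1. The four designed item pairs
  (PFI2/PFI4, ROLPH2/ROLPH3, ROLEM2/ROLEM3, MHI3/MHI4) share a pair
  factor `g` with weight δ (`pair_loading`, default 0.45): the SF-12
  represents most health dimensions by near-duplicate item pairs, and
  this within-pair redundancy — beyond the common factor — is precisely
  the information model-based imputation exploits. Setting
  `pair_loading=0` recovers a pure one-factor-per-subscale model.
* discretisation: `score = score_values[Σ(y > t_k)]`. Thresholds default
  to standard-normal quantiles of a Binomial(L−1, m/100)-shaped
  categorical, where *m* is the item's profile target mean score — this
  matches the target mean exactly under equal spacing and yields
  plausible unimodal (or skewed, for the role items) category masses.

The per-item loadings `λ_i` ship as calibrated presets
(`presets.ITEM_LOADINGS`): they were fitted once, by iterative matching
at n = 30,000, so that the generated corrected item-total correlations
reproduce the reference per-item values for each profile (clinical
spread .34–.67, normative .50–.68, matched to ±0.01). The resulting
subscale alphas are .74/.76 (clinical physical/mental) and .83/.78
(normative) — inside the range reported for real SF-12 samples. The
calibration is frozen; it is not re-run at generation time.

What the generator does **not** emulate: multidimensional residual
structure beyond the item pairs, cross-loadings (e.g. general health on
the mental factor), response styles, item-level floor/ceiling
heterogeneity beyond the first moment, and any joint structure of
missingness across items. Passing tests therefore show that the engines
behave correctly under a faithful two-factor-with-pairs ordinal model,
not that the exact ICC levels transfer to any particular clinical
dataset.

Auxiliary health measures (`ffbh` functional capacity, `scl_dep`
depression) are linear maps of the latents plus Gaussian noise
(defaults: weights (1.0, 0.25) and (−0.25, −1.0), noise SD 0.6), on a
standardised scale; they exist for missingness screens, not as scoring
targets.

## Missingness simulation

Per item, the probability that respondent *j*'s response is missing is
`p_j = 1 − expit(b0 + b_age·age_j + b_ssc·ssc_j + b_ueq·ueq_j)`; the
packaged coefficient preset (reference estimates from clinical SF-12
data) encodes higher nonresponse for older and less educated
respondents (e.g. PFI2: b0 4.50, age −0.03, SSC 1.62, UEQ 1.11 on the
response-indicator logit). Because complete-case subsamples are younger
and better educated than the populations they come from, raw logistic
probabilities understate the target rate; the attenuation step rescales
them, `p_adjust = clip(p · h / p̄, 0, 1)`, so the mean simulated
probability equals the item's target rate *h* exactly whenever no
element clips (clipping is possible for extreme covariate patterns, is
counted and logged, and biases the realized rate slightly low; with the
packaged presets no clipping occurs). Target rates default to the
per-profile presets (clinical 1.5–17.8%, normative 0.1–0.9%).

Indicators are independent Bernoulli draws per respondent; masking
touches exactly one item per dataset, and R replicates per item (default
10 ⇒ 120 datasets per cohort) run on RNG substreams derived from
`SeedSequence(seed, spawn_key=(item_index, replicate))`, so adding
replicates never perturbs existing ones.

Diagnostics mirror standard practice: 0/1 response indicators, per-item
and per-person missing-frequency tables, Pearson screens of indicators
against demographics/health scores (pairwise-complete; subscale scores
computed from the remaining five items when screened against a
same-subscale indicator), and per-item logistic fits (statsmodels
Newton ML, tol 1e−8, max 100 iterations; Wald SEs; Nagelkerke R² =
Cox–Snell rescaled by its maximum). Separation and non-convergence
raise rather than return garbage.

## Imputation engines

All engines see only the 12-item matrix — never covariates — and fill
only the masked cells; observed cells are conserved bit-exactly.

* **IMV** — column mean of observed responses.
* **PMV** — row mean over the respondent's other observed items;
  default scope is the five remaining same-subscale items (the scale
  semantics of "the other scale items"), configurable to all 11.
* **SR_RESID / SR_T** — OLS of the incomplete item on the other 11
  (fitted on rows with the item observed), fill = prediction + error.
  SR_RESID resamples the fitted residuals with replacement; SR_T draws
  t(df)·SE with df = n_obs − 12. Singular designs raise with the
  offending columns named.
* **EM** — expectation-maximization for the incomplete multivariate
  normal. E-step: per missingness pattern, conditional means of missing
  given observed plus the conditional-covariance correction to the
  second-moment statistics; M-step: mean and MLE (1/n) covariance.
  Stops when the largest absolute parameter change < tol (default
  1e−6, max 500 iterations); the observed-data log-likelihood is
  recorded each iteration and is nondecreasing. Fills are conditional
  means — deterministic, no residual noise (`add_noise=True` opts into
  posterior-style draws). Singular observed blocks are ridge-stabilised
  with a warning.
* **MI_DA** — data augmentation under the joint normal, started at the
  EM estimate. I-step: draw each missing cell from its conditional
  normal; P-step: Σ ~ InvWishart(n−1, S) and μ ~ N(x̄, Σ/n), the
  standard draws under the Jeffreys-type noninformative prior.
  Defaults: burn-in 200 sweeps, m = 5 imputations thinned 100 sweeps
  apart (declared defaults — the method definition does not fix them).
  Non-positive-definite scale matrices are retried with jitter, erroring
  after 10 failures.
* **MI_FCS** — chained equations with one Bayesian linear-regression
  imputation model per incomplete variable (σ² ~ scaled inverse-χ²,
  β ~ N(β̂, σ²(XᵀX)⁻¹), fills from the predictive normal); m = 5
  independent chains, 10 cycles each. With a single incomplete item
  this reduces to repeated posterior-predictive regression draws, which
  is why its results track MI_DA closely.

Fills stay on the continuous scale — not rounded to legal category
scores, not clipped to [0, 100] — because concordance is evaluated on
the raw imputations; rounding would only blur the method comparison.

## Concordance evaluation

ICC(2,1) with k = 2 raters (truth, fill) from the two-way ANOVA
decomposition; the residual sum of squares is computed from explicit
residuals (not by subtraction), which keeps the constant-fill case at
zero to machine precision. Fewer than 3 pairs raise; a zero denominator
(both columns constant) returns NaN and is dropped (and counted) in
summaries. Replicate ICCs are aggregated as min/max/median/SD on the raw
scale and mean on the Fisher-Z scale (values clamped to ±(1−1e−12)
before atanh so a perfect replicate stays finite). Multiple imputation
is pooled by computing the ICC per imputation and Fisher-averaging the
m values (default), or by averaging the m fills per cell first; the two
agree when chains coincide. The discrimination–accuracy summary
correlates Fisher-Z item-total correlations with Fisher-Z mean ICCs
across the 12 items.

Why EM wins on this metric: the conditional mean maximises agreement
with the truth given the observed items, while stochastic fills pay for
their injected noise and constant/mean fills pay for bias and lost
resolution. The one regime where the (unweighted, unbiased-ish)
person mean can edge out the conditional mean is a low-communality item
— conditional-mean fills shrink toward the item mean, and ICC(2,1)
penalises the scale mismatch — which is exactly where the two weakest
unpaired items (GHP1, SOC2) land in the clinical profile.

## Pipeline and reproducibility

`run_all` executes generate → simulate → impute → evaluate for one or
two cohorts from a validated config (unknown keys rejected, all
violations reported together). Every stage draws its seed from
`SeedSequence(run_seed, spawn_key=…)`; the manifest records the config
snapshot, per-stage seeds, per-dataset realized missing counts and the
package version, and two runs with the same config produce byte-identical
result CSVs. Replicates with fewer than 3 masked cells get NaN ICCs and
are dropped from summaries with a count.

## Problem sizes used in the checks

The test suite and acceptance script size their simulations for quick
but statistically meaningful checks: cohorts of n = 2000 (headline
study, R = 10, all 7 methods), n = 5000 for rate calibration over 50
replicates, n = 200,000 for the logistic parameter-recovery study, and
n ≈ 4000 with several hundred posterior draws for the MI
conditional-distribution oracles. The recovery study uses an
informative Monte-Carlo design (age ~ U(20, 87), education 40/30/30)
rather than the observational demographics, which would leave the
education coefficients' standard errors at the edge of the ±0.05
recovery band.

## Known limitations

* Single-item missingness only; joint multi-item patterns are out of
  scope by design.
* The joint-normal assumption behind SR/EM/MI is knowingly violated by
  the ordinal items (especially the dichotomous ones); this mirrors how
  the methods are used in practice, and EM is robust to it, but the
  engines make no attempt at latent-ordinal modelling.
* MI here quantifies per-cell predictive uncertainty for concordance
  scoring; pooling of downstream analyses by combining rules is not
  implemented.
* Generated ICC levels depend on the calibrated generator; treat them
  as a reproduction of the method *ranking*, not of any dataset's
  absolute values.
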