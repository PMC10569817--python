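# Methods

## Problem setting

A cohort is a rectangular table of N participants with a binary outcome
(event / non-event), categorical predictors (sex, smoking, treatment arm,
race/ethnicity, threshold indicators) and continuous predictors (age, BMI).
When the event prevalence is low (~6 % here), the maximum-likelihood
logistic fit minimises loss by predicting "non-event" for everyone at the
usual 0.5 threshold; sensitivity collapses to 0 and the model carries no
usable information about predictor importance.  The package's remedy is to
equalise the classes *before* fitting, in a way that provably preserves the
majority class's distributional character, then read importance off the
fitted model's partial-dependence curves.

## Step 1 — distribution-matched undersampling

Draw M independent simple random samples of size n₋ (the event count),
without replacement, from the non-event rows.  Each candidate is scored
against the *full* non-event population:

- categorical variable: Pearson chi-squared goodness-of-fit of the
  candidate's level counts against expected counts from the population
  level proportions;
- continuous variable: asymptotic two-sample Kolmogorov–Smirnov test of
  candidate vs population values.

The candidate score is the unweighted sum of the per-variable p-values and
the maximiser wins (ties broken by lowest candidate index).  Summing
p-values is deliberately simple — it treats every scored variable equally
and needs no calibration; a Fisher-style combination would over-weight a
single discordant variable for this selection purpose.

Test assignment rationale: the KS statistic is undefined for nominal data,
and the chi-squared test discards information when applied to binned
continuous data, so each variable type gets the test that suits it.  Age
and BMI are scored in continuous form by default; the binarized indicators
(age > 65, BMI > 25) remain available and can be scored instead via the
`variables` argument.

Defaults: M = 1,000 candidates.  The studies in the test-suite and the
acceptance script use M = 100 on cohorts of n = 30,000 — the selected
score's distribution is already tight there and the full M = 1,000 changes
nothing but runtime; M is a single argument away.

RNG contract: the call's seed feeds a `SeedSequence`, and candidate c uses
the c-th spawned child stream.  Scores are therefore independent of the
order in which candidates are evaluated, and the whole selection is
bit-reproducible from `(cohort, m, seed)`.

Degenerate inputs: an empty candidate errors; a categorical level absent
from the majority population is dropped from scoring with a warning (with
population-derived expected counts such a level can never be observed in a
candidate, which is a subset of that population); an event class larger
than the non-event class is rejected as "not an imbalance problem".

### Stratified variant

The cross of the stratifying variables (categorical; typically the age > 65
indicator and sex) partitions both classes.  Each candidate draws, within
every stratum, exactly the event class's count from that stratum's
non-event rows, so the sampled rows' joint strata distribution equals the
event class's *exactly* (chi-squared statistic of the strata table is 0 by
construction).  The target could equally have been the majority's own
strata distribution; matching the minority's is chosen because the
variant's purpose is to control age and sex out of the comparison, and
that requires the two classes to agree on them.  Candidates are drawn
jointly (one RNG stream per candidate, quotas fixed per stratum) and
scored on the non-stratum variables only.  A stratum where the non-event
rows cannot cover the quota raises an error naming the stratum.

### SMOTE (comparison method)

Synthetic-minority oversampling balances the classes from the other side:
each synthetic event row is a uniform convex combination z = (1−λ)·xᵢ +
λ·xⱼ of a random event row xᵢ and one of its k nearest event neighbours xⱼ
(k = 5, the technique's conventional default), with Euclidean distance
taken on standardized features: categorical predictors one-hot encoded,
all features centred/scaled by the pooled (both classes) mean and SD.
Indicator columns of a synthetic point are rounded back to {0, 1} by
argmax within each factor's block; parent indices and λ are recorded so
the convexity of every synthetic point is verifiable after the fact.
SMOTE's output retains all real rows plus n_majority − n_minority
synthetic rows, yielding equal classes of size n_majority.

## Step 2 — logistic regression and evaluation

`statsmodels` supplies the maximum-likelihood fit.  Factors use treatment
coding with the most frequent level as default reference (configurable),
which on trial-like data reproduces the conventional baselines (male,
age ≤ 65, BMI ≤ 25, non-smoking, placebo, largest race group).  Reported
alongside the coefficients: log-likelihood ℓ, AIC = −2ℓ + 2k,
BIC = −2ℓ + k·ln n (k = number of estimated parameters including the
intercept), and deviance = −2ℓ (the saturated log-likelihood is 0 for
Bernoulli data).

Separation is detected, not papered over: statsmodels' perfect-separation
warning, or any coefficient whose standard error exceeds 100 on the
log-odds scale, raises an error naming the offending term.  No penalised
fallback is applied — a quasi-infinite coefficient is a property of the
data the analyst should see.  Non-convergence likewise raises.

Confusion metrics are computed in-sample on the set the model was fitted
to by default, mirroring the balanced-vs-imbalanced comparison the
pipeline makes; an outcome-stratified holdout split is available
(`holdout_fraction`) for out-of-sample evaluation.  Precision and NPV are
reported as *undefined* (`None`) when their denominators are empty — the
all-negative classifier's precision is meaningless, not zero.

The two-proportion test uses the pooled chi-squared statistic without
continuity correction (df = 1) and a Wald-type unpooled CI; a pooled
proportion of exactly 0 or 1 returns χ² = 0, p = 1.  The multi-level
factor test is the joint Wald χ² b'V⁻¹b on the factor's L−1 coefficients
with the fitted covariance block, df = L−1.

### Case–control intercept shift

Undersampling the controls at fraction f = n₋/n₊ leaves the slope
estimands untouched but shifts the intercept by −ln f (standard
case–control sampling theory).  The parameter-recovery study checks both
facts: slopes within 3 estimated SEs of the generating values, intercept
within 3 SEs of β₀ − ln f.

## Step 3 — PDP-flatness importance

The partial dependence of the fitted model on predictor x is
PD(g) = mean over rows i of p̂(x = g, other columns as observed), computed
on the probability (response) scale — flatness of the *predicted response*
is what makes a predictor uninfluential for the outcome, and the response
scale keeps scores comparable across models.  Continuous grids use 20
equally spaced quantiles of the observed values (the sweep stays inside
the data's support); categorical grids enumerate the observed levels.

Scores: sample SD of the curve for continuous predictors; (max−min)/4 for
categorical ones — range/4 is the usual scale-matching convention that
makes a two-level factor's score comparable to an SD.  A predictor absent
from the model scores exactly 0.  Ranking is by descending score with
alphabetical tie-break for determinism.

## Synthetic cohort generator

The generator emulates the structure of a large randomized vitamin-D
prevention trial: race drawn from {NHW 71, NHB 20, Hispanic 4} %
renormalized over the three modeled groups; conditional on race, sex
(female fraction 48/62/35 %), current smoking (5/14/6 %), age and BMI
normal with the published per-group means and SDs (overall means 66.6 y
and 28.1 kg/m²), truncated to [50, 100] y and [15, 60] kg/m²; treatment
arm Bernoulli(0.5) independent of everything.  The outcome is Bernoulli
with logit(p) = β₀ + Σβⱼxⱼ on the indicators age > 65, BMI > 25, female,
smoker, active arm, race dummies; default effects are the pooled-model
estimates (0.5, 0.09, −0.43, 0.47, −0.05, −0.44, −0.48).  β₀ is calibrated
by root-finding on a 200,000-draw covariate pilot (its own fixed seed,
independent of cohort seeds) so the overall prevalence hits the 6.3 %
target; with all effects zeroed the calibration is exactly
logit(prevalence).

What the generator does **not** emulate: within-race covariate
correlations (covariates are conditionally independent given race — only
marginals and per-race contrasts are published), longitudinal follow-up,
censoring, mortality, or a second treatment factor.  Consequently, passing
tests demonstrate that the method recovers known effects under the
trial's marginal structure; they cannot certify behaviour under strong
covariate dependence, which real cohorts may exhibit.

## Study sizes and numerical choices

- Recovery/importance studies: 20 cohorts of n = 30,000 at the default
  (≈6.3 %) prevalence, best-of-100 undersampling — sizes at which the SEs
  are comparable to the motivating trial's and the studies complete in
  about a minute.
- Marginal-agreement study: n = 16,000 per cohort so the event class is
  ≈1,000, best-of-10.
- KS p-values use the asymptotic two-sample form (the finite-n Kolmogorov
  distribution at the effective sample size); ECDF steps at each observed
  value handle ties.
- Chi-squared scoring requires at least two populated levels; the score
  sums p-values exactly (no weighting).
- All tolerances in tests are stated at the arithmetic's natural precision
  (1e-8–1e-12 for deterministic identities; seed-count thresholds like
  18/20 for Monte-Carlo properties).

## Known limitations

- Undersampling discards most of the majority class; with very small event
  counts the balanced set is small and coefficient SEs grow accordingly.
- The best-of-M criterion optimises marginal agreement only; joint
  (multivariate) distributional agreement is not scored.
- PDP importance inherits the fitted model's additivity: interactions not
  in the model cannot surface in the ranking.
- In-sample metrics on the balanced set are optimistic relative to a held
  out evaluation; the holdout flag exists for that reason.
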