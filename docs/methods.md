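# Methods

`rwcea` implements a population-based, payer-perspective cost-effectiveness
comparison of two treatment strategies from patient-level administrative
claims: confounding control by propensity score (stabilized IPTW as the base
case, 1:1 caliper matching as a sensitivity analysis), censoring-adjusted
mean outcomes over a 5-year horizon via an interval-partitioned IPCW
estimator, and incremental economics (ICER with dominance handling,
net-benefit regression, nonparametric bootstrap, CE plane, CEAC). Because
real claims data of this kind are held behind data-access agreements, the
package carries a synthetic cohort generator with known ground truth; every
estimator is validated against that truth or against hand-computed worked
examples.

## Estimands and notation

For each arm we estimate discounted 5-year means of three quantities:
life-years (restricted mean survival time), quality-adjusted life-years, and
cost (total and per component). The horizon is H = 1826 days (5 x 365.25,
rounded down), partitioned into K = 61 intervals of L = 30 days (the last
interval is 26 days). With Q_ik the quantity accrued by patient i over
interval k, w_i an analysis weight, and omega_ik a censoring weight, the
partitioned estimator is

    mean = sum_k D_k * [ sum_i w_i omega_ik Q_ik ] / [ sum_i w_i ]

with discount factor D_k = (1+r)^(-m_k / 365.25) at the interval midpoint
m_k, r = 0.015/year by default. All follow-up times are integer days from
the index (treatment initiation) date.

## Propensity model and weights

The propensity score e(X) = P(focal arm | X) is a maximum-likelihood
logistic regression (statsmodels, Newton, gradient tolerance 1e-10, at most
100 iterations). Categorical covariates expand to indicator contrasts.
Perfect or quasi-separation (diverging coefficients, |log-odds| > 30) and
non-convergence raise explicit errors rather than returning degenerate
weights. Stabilized weights are w_i = p_T/e_i (focal) and
(1-p_T)/(1-e_i) (comparator) with p_T the observed treated fraction, so
each arm's effective size stays near its raw size; no trimming is applied
by default (an optional clip at configurable score bounds exists).

Balance is assessed by absolute weighted standardized differences:
continuous d = |m1-m2| / sqrt((s1^2+s2^2)/2) with frequency-weight
variances sum(w (x-m)^2)/(sum w - 1); binary d uses weighted prevalences.
|d| <= 0.1 is the conventional adequacy threshold. The binary formula is
what the reproduced published balance rows exercise; those targets are
insensitive to the variance-normalisation choice.

Matching (sensitivity analysis) is greedy 1:1 nearest-neighbour without
replacement on logit(e), caliper 0.2 x SD of logit(e) over the whole
cohort. The caliper is applied on the logit scale because the 0.2-SD
convention originates there; the matching order is randomized by seed to
remove input-order artifacts. Matched patients get weight 1, others 0.

## Censoring adjustment

The censoring distribution K_c(t) = P(censoring > t) is estimated by
Kaplan-Meier with censoring as the event and death as the competing
(censored) observation, pooled across arms (a per-arm option exists but the
pooled fit is the default, matching the independent-censoring assumption).
Deaths at t remain at risk for censoring events at t (lifelines' tie
convention realises this).

Completeness: delta_ik = 1 iff the patient was not censored before
min(death_i, e_k), where e_k is the interval end. A death during interval k
contributes its partial-interval quantity with delta = 1 (death is
observation, not censoring); a patient censored during interval k
contributes nothing for k — partial pre-censoring accrual is discarded,
the simple form of the partitioned estimator. Weights are
omega_ik = delta_ik / K_c(min(death_i, e_k)^-), evaluated at the left limit
so a censoring event exactly at the evaluation time does not deflate its
own weight. If K_c reaches zero where a weight is required the estimator is
not identified and the code raises an error naming the interval. With no
censoring in the data, every omega is exactly 1 and the estimator
reduces to the plain weighted mean at machine precision (tested).

## Outcomes

* Life-years: Q_ik = days alive in interval k / 365.25; fractional days are
  credited at death.
* QALYs: days alive split at the end-of-treatment day (the progression
  proxy): utility 0.8 on treatment (index through EOT) and 0.73 afterwards,
  both defaults configurable with the constraint 0 <= u_post <= u_pre <= 1.
  QALYs are discounted like survival by default (flag-controlled), since
  both survival and costs are discounted in the motivating design.
* Costs: recorded per-interval amounts per component; per-component means
  are estimated component-wise and the total is their sum (exact by
  construction).

Per-patient discounted, censoring-weighted totals E_i = sum_k D_k omega_ik
Q_ik are the building block everywhere: the weighted arm mean of the totals
equals the partitioned estimator exactly, which makes the net-benefit
regression identity below hold to machine precision.

## Economic evaluation

Incremental quantities are focal minus comparator. The ICER dC/dE is
reported only in the concordant quadrants; discordant sign patterns are
classified as "dominated" (dC > 0, dE < 0) or "dominant" (dC < 0, dE > 0),
and dE = 0 is reported by the sign of dC. Per-patient net monetary benefit
at willingness-to-pay lambda is NMB_i = lambda E_i - C_i; weighted least
squares of NMB_i on the treatment indicator (analysis weights as WLS
weights) yields INMB(lambda) = lambda dE - dC as the treatment coefficient,
exactly linear in lambda. The WTP grid default is $0-200,000 in $10,000
steps.

Uncertainty: patients are resampled with replacement (whole records), and
the propensity model, weights or matching, censoring survivor and IPCW
table are all re-estimated inside each replicate (B = 1000 by default), so
the intervals reflect estimation uncertainty in every stage; a
fixed-weights variant is available for comparison. Replicates that leave an
arm with fewer than two patients are redrawn and counted (warned above 1%
of B). CIs are percentile (simplest defensible choice; no BCa). The CEAC at
lambda is the fraction of replicates with lambda dE_b - dC_b > 0; CE-plane
quadrants are counted on (x = dE, y = dC) with NW meaning less effective
and more costly.

## Synthetic cohort generator

The generator emulates the *structure* of a provincial claims cohort:

* covariates: age ~ N(65, 9), female (p = 0.435), ECOG 1 vs 0 (p = 0.69),
  metastatic vs locally advanced (p = 0.69), prior cancer (p = 0.16);
* assignment: logistic in age, ECOG and extent of disease; coefficients
  chosen so the focal arm skews older/frailer and the marginal focal
  fraction is ~0.47, matching the motivating study's arm split;
* survival: per-arm Weibull (shape 1.1; scales 265 and 420 days, i.e.
  medians near 6 and 10 months), with accelerated-failure-time covariate
  effects on the log scale (age, ECOG, extent) so that assignment is
  genuinely confounded with survival. With those coefficients zeroed the
  model is pure per-arm Weibull and truths are analytic;
* end of treatment: Uniform(0.2, 0.8) fraction of survival time (the
  motivating design treats end of treatment as a progression proxy without
  describing its distribution; configurable);
* censoring: independent exponential (default 4e-4/day, roughly 11% of
  patients) plus an administrative cutoff; recovery tests raise the rate
  to ~25%. A covariate-dependent censoring option is deliberately absent
  from the default path, matching IPCW's identifying assumption;
* costs: nine components accrued per 30-day interval as lognormal draws
  with means split by on/off-treatment state, an elevated terminal-phase
  multiplier in the interval of death (reproducing the right-skewed,
  death-concentrated claims pattern), and optional occurrence thinning for
  episodic components. Default means were calibrated once, via the truth
  oracle, to the per-component 5-year magnitudes of the motivating study
  (focal ~ $103k vs comparator ~ $100k, incremental ~ +$2.5k), and are
  order-of-magnitude only.

What the generator does not emulate: database linkage error, unit-cost
derivation (resource-intensity weights), covariate-dependent censoring by
default, non-proportional cost inflation, or any Ontario-specific pricing.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated data-generating assumptions, not robustness to violations
of them.

## Ground truth

`compute_truth` never calls the estimation pipeline. Restricted mean
survival is the analytic integral int_0^H S(t) dt (adaptive quadrature;
discounted variant integrates S(t) (1+r)^(-t/365.25)) when survival has no
covariate dependence, and otherwise a Monte-Carlo average over 200,000
simulated subjects with the discounted years-alive in closed form per draw.
Cost truth always uses the Monte-Carlo oracle with censoring disabled and
noise-free expected per-interval accrual, mirroring the generator's
integer-day discretisation. Common random numbers are shared across the two
counterfactual arms, so identical arm parameters give exactly zero
incremental truth.

## Numerical choices and edge cases

* Discounting at interval midpoints with annual compounding converted by
  days/365.25; midpoint evaluation keeps the within-interval discounting
  error below 0.1% of the closed-form continuous integral at r = 1.5%.
* Survival times are drawn continuously and recorded as integer days
  (ceiling); the <= 0.5-day discretisation offset is negligible against the
  Monte-Carlo tolerances used and cancels in incremental contrasts.
* Zero pooled variance with a nonzero mean difference reports an infinite
  standardized difference with a warning rather than an error.
* An empty matched cohort (no pairs within caliper) is a warning, not an
  error; empty arms and zero-weight arms raise.
* Missing values in cohort CSVs are empty fields only; any other token is a
  parse error naming the row, to keep silent sentinel corruption out.
* Eligibility exclusions are applied in the motivating protocol's narrative
  order (treatment-before-diagnosis, death-before-index, non-resident,
  missing income, missing rurality, missing extent, ECOG >= 2 or missing);
  order affects only per-rule counts, never the retained set.

## Problem sizes used in validation

The validation suite exercises: worked examples at n = 2-6 (hand
arithmetic, exact to 1e-12); no-censoring equivalence at n = 1,000 (machine
precision); closed-form exponential recovery at n = 10,000 with ~25%
censoring (2 Monte-Carlo SEs); estimator unbiasedness over 60 replicates at
n = 2,000; and confounded parameter recovery over 50 replicates at
n = 2,000 with B = 200 bootstrap replicates per cohort (bootstrap CI
coverage of the true incremental life-years within [90%, 99%]). The
analysis drivers run the full cohort (n = 1,988) with B = 1,000. These
sizes are the package's validation design; all are configurable.

## Known limitations

* Percentile bootstrap CIs can undercover slightly at modest B; BCa is out
  of scope.
* The censoring model is marginal (no covariate-adjusted censoring
  weights); informative censoring correlated with covariates will bias the
  estimator, by design of the method.
* Greedy matching is order-dependent in principle; seed-randomized order
  plus the caliper makes the matched-set differences immaterial in the
  configurations tested, but optimal matching is not implemented.
* The generator's cost magnitudes are illustrative calibrations, not fitted
  to any patient-level data.
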