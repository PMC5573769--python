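# Methods

This note records the modelling choices, defaults, and limitations of the
package.  Everything stated here is computed by the code and exercised by
the test suite; nothing is an empirical claim beyond what the tests and
the acceptance script reproduce.

## The synthetic world

The generator (`synthworld`) builds a world of N locations (default 6)
spanning a development gradient d ∈ [0, 1], years 1990–2015 in 5-year
steps, 5-year age bands 0–95+ (closed-open [a, a+5), terminal 95+), and
two sexes.  Disease rates are piecewise-constant within age bands
(evaluated at band midpoints) and sex-shared by default; the solver
integrates them on a 1-year grid with classical Runge–Kutta at 4 substeps
per year, so stored band prevalence is the integral mean of the exact
illness-death solution and the world is internally consistent by
construction (checked to 1e-6 in the tests).

Baselines were chosen once to be epidemiologically plausible and are not
calibrated to any country:

* COPD: incidence 3e-4·exp(0.045·(a−25)) above age 25 (floor 1e-5),
  remission 0 (chronic, incurable), excess mortality
  2e-3·exp(0.045·(a−30)); prevalence reaches a few percent to ~30% at old
  ages depending on exposure.
* Asthma: childhood-onset incidence 6e-3·exp(−0.05·a) (floor 8e-4),
  remission 0.035/year, flat low excess mortality 4e-4.
* Background mortality: Gompertz 3e-4·exp(0.082·a) plus an infant term.

Risk exposures (smoking, second-hand smoke, household air pollution,
ambient PM2.5, ozone, occupational particulates for COPD; smoking and
occupational asthmagens for asthma) are deterministic functions of
development and calendar time — smoking and solid-fuel use fall with
development, ambient PM2.5 peaks mid-transition.  True incidence and
excess mortality scale log-linearly in the exposures with configured
effects; rescaled log-income enters excess mortality with effect −0.8
(case fatality falls with wealth).  The "combined risk scalar" covariate
supplied to the consistency fit is the true log-linear predictor, so its
coefficient should recover ≈ 1.

Sampling models: binomial at the survey's effective sample size for
prevalence datapoints (standard error sqrt(p̂(1−p̂)/n), p̂ floored at
0.5/n); Poisson for death counts; Gaussian on the ln(1−DW) scale for
encounter disability weights.  Each data stream draws from its own
generator split from the master seed, so streams can be toggled without
perturbing one another.  With noise off every stream equals its
expectation exactly.

What the world does **not** emulate: real-country magnitudes, correlated
survey design effects, age-dependent exposure, asthma–COPD overlap
(no consensus definition exists, so the two diseases are independent),
VA misclassification beyond cause aggregation (its magnitude is a free
parameter, not asserted), and secular trends other than the smooth
exposure drifts above.  Passing tests therefore demonstrate correctness
of the estimation machinery under a known generating model, not fidelity
to any real population.

## Data-quality parameters

Verbal-autopsy fraction per location defaults to 0.8·(1−d)^1.5 and VR
completeness to 0.7 + 0.3·d.  Demographic completeness estimation is out
of scope, so the pipeline treats completeness as known and divides
recorded VR deaths by it on entry; similarly all-cause mortality and
background mortality are taken from the demographic truth tables as given
inputs, mirroring the upstream all-cause envelope that the real chain
receives from demographic estimation.

## Crosswalks

Alternative spirometric definitions (pre-bronchodilator GOLD, LLN
variants) are adjusted by ratio(age) = exp(b0 + b1·age) fitted by least
squares of log ratios on age, using cells observed under both the
alternative and reference definitions (reference prevalence ≥ 0.01 to
keep ratios stable).  The adjusted mean divides by the ratio; the
standard error inflates by the delta method, SE' = sqrt((SE/ratio)² +
(mean/ratio)²·σ_res²), so adjustment never shrinks uncertainty.
Self-report and diagnosis-only definitions are instead handled inside the
consistency fit as study-level multipliers — two distinct adjustment
routes on purpose.  The algebraic direction (divide the alternative by
the fitted ratio) is this package's convention.

## Cause-of-death ensemble

Component families: linear mixed models of log death rates and of logit
cause fractions, always with age-band fixed effects and a location random
intercept, over an explicit pool of covariate subsets (no automated
covariate search).  MixedLM variance profiles occasionally diverge on
near-collinear covariates; a guard refits plain least squares when the
fixed-part training RMSE is implausible.  Out-of-sample weighting holds
out 20% of location-years, 5 repetitions, seeded; weights are
exp(−RMSE/τ) with τ = 1 in log-rate units.  Spatiotemporal Gaussian
processes are reduced to the location random effects — the ensemble
architecture is preserved at desk scale, the smoother is not.
Draws sample a component per draw (model-selection uncertainty) and then
from its predictive normal in link space.

## Consistency meta-regression

Age knots default to {0, 5, 15, 30, 45, 60, 75, 90}; log-scale Gaussian
smoothness priors on adjacent knot differences (sd 1.0 by default, 3.0 in
the recovery experiments where the truth is rough); ridge priors (sd 2)
on covariate coefficients; birth prevalence fixed at 0 for both diseases
(asthma's childhood onset is carried by high early incidence); COPD
remission fixed at zero, asthma remission fitted from sparse remission
datapoints.  Datapoints spanning age bands are integrated over the
solution (band averages on the substep grid), not midpoint-evaluated.
Transition rates are capped at 2/year inside the objective: higher values
are epidemiologically meaningless here and would destabilise the
fixed-step integrator during line search.

Optimisation is L-BFGS-B warm start followed by Gauss–Newton /
Levenberg–Marquardt polish; the Gauss–Newton curvature at the optimum
doubles as the Laplace covariance from which posterior draws are taken
(income coefficient truncated at 0 per draw).  This is a deliberate
light-posterior substitute for full MCMC: it preserves the consistency
architecture and uncertainty semantics at desk scale.  Posterior
calibration is checked empirically — over 200 simulated datasets the 95%
prevalence intervals cover truth within a 90–99% band, the slack
acknowledging curvature-approximation error.  The fits pool sexes (the
generator's rates are sex-shared); per-sex fits would double runtime
without exercising new code paths.  Whether the combined-exposure scalar
should enter incidence or prevalence is not externally fixed; it enters
incidence here.

## Severity

Disability weights per health state are configuration fixtures
(placeholders on the GBD scale, **not** authoritative elicited values):
COPD asymptomatic 0 / mild 0.019 / moderate 0.225 / severe 0.408; asthma
asymptomatic 0 / controlled 0.015 / partially controlled 0.036 /
uncontrolled 0.133.  Encounter records are decomposed by regressing
ln(1−DW) on condition indicators without intercept (the multiplicative
comorbidity model is additive on that scale) and attributing to each
individual their observed log-complement minus the estimated components
of their other conditions.  Classification uses midpoint cutpoints with
two conventions: the asymptomatic state is exactly DW = 0 (the first
threshold sits just above zero), and a weight exactly at a cutpoint goes
to the more severe state.  The GOLD→state map is a monotone coupling of
the two severity distributions (cumulative-quantile alignment); it
reproduces the reference state distribution exactly and is row-stochastic
and severity-ordered by construction.  The asthma split is a single
global distribution, reproducing the simplifying assumption that the
US-derived severity distribution generalises everywhere.  The overlap
between spirometric GOLD I cases and symptom-free (asymptomatic) cases is
handled implicitly by the quantile alignment and not otherwise resolved.

## Comparative risk assessment

Functional forms are the standard multi-category and integral
attributable-fraction formulas; no other forms are consistent with an
exposure/relative-risk/theoretical-minimum triple.  Smoking is modelled
categorically (never/former/current).  TMRELs: zero or none-exposed for
smoking, second-hand smoke, household air pollution and the occupational
exposures; uniform intervals for ambient PM2.5 (2.4–5.9 µg/m³) and ozone
(33.3–41.9 ppb), sampled once per draw.  Relative-risk uncertainty is a
shared log-normal shift per draw.  Mediation across multiple mediators
aggregates on the complement scale (MF_total = 1 − Π(1 − MF_j)) — the
aggregation rule is this package's choice.  The pipeline's vectorised
continuous-PAF path (Gauss–Legendre, 200 nodes) is verified against the
adaptive-quadrature reference in the tests.  PAFs vary by location-year
but not by age or sex (exposures are location-year level inputs).

## Burden accounting and reporting

The standard life table and standard population shipped under
`respburden/data/` are smooth synthetic fixtures, **not** authoritative
published tables.  Uncertainty intervals use the order-statistic rule
(25th/975th of 1000; floor(0.025·n + 0.5) scaled for other counts);
significance of a change requires strictly more than 95% of draw-wise
differences to share a sign.  Percent change is computed draw-wise, never
on means, so summary rows need not satisfy cross-tabulation identities
that only hold at the draw level.  Comorbidity correction across causes
(microsimulation) is out of scope; YLDs are per-cause products.  Rates
are per 100 000 person-years.

SDI is the geometric mean of rescaled log-income, education, and reversed
total fertility over the pooled location-year window; quintile cutoffs
use linear order-statistic interpolation on the pooled distribution with
labels from each location's 2015 value.  The expected-burden curve is a
LOESS (degree 1, tricube, span 0.6 — the span and degree are defaults,
not externally given), fitted unweighted over all location-years; the lag
distribution of income is an input column, not computed.

## Problem sizes and numerical tolerances

The demo pipeline uses 6 locations, 6 years, 20 age bands, 2 sexes and
100 draws (~60 s end to end); the default draw count for the container
types is 1000.  Solver tolerance against the closed-form limit is 1e-6;
squeeze conservation is exact to 1e-12; the noise-free recovery target is
2% relative at all knots; comorbidity-weight recovery 0.01 absolute at
n = 10 000.  Reruns with the same seed are byte-identical (all float
output is written at 12 significant digits; every random stream descends
from the master seed).

## Known limitations

* The Laplace posterior understates skewness for parameters near bounds
  (notably the income coefficient when weakly identified).
* The ensemble's predictive-validity metric is RMSE only; a trend
  component would be a natural extension.
* VR completeness and background mortality are supplied, not estimated.
* Crosswalk curves are fitted pooled across sexes and assumed log-linear
  in age over the observed range; extrapolation beyond it is logged.
* The single-level meta-regression has no location-hierarchy cascade;
  location heterogeneity enters only through covariates.
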