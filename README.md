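# respburden

A desk-scale, fully tested re-implementation of the GBD 2015 estimation
chain for the global burden of chronic obstructive pulmonary disease
(COPD) and asthma.  It is written for epidemiologists and biostatisticians
who want to study, teach, or stress-test the machinery of burden-of-disease
estimation — case-definition crosswalks, cause-of-death ensembles,
illness-death consistency modelling, severity splits, comparative risk
assessment, and draw-based DALY accounting — without the full GBD input
database.  All data streams come from a seeded synthetic world whose
ground truth is known, so every stage can be validated against the truth
it was generated from.

## The models

**Illness-death consistency.**  Prevalence p, incidence i, remission r
(the cure rate), excess mortality f, and background mortality m are linked
through the two-compartment system

    dS/da = -(i + m) S + r C
    dC/da =  i S - (r + m + f) C,        p(a) = C / (S + C)

with S(0) = 1, C(0) = 0.  The meta-regression (`dismod_lite`) fits
log-rates on age knots by maximum a posteriori with Gaussian smoothness
priors, study-level multiplicative covariates for non-reference case
definitions, a combined risk-exposure scalar on incidence, and income on
excess mortality with the coefficient constrained non-positive.  Every
predicted measure is the illness-death solution of the fitted rates —
consistency is structural.  Posterior draws come from the Gauss–Newton
curvature at the optimum.

**Cause-of-death ensemble.**  Mixed-effects regressions of log death
rates and logit cause fractions on varying covariate subsets are weighted
by out-of-sample RMSE, w_k ∝ exp(−RMSE_k/τ).  Verbal-autopsy records
carry only the aggregate chronic-respiratory cause; specific causes are
fitted on vital registration and squeezed to the envelope draw by draw
(child'_k = child_k × envelope / Σ_j child_j), then all causes to
all-cause mortality.

**Comparative risk assessment.**  PAF = Σ p_i (RR_i − 1) / (Σ p_i (RR_i −
1) + 1) for categorical risks and (E_f[RR] − E_g[RR]) / E_f[RR] against a
theoretical-minimum exposure distribution g for continuous ones; mediation
discounts PAF' = 1 − (1 − PAF)^(1 − MF); risks combine multiplicatively,
1 − Π(1 − PAF_k), so attribution never exceeds the total burden.

**DALY accounting.**  YLL = deaths × standard remaining life expectancy;
YLD = Σ states prevalence × disability weight × population; DALY = YLL +
YLD, all computed on aligned vectors of posterior draws.  Uncertainty
intervals are the 25th/975th order statistics of 1000 draws; a change is
significant when >95% of draw-wise differences share a sign.

## Worked example

Run the demo world (6 locations spanning the development spectrum, years
1990–2015 in 5-year steps, 100 posterior draws) end to end:

```bash
respburden all --seed 11 --draws 100 --outdir demo_out
respburden report --outdir demo_out
```

The global rows of `demo_out/burden_summary.csv` (counts in thousands,
95% uncertainty intervals from draw order statistics):

```
 cause stratum  daly_thousands  daly_lower  daly_upper  daly_pct_change  daly_change_significant
  copd  global          1058.2       996.7      1120.7              1.4                    False
asthma  global           291.5       279.2       304.0              9.0                     True
```

COPD DALYs dominate asthma DALYs in this world because COPD carries far
higher excess mortality at old ages (YLL-dominated), while asthma burden
is mostly years lived with disability — the same asymmetry seen in real
global estimates.  The attribution table
(`attribution_by_quintile.csv`) decomposes COPD DALYs into exclusive
behavioural / environmental-and-occupational contributions per
Socio-demographic-Index quintile:

```
cause     stratum  env_only_pct  joint_pct  beh_only_pct  unattributed_pct
 copd      middle          31.3       19.9          18.9              29.8
 copd        high          18.8        8.5          22.1              50.6
```

Middle-development locations carry the largest environmental share
(household and ambient air pollution peak mid-transition), and the four
columns sum to 100 exactly by construction.  Magnitudes are properties of
the synthetic world, not of any real country.

## Layout

| module | role |
|---|---|
| `synthworld` | seeded synthetic world: surveys, death records, encounters, exposures, SDI components |
| `crosswalk` | exponential age-ratio adjustment of non-reference case definitions |
| `codem_lite` | cause-of-death component models, predictive-validity weighting, envelope squeeze |
| `dismod_lite` | illness-death solver and consistency meta-regression |
| `severity` | GOLD-class scaling, comorbidity-corrected disability weights, state maps |
| `cra` | population-attributable fractions, mediation, multiplicative combination |
| `burden` | draw cubes, YLL/YLD/DALY, age-standardisation, uncertainty intervals |
| `sdi_report` | SDI construction, quintiles, LOESS expected curves, reporting |

See `docs/methods.md` for modelling assumptions, defaults, and
limitations.
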