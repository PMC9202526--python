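# Methods

## The model family

`ckbcvd` implements the CKB-CVD family of sex-specific 10-year cardiovascular
risk models for Chinese adults aged 30–79. Rather than a single model for a
composite endpoint, the family consists of three cause-specific Cox
proportional-hazards submodels per sex — ischemic heart disease (IHD),
ischemic stroke (IS) and hemorrhagic stroke (HS) — because the relative
burden of these outcomes varies strongly across regions of China and a
composite model's coefficients would be driven by the outcome mix of its
derivation cohort. Each submodel converts a linear predictor into an
absolute 10-year risk through a baseline survival anchor:

    risk_k(x) = 1 − S0_k(10) ^ exp(LP_k(x)),    k ∈ {IHD, IS, HS}

and the total CVD risk combines the three under a conditional-probability
(independence) identity:

    risk_CVD = 1 − (1 − risk_IHD)(1 − risk_IS)(1 − risk_HS).

The seven predictors — age, systolic and diastolic blood pressure, use of
blood-pressure-lowering treatment, current daily smoking, self-reported
diabetes, and waist circumference — are exactly the fields available in
China's resident health records; no blood lipids are required. Continuous
predictors enter linearly in model units (age per 5 years centered at 55;
SBP/DBP per 10 mm Hg centered at 120/80 mm Hg; waist per 10 cm centered at
80 cm); binaries are 0/1 centered at absent. Each non-age predictor also has
an age-interaction term coded `u_age · u_p` with `u_age = (age − 55)/5`, so
an interaction coefficient is a log-hazard-ratio per model unit of the
predictor per 5 years of age. This coding is stated prominently because the
published hazard-ratio table prints the interaction column without unit
annotation.

The packaged coefficient files store `ln(HR)` at the 2-decimal precision of
the published hazard ratios; the exact regression coefficients were never
released. Parameter-recovery checks therefore use tolerances, never
equality. Hazard ratios are stored alongside the log values for human
audit, and the JSON schema is versioned.

## Derivation

`fit_stratified_cox` maximizes the region-stratified partial likelihood with
the Efron tie correction by Newton–Raphson with step-halving; convergence
requires max |gradient| < 1e-7 and relative log-likelihood change < 1e-9
within 100 iterations. Risk-set suffix sums are accumulated from segment
sums between consecutive distinct event times (`np.add.reduceat`), which
keeps a 13-parameter fit on 200,000 subjects around five seconds on one
core. Efron was chosen because tied times arise naturally when synthetic or
registry data carry coarse time resolution; with continuous times it reduces
to the Breslow form. The fitter agrees with an independent implementation
(lifelines `CoxPHFitter`) to ~1e-5 on identical data, and with a 1-D
grid-search maximizer of a hand-written partial likelihood to 1e-3 on tiny
fixtures; those cross-checks live in the test suite.

Event-time conventions: time on study is the scale; a subject's first event
among {IHD, IS, HS, unspecified stroke, non-CVD death} determines their
(time, event) pair, and for each target outcome all other first events
censor at that time (cause-specific hazards). Unspecified stroke counts
toward total-CVD evaluation but belongs to none of the three submodels.
Covariates with zero variance are excluded from optimization and reported
with coefficient 0 and infinite standard error rather than failing the fit;
diverging coefficients (|β| > 50) raise a separation error.

Baseline survival per region is the Breslow estimator evaluated at the
centered covariate origin, `S0_r(10) = exp(−H0_r(10))`; a region with no
target events before the horizon gets `S0_r = 1` with a warning. The pooled
`S0(10)` is the mean of regional values weighted by the number of
target-outcome events occurring by 10 years.

Internal–external cross-validation leaves one region out, fits on the rest,
and computes Harrell C in the held-out region; per-region values are pooled
by inverse-variance fixed-effect weighting on the C scale (the source
publication says only "pooling"; this is the declared choice). Regional
standard errors are floored at 1e-10 so that degenerate regions (all-tie or
perfect discrimination) do not divide by zero.

The independence assumption behind the risk combination is *reported, not
enforced*: `independence_diagnostic` compares the mean combined predicted
risk with an Aalen–Johansen any-CVD cumulative incidence that treats
non-CVD death as a competing risk. Proportional-hazards assessment is
supported by `schoenfeld_residuals` (unscaled residuals per event time) for
graphical use only.

## Recalibration

Both recalibration methods replace each submodel's baseline survival for a
target region and leave every regression coefficient untouched, so each
submodel's risk undergoes a strictly monotone transform and within-region
concordance is unchanged bit for bit.

**Practical** recalibration needs only cross-sectional summaries: per
5-year age group, the mean of the seven predictors (binaries as
prevalences) and the annual incidence of each outcome. The model-implied
10-year cumulative hazard at each group's mean profile,
`Hhat_g = exp(LP_g)·(−ln S0(10))`, is compared with the observed
`H_g = 10·λ_g`, and the population-share-weighted ratio

    c = Σ_g w_g H_g / Σ_g w_g Hhat_g

rescales the baseline on the cumulative-hazard scale: `S0_new = S0^c`. This
is the standard flexible recalibration mechanism used for risk charts built
from summary data; since the original description's worked details are not
public, the operative contract here is self-consistency — an incidence
table generated from the model itself yields `c = 1` to floating-point
accuracy, and doubling every incidence yields exactly `c = 2`. The rate
form `H = 10·λ` is the default; an annual-risk form `H = −10·ln(1−q)` sits
behind the `incidence_kind` switch. Evaluating `LP_g` at group means rather
than averaging `exp(LP)` over individuals introduces a Jensen gap; this is
inherent to the summary-data setting and is one reason practical
recalibration trails ideal recalibration.

**Ideal** recalibration assumes the region's observed 10-year risk is
available — here the Kaplan–Meier estimate at 10 years with competing first
events censored, matching the derivation convention — and solves

    mean_i [ 1 − s0 ^ exp(LP_i) ] = observed risk

for `s0` by Brent's method on (0, 1); the solution is verified to close the
mean-risk gap to 1e-10. An observed risk of zero returns `s0 = 1` with a
warning.

## Evaluation statistics

* **Harrell C**: a pair is usable when one subject's event strictly
  precedes the other's time, or coincides with the other's censoring time;
  two events at the same time are not comparable; ties in predicted risk
  score 1/2. The standard error is the leave-one-subject-out jackknife of
  the ratio of pair sums — an asymptotic SE that requires no extra
  distributional choices — and the 95% CI is normal-theory. The
  implementation enumerates pairs blockwise (O(events × n)), adequate for
  the cohort sizes used here.
* **Nam–D'Agostino**: subjects are grouped by deciles of predicted risk
  (boundary ties to the lower group); per group the Kaplan–Meier observed
  10-year risk is compared with the mean prediction via
  `χ² = Σ n_g (KM_g − p̄_g)² / (p̄_g(1 − p̄_g))` on `groups − 1` degrees of
  freedom. Several variance forms of this test exist in the literature; this
  form is pinned and oracle-tested rather than claimed identical to any
  particular publication's variant.
* **IDI / relative IDI**: cases are subjects with an event by the horizon,
  controls those still in view at the horizon; subjects censored earlier are
  excluded. IDI is the change in discrimination slope (mean risk in cases
  minus mean risk in controls), and relative IDI expresses it as a
  percentage of the base model's slope.
* **Calibration table**: the decile table of mean predicted versus
  Kaplan–Meier observed risk with Greenwood CIs, plot-ready; subgroup
  evaluation (age bands, hypertension, diabetes) is plain filtering of the
  inputs.

Kaplan–Meier and Aalen–Johansen estimation is delegated to lifelines.

## The synthetic cohort generator

The generator exists so that derivation, recalibration and evaluation are
exercisable without access to the restricted source cohort. Its defaults
*are* the study conditions: age uniform over 30–79; SBP/DBP bivariate
normal around the published medians (126/76 mm Hg women, 129.5/78.5 men)
with declared SDs 20/11 mm Hg and correlation 0.7; waist normal around the
published medians (78.2 / 81.3 cm) with SDs from the printed interquartile
ranges (IQR/1.349 ≈ 9.6 / 10.4 cm); daily smoking 2.0% / 57.1%, treatment
11.8% / 10.2%, diabetes 2.9% / 2.5% (women / men); 59% women. Physically
impossible blood-pressure pairs (SBP < DBP or out of admissible range) are
redrawn.

Event times are exponential given covariates: each subject carries
cause-specific hazards `λ0_k · m_{k,region} · exp(LP_k)` with
`λ0_k = −ln(S0_k(10))/10`, so that with multiplier 1 the simulated
population reproduces the packaged baseline survival exactly, and
`S(10|x) = S0^exp(LP)` holds by construction — a correctly specified world
in which the model is exactly true. Regional multipliers default to a
geometric grid over [0.5, 2] rotated one position per outcome, emulating
the strong regional variation in absolute risk that motivates
recalibration. Unspecified stroke is a competing cause at 1.3% of the
combined stroke hazard (the published cohort's share of first strokes is
1.2–1.4%); non-CVD death is a constant 0.004/year; administrative censoring
is uniform on 10–13 years (the published follow-up IQR is ~10.3–12.2) and
random loss to follow-up is 0.8%. Constant hazards keep every cumulative
incidence in closed form for testing; a Weibull shape parameter is exposed
for robustness checks but defaults to 1.

What the generator deliberately does **not** emulate: correlations between
binary risk factors and continuous ones (e.g. treatment given
hypertension), region-specific covariate distributions, secular trends, or
any misspecification of the linear predictor. Passing tests therefore
demonstrate internal consistency — the machinery recovers what generated
the data — not transportability to real populations, where proportional
hazards and linearity are approximations.

## Problem sizes and numerical choices

Parameter-recovery runs use 200,000 subjects per sex across 10 regions,
which yields roughly 5,000–28,000 events per submodel and standard errors
small enough (~0.01–0.03 on the log scale) that the printed hazard ratios
are a 3-SE-sharp target. Test-suite simulations use 3–5 regions of
1,000–4,000 subjects, enough for the qualitative recalibration ordering
(original ≤ practical ≤ ideal in pooled C) to emerge above its ~0.003
simulation noise. The ideal-recalibration root finder uses Brent with xtol
1e-16 and verifies the mean-risk gap at 1e-10; the Newton–Raphson fitter
halves steps up to 30 times per iteration before declaring failure;
information-matrix singularity and coefficient divergence raise explicit
fitting errors rather than returning garbage.

## Known limitations

* Packaged coefficients carry the 2-decimal rounding of the published
  hazard ratios; predictions can differ in the third decimal from those of
  the exact (unreleased) coefficients.
* The combined-risk independence assumption is diagnosed, not modeled; no
  Fine–Gray or multistate alternative is provided.
* The Nam–D'Agostino variant and the C-pooling method are declared choices
  among several published options.
* `harrell_c` is O(events × n) and intended for cohorts up to a few hundred
  thousand subjects, not millions.
* No delayed entry, time-varying covariates, age-as-timescale variant, or
  missing-data handling (the derivation population had complete predictor
  data).
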