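# ckbcvd

Sex-specific 10-year cardiovascular risk models for Chinese adults aged
30–79, with regional recalibration. The package is aimed at biostatisticians
and epidemiologists who want to apply, re-derive, recalibrate or stress-test
the CKB-CVD model family — three cause-specific Cox submodels per sex
(ischemic heart disease, IHD; ischemic stroke, IS; hemorrhagic stroke, HS)
whose predictions combine into a total CVD risk.

## The model

Each submodel turns a centered linear predictor into an absolute risk via a
10-year baseline survival anchor, and the three cause-specific risks combine
under conditional probability:

    risk_k(x)  = 1 − S0_k(10) ^ exp(LP_k(x)),         k ∈ {IHD, IS, HS}
    risk_CVD   = 1 − (1 − risk_IHD)(1 − risk_IS)(1 − risk_HS)

    LP_k(x) = Σ_p β_p u_p + Σ_{p≠age} γ_p u_age u_p

with seven predictors available in China's resident health records — age,
systolic and diastolic blood pressure, blood-pressure-lowering treatment,
current daily smoking, self-reported diabetes, waist circumference — in
model units (age per 5 y centered at 55; SBP/DBP per 10 mm Hg centered at
120/80; waist per 10 cm centered at 80; binaries 0/1). No blood lipids are
needed. The published coefficient sets for both sexes ship with the package
as versioned JSON.

Beyond prediction, the package provides:

* **derivation** — region-stratified Cox fitting (Newton–Raphson, Efron
  ties), Breslow baseline survival at the centered origin, case-weighted
  pooling of regional S0(10), and leave-one-region-out (internal–external)
  cross-validation;
* **recalibration** — adapting a model to a region by replacing baseline
  survivals only: *practical* (from age-group mean risk-factor levels and
  annual incidences, `S0_new = S0^c`) or *ideal* (solving for the baseline
  survival that matches the observed 10-year Kaplan–Meier risk);
* **evaluation** — Harrell C with jackknife CI, the Nam–D'Agostino
  calibration chi-square across risk deciles, decile calibration tables and
  plots, and (relative) integrated discrimination improvement;
* **synthetic cohorts** — multi-region cohorts with the derivation
  population's covariate structure and cause-specific exponential hazards
  driven by the packaged coefficients, so everything above is testable
  without restricted data.

## Worked example

```python
from ckbcvd import RiskProfile, load_family, predict_total_cvd

family = load_family("female")
profile = RiskProfile(sex="female", age=62.5, sbp=150, dbp=95,
                      bp_treatment=True, daily_smoker=False,
                      diabetes=True, waist=92)
result = predict_total_cvd(profile, family)
print(f"IHD {result.risk_ihd:.3f}  IS {result.risk_is:.3f}  "
      f"HS {result.risk_hs:.3f}  total CVD {result.risk_cvd:.3f}")
```

prints

```
IHD 0.368  IS 0.422  HS 0.092  total CVD 0.668
```

i.e. this 62-year-old woman with treated hypertension and diabetes has a
36.8% 10-year IHD risk, 42.2% IS risk and 9.2% HS risk; the chance of at
least one of the three events is 66.8% (= 1 − 0.632·0.578·0.908). At the
reference profile (age 55, SBP 120, DBP 80, waist 80, no binary risk
factors) each submodel returns exactly 1 − S0(10): 0.100, 0.090 and 0.014
for women's IHD, IS and HS.

The same operations are available from the shell:

```bash
ckbcvd simulate   --config sim.yaml --out cohort.csv --recal-table table.csv
ckbcvd fit        --cohort cohort.csv --outcome HS --sex male --out fit.json
ckbcvd predict    --profiles profiles.csv --model model.json --out risks.csv
ckbcvd recalibrate --model model.json --mode practical --region 3 \
                   --table table.csv --out model_r3.json
ckbcvd evaluate   --cohort cohort.csv --model model_r3.json --out report.json
ckbcvd pipeline   --config sim.yaml --out run/   # simulate→fit→recalibrate→evaluate
```

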