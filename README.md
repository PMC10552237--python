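# kfrisk

External validation, updating, and competing-risks extension of
kidney-failure risk equations on primary-care chronic kidney disease (CKD)
cohorts — with a calibrated synthetic cohort generator so every stage is
testable without access to patient data.

`kfrisk` is aimed at biostatisticians and nephrology researchers who need to

* evaluate a 4-variable KFRE-style risk equation (age, sex, eGFR, urine
  albumin-to-creatinine ratio) for the 5-year risk of kidney replacement
  therapy (KRT),
* externally validate it (discrimination, calibration, Brier score) in a
  cohort with two ethnic strata (white, South Asian),
* update it along the standard ladder — baseline recalibration, linear
  predictor rescaling, added predictors, full re-estimation with
  interaction selection and shrinkage, and a Fine–Gray competing-risks
  refit — and
* quantify clinical impact through referral tables and decision-curve net
  benefit.

## The model

All risk equations handled here share the proportional-hazards form

```
risk(5y) = 1 − S₀(5)^exp(LP),     LP = m · Σⱼ βⱼ (xⱼ/sⱼ − cⱼ)
```

where `S₀(5)` is the baseline 5-year survival (for a Fine–Gray model, the
complement of the baseline cumulative incidence), the covariates are scaled
by `sⱼ` and centred at `cⱼ`, ACR is log-transformed, and `m` is a uniform
recalibration/shrinkage multiplier.  The packaged default configuration is
the published non-North-American 4-variable 5-year KFRE (coefficients
−0.2201 age/10, +0.2467 male, −0.5567 eGFR/5, +0.4510 ln ACR; S₀(5) =
0.9240; ACR converted from mg/mmol to mg/g before the log).

Observed risk is available in two conventions throughout: the Kaplan–Meier
complement with deaths censored (`view="km"`), and the Aalen–Johansen
cumulative incidence with death as a competing event (`view="aj"`); the KM
view never falls below the AJ view, which is the overestimation that
motivates competing-risks modelling.  Calibration intercept and slope are
estimated by regressing jackknife pseudo-observations on the cloglog of
predicted risk; Harrell's C is truncated at the horizon; the Brier score is
inverse-probability-of-censoring weighted.

## Worked example

```python
import kfrisk
from kfrisk.synthetic import default_cohort_spec

spec = default_cohort_spec()                 # the two-stratum study conditions
spec.n_white, spec.n_south_asian = 9000, 1000  # scaled-down cohort
cohort = kfrisk.generate_cohort(spec, seed=11)
model = kfrisk.default_kfre_model()

report = kfrisk.validate(model, cohort, horizon=5.0, view="km",
                         n_bootstrap=200, seed=11)
for name, vals in report.metrics.items():
    print(f"{name:>22}: {vals['estimate']:6.3f} "
          f"({vals['ci_lower']:.3f}, {vals['ci_upper']:.3f})")
```

prints

```
               c_index:  0.851 (0.809, 0.885)
              oe_ratio:  0.758 (0.637, 0.894)
 calibration_intercept: -1.711 (-2.347, -1.060)
     calibration_slope:  0.481 (0.422, 0.557)
                 brier:  0.015 (0.012, 0.017)
          scaled_brier:  0.100 (0.073, 0.128)
```

Discrimination is high (C = 0.85) but the equation is miscalibrated on this
cohort: it over-predicts on average (observed/expected = 0.76) and the
predictions are too extreme (slope 0.48), largely because the synthetic
cohort's heavy competing mortality removes high-risk patients before KRT —
exactly the situation the updating ladder addresses.  Recalibrating the
baseline restores calibration-in-the-large:

```python
updated = kfrisk.update_baseline(model, cohort).model
print(updated.intercept_shift)     # -0.311
p = kfrisk.predict_risk_5y(updated, cohort)
kfrisk.oe_ratio(p, cohort["follow_up_time"], cohort["event"])   # 1.0
```

and a Fine–Gray refit with ethnicity gives subdistribution-hazard
coefficients directly:

```python
fg = kfrisk.fit_fine_gray(cohort)
# {'age': -0.175, 'sex': 0.117, 'egfr': -0.297, 'acr': 0.333, 'ethnicity': 1.017}
```

The same stages are available from the shell:

```bash
kfrisk simulate --seed 3 --out cohort.csv
kfrisk validate --cohort cohort.csv --view km --n-boot 1000 --seed 7 --out report.json
kfrisk update   --cohort cohort.csv --method 5 --out model5.yaml
kfrisk impact   --cohort cohort.csv --criterion hybrid --risk-threshold 0.05 --out referrals.csv
kfrisk pipeline --cohort cohort.csv --seed 1 --out bundle.json
```

## Layout

| module | contents |
| --- | --- |
| `kfrisk.core` | risk-equation evaluation, risk groups, model YAML I/O |
| `kfrisk.cohort` | cohort file I/O with exclusion accounting |
| `kfrisk.synthetic` | calibrated two-stratum cohort generator |
| `kfrisk.estimators` | KM, Aalen–Johansen, Breslow, IPCW, pseudo-observations |
| `kfrisk.phreg` | Cox / Fine–Gray partial-likelihood Newton–Raphson engine |
| `kfrisk.updating` | updating methods 1–6, bootstrap internal validation |
| `kfrisk.metrics` | C-index, O/E, calibration regression, Brier, bootstrap CIs |
| `kfrisk.impact` | referral criteria, referral tables, decision curves |
| `kfrisk.pipeline` / `kfrisk.cli` | orchestration and command line |

See `docs/methods.md` for the statistical conventions, generator design and
known limitations.
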