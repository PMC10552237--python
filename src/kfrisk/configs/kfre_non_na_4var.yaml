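# Non-North-American 4-variable kidney failure risk equation, 5-year horizon.
# Coefficients, centring constants and baseline survival transcribed from the
# published multinational KFRE calibration (Tangri et al., JAMA 2016;
# doi:10.1001/jama.2015.18202), the form recommended for UK use.
# The published equation expects ACR in mg/g; cohort files carry mg/mmol, so
# acr_unit_factor converts (1 mg/mmol = 8.84 mg/g) before the natural log.
family: cox_cause_specific
coefficients:
  age: -0.2201
  sex: 0.2467
  egfr: -0.5567
  acr: 0.4510
centring:
  age: [10.0, 7.036]      # age in decades, centred at 70.36 years
  sex: [1.0, 0.5642]      # male = 1
  egfr: [5.0, 7.222]      # eGFR per 5 ml/min/1.73m2, centred at 36.11
  acr: [1.0, 5.137]       # ln(ACR mg/g), centred at ln-ACR 5.137
acr_log_transform: true
acr_unit_factor: 8.84
baseline_survival_5y: 0.9240
lp_multiplier: 1.0
intercept_shift: 0.0
meta:
  name: kfre_non_na_4var_5y
  provenance: >-
    Tangri et al. 2016 multinational meta-analysis, non-North-American
    calibration of the 4-variable KFRE (age, sex, eGFR, ACR), 5-year horizon.
  acr_input_unit: mg/mmol
  acr_model_unit: mg/g
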