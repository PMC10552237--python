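# Referral-criteria evaluation counts reported for the UK (Leicester)
# primary-care CKD cohort's eligibility assessment cohort (patients not
# previously known to secondary care); cohort deposited at Figshare
# DOI 10.25392/leicester.data.9860807.v1.  Criteria: previous NICE rule
# (eGFR < 30 ml/min/1.73m2 and/or ACR >= 70 mg/mmol) versus predicted
# 5-year KRT risk >= 5% or ACR >= 70 mg/mmol under each updated model.
# Fields per row: correct referrals, unnecessary referrals, missed KRT
# cases, total referrals.
white:
  n: 11596
  nice_previous: {correct: 26, unnecessary: 609, missed: 32, total: 635}
  model_2: {correct: 29, unnecessary: 510, missed: 29, total: 539}
  model_3: {correct: 29, unnecessary: 498, missed: 29, total: 527}
  model_4: {correct: 29, unnecessary: 509, missed: 29, total: 538}
  model_5: {correct: 29, unnecessary: 351, missed: 29, total: 380}
  model_6: {correct: 30, unnecessary: 341, missed: 28, total: 371}
south_asian:
  n: 2124
  nice_previous: {correct: 19, unnecessary: 127, missed: 5, total: 146}
  model_2: {correct: 23, unnecessary: 188, missed: 1, total: 211}
  model_3: {correct: 23, unnecessary: 202, missed: 1, total: 225}
  model_4: {correct: 23, unnecessary: 186, missed: 1, total: 209}
  model_5: {correct: 23, unnecessary: 155, missed: 1, total: 178}
  model_6: {correct: 23, unnecessary: 168, missed: 1, total: 191}
overall:
  n: 13720
  nice_previous: {correct: 45, unnecessary: 736, missed: 37, total: 781}
  model_2: {correct: 52, unnecessary: 698, missed: 30, total: 750}
  model_3: {correct: 52, unnecessary: 700, missed: 30, total: 752}
  model_4: {correct: 52, unnecessary: 695, missed: 30, total: 747}
  model_5: {correct: 52, unnecessary: 506, missed: 30, total: 558}
  model_6: {correct: 53, unnecessary: 509, missed: 29, total: 562}
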