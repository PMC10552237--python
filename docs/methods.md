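# Methods

This note records the statistical conventions, the synthetic-cohort design,
and the numerical choices behind `kfrisk`, in the spirit of a model
documentation page: what is computed, under which assumptions, and what the
package's tests do and do not demonstrate about real data.

## Risk equations

Every model is a proportional-hazards risk equation

    risk(5y) = 1 − S₀(5)^exp(LP + δ),      LP = m · Σⱼ βⱼ (xⱼ/sⱼ − cⱼ),

with scaling/centring constants `(sⱼ, cⱼ)` carried in the model
configuration, a natural-log ACR transform, a uniform multiplier `m`
(recalibration or shrinkage) and an additive baseline shift `δ` on the
log-cumulative-hazard scale.  For a Fine–Gray model the identical algebra
applies on the subdistribution scale, with `S₀(5)` the complement of the
baseline cumulative incidence.

The packaged default is the published non-North-American 4-variable 5-year
KFRE.  Its coefficients expect ACR in mg/g while UK cohort files carry
mg/mmol, so the configuration sets `acr_unit_factor: 8.84` (1 mg/mmol =
8.84 mg/g) applied before the log; the conversion is a property of the model
file, not hard-coded behaviour.  Sex is coded male = 1, ethnicity
South Asian = 1.  Risk groups split at <3%, 3–<5%, 5–<15%, 15–<25%, 25–<50%
and ≥50%, left-closed.

## Observed risk: two conventions

Validation metrics exist in a "KM view" and an "AJ view":

* **KM view** — deaths are censored at the death time and observed risk is
  the Kaplan–Meier complement.  This is the convention under which KFRE-type
  equations were developed, and it overstates absolute risk when competing
  mortality is heavy.
* **AJ view** — death is a competing event and observed risk is the
  Aalen–Johansen cumulative incidence.  At every time point
  CIF_krt + CIF_death + S_overall = 1, and CIF_krt ≤ 1 − KM.

Tied event and censoring times follow the standard convention that events
precede censorings, so subjects censored at t remain in the risk set at t.
The censoring survivor function Ĝ (overall KM of censoring) is evaluated
with left limits at event times to avoid self-weighting.

## Validation metrics

* **Harrell's C** with follow-up administratively truncated at the horizon;
  in the competing-risks view deaths censor at the death time
  (cause-specific concordance).  Prediction ties count ½.
* **O/E ratio**: observed horizon risk (KM or AJ) over mean predicted risk.
* **Calibration intercept and slope**: jackknife pseudo-observations of the
  horizon cumulative incidence are regressed on cloglog(predicted risk)
  with a cloglog-inverse mean function and identity working covariance
  (equivalently nonlinear least squares; a logit link is available).  The
  slope comes from the two-parameter fit; the intercept from a second fit
  with the slope fixed at 1 (calibration-in-the-large convention).  The
  convention is echoed in every report because the regression machinery
  behind published intercept/slope pairs is rarely stated.
* **Brier / scaled Brier**: IPCW-weighted squared error at the horizon; in
  the AJ view deaths before the horizon are known non-events with weight
  1/Ĝ(T⁻), in the KM view they are censored.  The null model for scaling
  predicts the overall observed risk for everyone (a stratum-specific null
  is switchable).
* **Confidence intervals**: percentile bootstrap, resampling patients with
  replacement stratified by ethnicity (default 1000 resamples; 500 for
  internal validation), all seeded.  Reported intervals are widened, when
  necessary, to contain the point estimate.

Pseudo-observations are computed by an exact O(n log n) leave-one-out
algorithm using prefix products/sums over the risk table, for both the KM
complement and the Aalen–Johansen estimator; the test suite validates it
against direct O(n²) leave-one-out recomputation.  With no censoring the KM
pseudo-values reduce exactly to 0/1 event indicators.

## The updating ladder

1. no change;
2. baseline re-estimation: δ solved (Brent) so mean predicted = observed →
   in-sample O/E = 1 exactly; applied per ethnic stratum for models 2a/2b;
3. method 2 plus LP rescaling by the slope of a one-covariate Cox fit with
   the current LP as sole covariate;
4. method 2 plus one new predictor (ethnicity) estimated by a Cox fit with
   the original LP as a fixed offset — original coefficients untouched;
5. full Cox re-estimation (age, sex, eGFR, log ACR, ethnicity) on the
   configured scaled/centred basis, with ethnicity-interaction candidates
   (ethnicity × each of age, sex, eGFR, log ACR — no other predictors are
   considered) screened one at a time by likelihood-ratio test at α = 0.05
   and the winners jointly refitted; bootstrap internal validation (Harrell
   optimism: fit on the resample, score on resample and original; optimism
   = mean difference; adjusted = apparent − optimism); the
   optimism-adjusted calibration slope applied as a uniform shrinkage
   factor, after which the baseline must be re-estimated — enforced by a
   staleness flag that blocks prediction until it is;
6. a Fine–Gray refit with the same predictors (model 5's interaction set is
   inherited by default; re-selection is a switch), internally validated the
   same way.

Scaling/centring constants are taken from the model configuration, not
re-derived per dataset, so re-estimated coefficients remain comparable with
the original equation's.

### Partial-likelihood engine

Cox fits use an in-package Newton–Raphson maximiser (Efron ties by default,
Breslow available; offsets supported) with step-halving, convergence at
max |score| < 1e-7 and a 50-iteration cap; separation is flagged via a
diverging-coefficient guard.  The Breslow estimator supplies the baseline
cumulative hazard regardless of the tie correction used for β.  The
Fine–Gray maximiser keeps subjects who failed from the competing cause in
subdistribution risk sets with time-decaying weights Ĝ(t⁻)/Ĝ(T⁻), with Ĝ
the overall censoring KM (not covariate-adjusted, matching the original
estimator); the computation is organised as suffix sums over
still-observed subjects plus Ĝ-scaled prefix sums over competing failures,
so each iteration is O(n·p²).  With no competing events and no censoring
the two engines agree to numerical precision, and the test suite pins the
Fine–Gray optimum against an independent reference implementation and a
brute-force grid search on a tiny fixture.  An external Cox implementation
(lifelines) serves as a cross-check oracle, never as the fitting path.

## Synthetic cohort generator

The generator emulates a two-stratum UK primary-care CKD cohort:

* **Stratum sizes** default to 27,017 white and 2,728 South Asian.
* **Covariates** per stratum: age normal (76.6 ± 10.3 / 70.2 ± 11.6 years);
  eGFR normal truncated to (0, 60) ml/min/1.73m² with the *observed*
  moments matching 48.0 ± 9.88 / 48.1 ± 10.6 (the underlying parameters are
  solved numerically); ACR log-normal matching the printed median exactly
  (3.10 / 4.90 mg/mmol) with σ minimising squared error to the printed
  quartiles; sex and comorbidities Bernoulli at the printed prevalences.
* **Outcomes**: latent cause-specific event times for KRT and death,
  exponential by default (Weibull shapes available), with proportional
  hazards on the same scaled/centred basis as the risk equation.  The true
  coefficient vector defaults to the published KFRE coefficients and drives
  both causes (a cause-specific vector is a config switch).  The South
  Asian stratum's coefficients are offset by interaction terms
  (ethnicity × log ACR +0.45, ethnicity × eGFR −0.45 on the scaled basis) —
  magnitudes chosen a priori as effects detectable by a stratum of ~2,700
  patients with ~100 events, mirroring the qualitative finding that
  ethnicity modifies the ACR and eGFR effects.  Stratum-specific baseline
  hazards play the role of an ethnicity main effect.
* **Calibration**: baseline hazards and the dropout rate were calibrated
  once, by large-n simulation, so the defaults reproduce the printed
  marginal event rates (KRT 2.95 / 9.20 and death 59.6 / 31.0 per 1000
  person-years by stratum) and the white stratum's mean follow-up
  (≈4.7 years); the frozen values live in `synthetic.py`.
* **Censoring**: staggered entry uniform over 0–7 years against a 12-year
  administrative horizon (so administrative censoring between 5 and 12
  years) plus exponential dropout at 0.0797/year.  Eligibility (not
  previously known to secondary care) is Bernoulli(0.461), a loose
  approximation to the published eligibility fraction.

What the generator does **not** emulate: GP-practice clustering, repeated
eGFR measurements and the 90-day confirmation window (represented only by
the eGFR < 60 inclusion rule), covariate-dependent censoring mechanisms,
and a realistic age–mortality gradient — because the same coefficient
vector drives both causes by default, death risk *decreases* with age like
KRT risk does, which makes competing-risk distortion of the KM view
stronger than in the real cohort (visible as calibration slopes well below
1 when the original equation is validated on the full default cohort).
Passing tests therefore demonstrate internal consistency of the estimators
and the updating machinery under known truth, not real-world performance
of any particular equation.

## Numerical choices and degenerate inputs

* Newton–Raphson tolerance 1e-7 on the score, 50 iterations, 30
  step-halvings; constant predictors and event-free data are rejected with
  explicit errors.
* Brent root-finding for baseline shifts over δ ∈ [−30, 30].
* Ĝ = 0 at a required time raises, naming the time.
* Empty cohorts, all-censored KM (survival ≡ 1), and empty fixed risk
  groups (reported with null observed risk) are handled explicitly.
* Pseudo-observation regression clips the linear predictor at ±30 on the
  link scale; predictions are clipped away from {0, 1} by 1e-12 before the
  cloglog.
* All randomness flows from explicit seeds; the pipeline splits one root
  seed per stage via `numpy` SeedSequence.

## Problem sizes used in the tests

Unit tests run at n ≤ 3,000 with brute-force oracles at n ≤ 40.  The
acceptance suite uses the study-scale conditions where the property demands
them: coefficient recovery and interaction selection at n ≈ 30,000 (50
seeds), calibration self-consistency at n = 50,000, and bootstrap optimism
at n = 20,000 with 500 resamples — sizes at which the Monte-Carlo error of
each quantity is comfortably below the asserted band.

## Known limitations

* The Fine–Gray engine uses Breslow tie handling (as the original
  estimator); heavy ties in subdistribution risk sets are therefore
  slightly biased relative to an Efron-style correction.
* Bootstrap percentile intervals are reported without bias correction
  (BCa); for strongly skewed metrics at small n they can under-cover.
* The calibration intercept is estimated with the slope fixed at 1; when
  predictions are grossly over-dispersed the intercept mixes scale and
  spread miscalibration, and its bootstrap distribution is noticeably
  nonlinear.
* Decision-curve true/false positives use observed event probabilities
  within the referred group (KM or AJ), which reduces to raw counts only
  under complete follow-up.  Referral tables use the raw-indicator
  convention (patients censored before the horizon count as non-cases),
  matching how published referral counts are tabulated; the two conventions
  coincide in fully observed data.
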