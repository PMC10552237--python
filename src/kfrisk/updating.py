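"""Model updating ladder for an externally validated risk equation.

The six methods, in increasing order of revision:

1. no change (the original equation);
2. re-estimate the baseline risk so mean predicted = observed (O/E = 1);
3. method 2 plus rescaling of the linear predictor by the calibration slope
   from a one-covariate Cox fit;
4. method 2 plus an ethnicity predictor estimated with the original linear
   predictor held fixed as an offset;
5. full Cox re-estimation with ethnicity and likelihood-ratio-selected
   ethnicity interactions, bootstrap-internally validated, with the
   optimism-adjusted calibration slope applied as a uniform shrinkage factor;
6. a Fine-Gray subdistribution-hazard refit with the same predictors,
   accounting for the competing risk of death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    COX_CAUSE_SPECIFIC,
    FINE_GRAY,
    SurvivalModel,
    design_matrix,
    linear_predictor,
    predict_risk_5y,
)
from .estimators import EVENT_CODES, aalen_johansen, kaplan_meier
from .phreg import cox_newton_raphson, fine_gray_newton_raphson

__all__ = [
    "UpdateResult",
    "OptimismReport",
    "fit_cox",
    "update_baseline",
    "recalibrate_slope",
    "add_predictor",
    "select_interactions",
    "fit_fine_gray",
    "apply_shrinkage",
    "internal_validate",
    "observed_risk",
]

DEFAULT_PREDICTORS = ("age", "sex", "egfr", "acr", "ethnicity")
DEFAULT_CANDIDATES = (
    "ethnicity:age",
    "ethnicity:sex",
    "ethnicity:egfr",
    "ethnicity:acr",
)


@dataclass
class UpdateResult:
    model: SurvivalModel
    method: int
    selected_interactions: list = field(default_factory=list)
    lrt_records: list = field(default_factory=list)
    shrinkage_factor: float | None = None

    def as_dict(self) -> dict:
        from .core import _model_to_dict

        return {
            "method": self.method,
            "model": _model_to_dict(self.model),
            "selected_interactions": list(self.selected_interactions),
            "lrt_records": [dict(r) for r in self.lrt_records],
            "shrinkage_factor": self.shrinkage_factor,
        }


@dataclass
class OptimismReport:
    """Harrell bootstrap optimism: adjusted = apparent - mean(boot - test)."""

    metrics: dict  # name -> {"apparent", "optimism", "optimism_adjusted"}
    n_bootstrap: int
    n_failed: int = 0

    def as_dict(self) -> dict:
        return {
            "metrics": {k: dict(v) for k, v in self.metrics.items()},
            "n_bootstrap": self.n_bootstrap,
            "n_failed": self.n_failed,
        }


def event_codes(cohort: pd.DataFrame) -> np.ndarray:
    return cohort["event"].map(EVENT_CODES).to_numpy(dtype=int)


def observed_risk(cohort: pd.DataFrame, horizon: float, view: str = "km") -> float:
    """Observed cumulative incidence of KRT at the horizon.

    ``view="km"``: complement of the Kaplan-Meier with deaths censored (the
    convention under which the original equation was built); ``view="aj"``:
    Aalen-Johansen cumulative incidence treating death as a competing event.
    """
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    codes = event_codes(cohort)
    if view == "km":
        km = kaplan_meier(times, (codes == 1).astype(int))
        return 1.0 - float(km(horizon))
    if view == "aj":
        return float(aalen_johansen(times, codes)["krt"](horizon))
    raise ValueError(f"unknown observed-risk view {view!r}")


def _template(model_or_centring, family=COX_CAUSE_SPECIFIC) -> SurvivalModel:
    if isinstance(model_or_centring, SurvivalModel):
        return model_or_centring
    from .core import default_kfre_model

    base = default_kfre_model()
    if model_or_centring:
        base.centring.update(model_or_centring)
    return base


def _ensure_centring(model: SurvivalModel, names) -> None:
    for name in names:
        for part in name.split(":"):
            model.centring.setdefault(part, (1.0, 0.0))


def fit_cox(
    cohort: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    interactions=(),
    template: SurvivalModel | None = None,
    horizon: float = 5.0,
    ties: str = "efron",
) -> SurvivalModel:
    """Cause-specific Cox fit (deaths censored) on the scaled/centred basis.

    Scaling/centring constants come from the template model (the packaged
    risk-equation conventions by default) rather than from the data, so
    re-estimated coefficients stay comparable with the original equation.
    Returns a model with a Breslow-derived baseline 5-year survival.
    """
    tmpl = _template(template)
    names = list(predictors) + list(interactions)
    probe = tmpl.copy()
    _ensure_centring(probe, names)
    probe.coefficients = {n: 0.0 for n in names}
    probe.lp_multiplier = 1.0
    X = design_matrix(probe, cohort).to_numpy()
    codes = event_codes(cohort)
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    fit = cox_newton_raphson(X, times, (codes == 1).astype(int), ties=ties)
    out = probe.copy(
        family=COX_CAUSE_SPECIFIC,
        coefficients=dict(zip(names, fit.beta)),
        baseline_survival_5y=fit.baseline_survival(horizon),
        lp_multiplier=1.0,
        intercept_shift=0.0,
        baseline_stale=False,
    )
    out.meta = {
        "fitted": "cox_cause_specific",
        "loglik": float(fit.loglik),
        "n_iter": fit.n_iter,
        "se": {n: float(s) for n, s in zip(names, fit.se)},
    }
    return out


def update_baseline(
    model: SurvivalModel,
    cohort: pd.DataFrame,
    horizon: float = 5.0,
    view: str = "km",
) -> UpdateResult:
    """Method 2: recalibrate the baseline so in-sample O/E = 1.

    Coefficients are untouched; the intercept shift (on the
    log-cumulative-hazard scale, equivalent to a new S0(5)) is solved so the
    mean predicted risk equals the observed risk at the horizon.
    """
    obs = observed_risk(cohort, horizon, view=view)
    if not 0.0 < obs < 1.0:
        raise ValueError(f"observed risk is {obs}; baseline update undefined")
    lp = linear_predictor(model, cohort)
    s0 = model.baseline_survival_5y

    def mean_risk(shift: float) -> float:
        return float(np.mean(1.0 - s0 ** np.exp(lp + shift)))

    sol = optimize.brentq(lambda s: mean_risk(s) - obs, -30.0, 30.0, xtol=1e-12)
    new = model.copy(intercept_shift=float(sol), baseline_stale=False)
    return UpdateResult(model=new, method=2)


def recalibrate_slope(
    model: SurvivalModel,
    cohort: pd.DataFrame,
    horizon: float = 5.0,
    view: str = "km",
) -> UpdateResult:
    """Method 3: rescale the linear predictor, then recalibrate the baseline.

    The multiplier is the coefficient of a one-covariate Cox fit with the
    current linear predictor as sole covariate (the Cox calibration slope).
    """
    lp = linear_predictor(model, cohort)
    if np.ptp(lp) == 0:
        raise ValueError("constant linear predictor; slope unidentifiable")
    codes = event_codes(cohort)
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    fit = cox_newton_raphson(lp[:, None], times, (codes == 1).astype(int))
    slope = float(fit.beta[0])
    rescaled = model.copy(
        lp_multiplier=model.lp_multiplier * slope, baseline_stale=True
    )
    out = update_baseline(rescaled, cohort, horizon=horizon, view=view)
    out.method = 3
    out.shrinkage_factor = None
    out.model.meta = {**model.meta, "lp_slope": slope}
    return out


def add_predictor(
    model: SurvivalModel,
    cohort: pd.DataFrame,
    new_predictor: str = "ethnicity",
    horizon: float = 5.0,
    view: str = "km",
) -> UpdateResult:
    """Method 4: estimate one new predictor with the original LP as offset,
    then recalibrate the baseline.  Original coefficients are untouched."""
    offset = linear_predictor(model, cohort)
    probe = model.copy()
    _ensure_centring(probe, [new_predictor])
    probe.coefficients = {new_predictor: 0.0}
    x = design_matrix(probe, cohort).to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"new predictor {new_predictor!r} is constant")
    codes = event_codes(cohort)
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    fit = cox_newton_raphson(x, times, (codes == 1).astype(int), offset=offset)
    gamma = float(fit.beta[0])
    new = model.copy()
    _ensure_centring(new, [new_predictor])
    # stored on the pre-multiplier scale so the effective effect is gamma
    new.coefficients[new_predictor] = gamma / model.lp_multiplier
    new.meta = {**model.meta, "added_predictor": new_predictor, "added_coef": gamma}
    out = update_baseline(new, cohort, horizon=horizon, view=view)
    out.method = 4
    return out


def _refit(cohort, predictors, interactions, template, horizon, family):
    if family == FINE_GRAY:
        return fit_fine_gray(
            cohort, predictors, interactions, template=template, horizon=horizon
        )
    return fit_cox(
        cohort, predictors, interactions, template=template, horizon=horizon
    )


def select_interactions(
    cohort: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    candidates=DEFAULT_CANDIDATES,
    alpha: float = 0.05,
    template: SurvivalModel | None = None,
    horizon: float = 5.0,
    family: str = COX_CAUSE_SPECIFIC,
) -> UpdateResult:
    """Method 5 model building: one-at-a-time likelihood-ratio screening of
    ethnicity-interaction candidates, then a joint refit with the winners.

    Each candidate is added alone to the base model; a chi-squared LRT
    (df = 1) compares the nested fits, and candidates with p < alpha enter
    the final model.  Audit records of every test are returned.
    """
    base = _refit(cohort, predictors, (), template, horizon, family)
    base_ll = base.meta["loglik"]
    records = []
    selected = []
    for cand in candidates:
        trial = _refit(cohort, predictors, (cand,), template, horizon, family)
        lr = 2.0 * (trial.meta["loglik"] - base_ll)
        pval = float(stats.chi2.sf(max(lr, 0.0), df=1))
        records.append({"interaction": cand, "statistic": float(lr), "df": 1, "p_value": pval})
        if pval < alpha:
            selected.append(cand)
    final = _refit(cohort, predictors, tuple(selected), template, horizon, family)
    return UpdateResult(
        model=final,
        method=5 if family == COX_CAUSE_SPECIFIC else 6,
        selected_interactions=selected,
        lrt_records=records,
    )


def fit_fine_gray(
    cohort: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    interactions=(),
    template: SurvivalModel | None = None,
    horizon: float = 5.0,
) -> SurvivalModel:
    """Method 6: Fine-Gray subdistribution-hazard fit with the same predictor
    set; deaths remain in risk sets with time-decaying censoring weights.

    The returned baseline is the complement of the baseline cumulative
    incidence at the horizon, so ``predict_risk_5y`` yields subdistribution
    risks directly."""
    tmpl = _template(template)
    names = list(predictors) + list(interactions)
    probe = tmpl.copy()
    _ensure_centring(probe, names)
    probe.coefficients = {n: 0.0 for n in names}
    probe.lp_multiplier = 1.0
    X = design_matrix(probe, cohort).to_numpy()
    codes = event_codes(cohort)
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    fit = fine_gray_newton_raphson(X, times, codes)
    out = probe.copy(
        family=FINE_GRAY,
        coefficients=dict(zip(names, fit.beta)),
        baseline_survival_5y=fit.baseline_survival(horizon),
        lp_multiplier=1.0,
        intercept_shift=0.0,
        baseline_stale=False,
    )
    out.meta = {
        "fitted": "fine_gray",
        "loglik": float(fit.loglik),
        "n_iter": fit.n_iter,
        "se": {n: float(s) for n, s in zip(names, fit.se)},
    }
    return out


def apply_shrinkage(model: SurvivalModel, factor: float) -> SurvivalModel:
    """Uniform shrinkage: multiply the linear predictor by ``factor``.

    Marks the baseline stale; predictions are refused until the baseline has
    been re-estimated with :func:`update_baseline`."""
    if not factor > 0:
        raise ValueError("shrinkage factor must be positive")
    out = model.copy(lp_multiplier=model.lp_multiplier * factor)
    out.baseline_stale = factor != 1.0
    return out


def stratified_bootstrap_index(cohort: pd.DataFrame, rng, stratum_col="ethnicity"):
    """Patient-level resample with replacement, stratified to preserve the
    small South Asian stratum."""
    parts = []
    if stratum_col in cohort:
        for _, grp in cohort.groupby(stratum_col):
            parts.append(rng.choice(grp.index.to_numpy(), size=len(grp), replace=True))
    else:
        parts.append(rng.choice(cohort.index.to_numpy(), size=len(cohort), replace=True))
    return np.concatenate(parts)


def internal_validate(
    fit_fn,
    metric_fn,
    cohort: pd.DataFrame,
    n_bootstrap: int = 500,
    seed=None,
) -> OptimismReport:
    """Harrell bootstrap optimism correction.

    ``fit_fn(data) -> model``; ``metric_fn(model, data) -> {name: value}``.
    For each resample: fit on the resample, evaluate on the resample (boot
    performance) and on the original data (test performance); optimism is the
    mean of (boot - test), and adjusted = apparent - optimism.  Failed
    bootstrap fits are dropped and counted.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    apparent_model = fit_fn(cohort)
    apparent = metric_fn(apparent_model, cohort)
    sums = {k: 0.0 for k in apparent}
    n_ok = 0
    n_failed = 0
    for _ in range(n_bootstrap):
        idx = stratified_bootstrap_index(cohort, rng)
        boot = cohort.loc[idx].reset_index(drop=True)
        try:
            m = fit_fn(boot)
            perf_boot = metric_fn(m, boot)
            perf_test = metric_fn(m, cohort)
        except Exception:
            n_failed += 1
            continue
        for k in sums:
            sums[k] += perf_boot[k] - perf_test[k]
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("every bootstrap fit failed")
    metrics = {}
    for k, app in apparent.items():
        opt = sums[k] / n_ok
        metrics[k] = {
            "apparent": float(app),
            "optimism": float(opt),
            "optimism_adjusted": float(app - opt),
        }
    return OptimismReport(metrics=metrics, n_bootstrap=n_bootstrap, n_failed=n_failed)
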