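"""Discrimination, calibration and overall-fit measures for 5-year risk.

Every measure exists in two observed-risk conventions:

* ``view="km"`` — deaths are censored at the death time and the observed risk
  is the Kaplan-Meier complement (the convention under which the original
  risk equation was developed);
* ``view="aj"`` — death is a competing event and the observed risk is the
  Aalen-Johansen cumulative incidence, which is never larger than the KM
  complement.

Calibration intercept and slope regress jackknife pseudo-observations on the
cloglog of predicted risk with a cloglog-inverse mean function (a generalised
estimating equation with identity working covariance, i.e. nonlinear least
squares); the intercept is estimated with the slope fixed at 1
(calibration-in-the-large convention).  The convention is echoed in every
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy import optimize

from .core import SurvivalModel, predict_risk_5y
from .estimators import (
    EVENT_CODES,
    aalen_johansen,
    censoring_weights,
    kaplan_meier,
    pseudo_observations,
)
from .updating import event_codes, observed_risk, stratified_bootstrap_index

__all__ = [
    "ValidationReport",
    "CalibrationTable",
    "harrell_c",
    "oe_ratio",
    "calibration_intercept_slope",
    "brier_scores",
    "bootstrap_ci",
    "calibration_table",
    "point_metrics",
    "validate",
]

_VIEW_TO_ESTIMATOR = {"km": "km_complement", "aj": "aalen_johansen"}

METRIC_NAMES = (
    "c_index",
    "oe_ratio",
    "calibration_intercept",
    "calibration_slope",
    "brier",
    "scaled_brier",
)


@dataclass
class ValidationReport:
    """Point estimates with bootstrap percentile CIs for the six measures."""

    metrics: dict  # name -> {"estimate", "ci_lower", "ci_upper"}
    horizon: float
    observed_risk_estimator: str
    n_bootstrap: int
    calibration_convention: str = (
        "pseudo-observations regressed on cloglog(predicted risk); "
        "intercept with slope fixed at 1"
    )
    n_dropped_resamples: int = 0

    def __getitem__(self, key):
        return self.metrics[key]

    def as_dict(self) -> dict:
        return {
            "metrics": {k: dict(v) for k, v in self.metrics.items()},
            "horizon": self.horizon,
            "observed_risk_estimator": self.observed_risk_estimator,
            "n_bootstrap": self.n_bootstrap,
            "calibration_convention": self.calibration_convention,
            "n_dropped_resamples": self.n_dropped_resamples,
        }


@dataclass
class CalibrationTable:
    """Mean predicted vs observed risk per group of predicted risk."""

    grouping: str
    table: pd.DataFrame
    stratum: str | None = None


def _truncate(times, flags, horizon):
    t = np.minimum(times, horizon)
    f = np.where(times <= horizon, flags, 0)
    return t, f


def harrell_c(predictions, times, event_flags, horizon: float = 5.0) -> float:
    """Harrell's C with follow-up administratively truncated at the horizon.

    ``event_flags`` marks the primary event; competing deaths must already be
    coded 0 (they censor at the death time — cause-specific concordance).
    Higher predicted risk pairing with earlier events counts as concordant;
    prediction ties count 1/2.
    """
    predictions = np.asarray(predictions, dtype=float)
    if not np.all(np.isfinite(predictions)):
        raise ValueError("predictions must be finite")
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags).astype(int)
    t, f = _truncate(times, flags, horizon)
    if f.sum() == 0:
        raise ValueError("no comparable pairs: no events before the horizon")
    try:
        return float(concordance_index(t, -predictions, f))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs") from exc


def oe_ratio(predictions, times, event_types, horizon: float = 5.0, view: str = "km") -> float:
    """Observed/expected ratio: observed horizon risk over mean predicted."""
    predictions = np.asarray(predictions, dtype=float)
    expected = predictions.mean()
    if expected <= 0:
        raise ValueError("mean predicted risk is 0; O/E undefined")
    frame = pd.DataFrame(
        {
            "follow_up_time": np.asarray(times, dtype=float),
            "event": np.asarray(event_types),
        }
    )
    obs = observed_risk(frame, horizon, view=view)
    return float(obs / expected)


def _cloglog(p):
    return np.log(-np.log1p(-p))


def calibration_intercept_slope(predictions, pseudo_obs, link: str = "cloglog"):
    """Calibration intercept and slope from a pseudo-observation regression.

    Fits E[y] = g^{-1}(a + b * g(p)) by least squares (GEE, identity working
    covariance), where g is the cloglog (default) or logit link, y are the
    jackknife pseudo-observations and p the predicted risks.  The slope is b
    from the two-parameter fit; the intercept is a from a second fit with b
    fixed at 1.
    """
    p = np.asarray(predictions, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    if np.ptp(p) == 0:
        raise ValueError("constant predictions; calibration slope unidentifiable")
    y = np.asarray(pseudo_obs.values if hasattr(pseudo_obs, "values") else pseudo_obs,
                   dtype=float)
    if link == "cloglog":
        z = _cloglog(p)

        def mean_fn(a, b):
            return 1.0 - np.exp(-np.exp(np.clip(a + b * z, -30, 30)))

    elif link == "logit":
        z = np.log(p / (1 - p))

        def mean_fn(a, b):
            return 1.0 / (1.0 + np.exp(-np.clip(a + b * z, -30, 30)))

    else:
        raise ValueError(f"unknown link {link!r}")

    res2 = optimize.least_squares(
        lambda ab: y - mean_fn(ab[0], ab[1]), x0=[0.0, 1.0], method="lm"
    )
    slope = float(res2.x[1])
    res1 = optimize.least_squares(
        lambda a: y - mean_fn(a[0], 1.0), x0=[0.0], method="lm"
    )
    intercept = float(res1.x[0])
    return intercept, slope


def brier_scores(predictions, times, event_types, horizon: float = 5.0, view: str = "km"):
    """IPCW Brier score and scaled Brier score at the horizon.

    Squared error between predicted risk and the horizon event status,
    weighted by inverse-probability-of-censoring weights.  In the AJ view,
    deaths before the horizon count as known non-events (status 0, weight
    1/G); in the KM view they are censored.  The scaled score is
    1 - brier/brier_null with the null model predicting the overall observed
    risk for everyone.
    """
    p = np.asarray(predictions, dtype=float)
    times = np.asarray(times, dtype=float)
    codes = np.asarray(pd.Series(event_types).map(
        lambda e: EVENT_CODES[e] if isinstance(e, str) else int(e)
    ))
    if view == "km":
        flags = (codes == 1).astype(int)
    elif view == "aj":
        flags = (codes > 0).astype(int)
    else:
        raise ValueError(f"unknown view {view!r}")
    w = censoring_weights(times, flags, horizon)
    o = ((codes == 1) & (times <= horizon)).astype(float)
    n = times.size
    brier = float(np.sum(w * (p - o) ** 2) / n)
    frame = pd.DataFrame({"follow_up_time": times,
                          "event": pd.Series(codes).map({0: "censored", 1: "krt", 2: "death"})})
    null_p = observed_risk(frame, horizon, view=view)
    brier_null = float(np.sum(w * (null_p - o) ** 2) / n)
    scaled = 1.0 - brier / brier_null if brier_null > 0 else np.nan
    return brier, float(scaled)


def bootstrap_ci(metric_fn, data: pd.DataFrame, n_bootstrap: int = 1000, seed=None,
                 stratum_col: str | None = "ethnicity"):
    """Percentile bootstrap 95% CI of a scalar statistic of a cohort table.

    Resamples patients with replacement (stratified when a stratum column is
    present); failed resamples are dropped and counted.
    """
    if n_bootstrap < 100:
        warnings.warn("fewer than 100 bootstrap samples; percentile CI unreliable")
    rng = np.random.default_rng(seed)
    vals = []
    dropped = 0
    col = stratum_col if (stratum_col and stratum_col in data) else None
    for _ in range(n_bootstrap):
        if col:
            idx = stratified_bootstrap_index(data, rng, stratum_col=col)
        else:
            idx = rng.choice(data.index.to_numpy(), size=len(data), replace=True)
        try:
            vals.append(metric_fn(data.loc[idx].reset_index(drop=True)))
        except Exception:
            dropped += 1
    if not vals:
        raise RuntimeError("all bootstrap resamples failed")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi), dropped


def calibration_table(
    predictions,
    times,
    event_types,
    horizon: float = 5.0,
    grouping: str = "deciles_of_predicted_risk",
    view: str = "km",
    n_bootstrap: int = 200,
    seed=None,
) -> CalibrationTable:
    """Mean predicted vs observed risk by decile of predicted risk or by the
    fixed 6-level risk groups, with percentile bootstrap CIs per group."""
    from .core import risk_group

    p = np.asarray(predictions, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_types)
    if grouping == "deciles_of_predicted_risk":
        order = np.argsort(p, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(p.size)
        groups = np.minimum((ranks * 10) // p.size, 9).astype(int) + 1
        labels = range(1, 11)
    elif grouping == "fixed_risk_groups":
        groups = np.asarray(risk_group(p))
        labels = range(1, 7)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in labels:
        mask = groups == g
        if not mask.any():
            rows.append({"group": g, "n": 0, "mean_predicted": np.nan,
                         "observed": np.nan, "ci_lower": np.nan, "ci_upper": np.nan})
            continue
        sub = pd.DataFrame({"follow_up_time": times[mask], "event": events[mask]})
        obs = observed_risk(sub, horizon, view=view)
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(sub), len(sub))
            try:
                boots.append(observed_risk(sub.iloc[idx], horizon, view=view))
            except Exception:
                continue
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows.append({"group": int(g), "n": int(mask.sum()),
                     "mean_predicted": float(p[mask].mean()), "observed": float(obs),
                     "ci_lower": float(lo), "ci_upper": float(hi)})
    return CalibrationTable(grouping=grouping, table=pd.DataFrame(rows))


def point_metrics(model: SurvivalModel, cohort: pd.DataFrame,
                  horizon: float = 5.0, view: str = "km") -> dict:
    """All six performance measures as point estimates (no CIs)."""
    p = np.asarray(predict_risk_5y(model, cohort), dtype=float)
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    codes = event_codes(cohort)
    flags = (codes == 1).astype(int)
    c = harrell_c(p, times, flags, horizon)
    oe = oe_ratio(p, times, cohort["event"].to_numpy(), horizon, view=view)
    pseudo = pseudo_observations(times, codes, horizon,
                                 estimator=_VIEW_TO_ESTIMATOR[view])
    p_clip = np.clip(p, 1e-12, 1 - 1e-12)
    intercept, slope = calibration_intercept_slope(p_clip, pseudo)
    brier, scaled = brier_scores(p, times, codes, horizon, view=view)
    return {
        "c_index": c,
        "oe_ratio": oe,
        "calibration_intercept": intercept,
        "calibration_slope": slope,
        "brier": brier,
        "scaled_brier": scaled,
    }


def validate(
    model: SurvivalModel,
    cohort: pd.DataFrame,
    horizon: float = 5.0,
    view: str = "km",
    n_bootstrap: int = 1000,
    seed=None,
) -> ValidationReport:
    """Full validation report under one observed-risk convention.

    All six measures are recomputed on each stratified bootstrap resample to
    give percentile CIs; ``n_bootstrap=0`` skips the CIs (point estimates
    only).
    """
    points = point_metrics(model, cohort, horizon, view)
    metrics = {k: {"estimate": float(v), "ci_lower": float("nan"),
                   "ci_upper": float("nan")} for k, v in points.items()}
    dropped = 0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples = {k: [] for k in points}
        for _ in range(n_bootstrap):
            idx = stratified_bootstrap_index(cohort, rng)
            boot = cohort.loc[idx].reset_index(drop=True)
            try:
                vals = point_metrics(model, boot, horizon, view)
            except Exception:
                dropped += 1
                continue
            for k, v in vals.items():
                samples[k].append(v)
        for k in metrics:
            if samples[k]:
                lo, hi = np.percentile(samples[k], [2.5, 97.5])
                metrics[k]["ci_lower"] = float(min(lo, points[k]))
                metrics[k]["ci_upper"] = float(max(hi, points[k]))
    return ValidationReport(
        metrics=metrics,
        horizon=horizon,
        observed_risk_estimator=_VIEW_TO_ESTIMATOR[view],
        n_bootstrap=n_bootstrap,
        n_dropped_resamples=dropped,
    )
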