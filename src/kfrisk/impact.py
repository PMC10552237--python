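"""Clinical impact of referral criteria: referral tables and decision curves.

Criteria evaluated on the eligibility cohort (patients not previously known
to secondary care):

* ``nice_previous`` — refer iff eGFR < 30 ml/min/1.73m2 or ACR >= 70 mg/mmol
  (the pre-2019 NICE rule);
* ``risk_threshold`` — refer iff predicted 5-year KRT risk >= threshold;
* ``hybrid`` — refer iff predicted risk >= threshold or ACR >= 70 mg/mmol.

Referral accounting over a horizon: correct = referred patients with KRT
within the horizon, unnecessary = referred without, missed = unreferred with
KRT.  Net benefit NB(p_t) = TP/n - (FP/n) * p_t/(1-p_t); with censored
follow-up TP and FP are derived from the observed event probability
(Kaplan-Meier complement or Aalen-Johansen) within the referred group, which
reduces to raw counts under complete follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .updating import observed_risk

__all__ = [
    "ReferralCriterion",
    "ReferralTable",
    "NetBenefitCurve",
    "apply_criterion",
    "referral_table",
    "net_benefit",
    "decision_curves",
    "compare_referral_tables",
    "default_threshold_grid",
]


@dataclass
class ReferralCriterion:
    """A referral rule; ``kind`` in {nice_previous, risk_threshold, hybrid}."""

    kind: str
    risk_threshold: float | None = None
    acr_cut: float = 70.0
    egfr_cut: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("nice_previous", "risk_threshold", "hybrid"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.kind in ("risk_threshold", "hybrid"):
            if self.risk_threshold is None or not 0 < self.risk_threshold < 1:
                raise ValueError("risk_threshold must lie in (0, 1)")
        if self.acr_cut <= 0 or self.egfr_cut <= 0:
            raise ValueError("cut-offs must be positive")

    @property
    def label(self) -> str:
        if self.kind == "nice_previous":
            return "nice_previous"
        return f"{self.kind}@{self.risk_threshold:g}"


@dataclass
class ReferralTable:
    """Correct / unnecessary / missed referral accounting for one criterion.

    Invariants: total = correct + unnecessary; correct + missed = all KRT
    cases within the horizon.  Percentages follow the published convention:
    correct and unnecessary over total referrals, missed over total cases.
    """

    correct: int
    unnecessary: int
    missed: int
    total_referrals: int
    stratum: str | None = None

    def __post_init__(self) -> None:
        assert self.total_referrals == self.correct + self.unnecessary

    @property
    def total_krt_cases(self) -> int:
        return self.correct + self.missed

    def percentages(self) -> dict:
        tot = self.total_referrals
        cases = self.total_krt_cases
        return {
            "correct_pct_of_referrals": 100.0 * self.correct / tot if tot else np.nan,
            "unnecessary_pct_of_referrals": 100.0 * self.unnecessary / tot if tot else np.nan,
            "missed_pct_of_cases": 100.0 * self.missed / cases if cases else np.nan,
        }

    def as_dict(self) -> dict:
        return {
            "correct": self.correct,
            "unnecessary": self.unnecessary,
            "missed": self.missed,
            "total_referrals": self.total_referrals,
            "stratum": self.stratum,
            **self.percentages(),
        }


@dataclass
class NetBenefitCurve:
    label: str
    thresholds: np.ndarray
    net_benefit: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": self.label, "threshold": self.thresholds,
             "net_benefit": self.net_benefit}
        )


def default_threshold_grid() -> np.ndarray:
    """Threshold probabilities 1-12% in 0.5% steps."""
    return np.round(np.arange(0.01, 0.1201, 0.005), 4)


def apply_criterion(criterion: ReferralCriterion, cohort: pd.DataFrame,
                    predictions=None) -> np.ndarray:
    """Boolean referral flag per patient.

    The caller is responsible for restricting ``cohort`` (and predictions)
    to the eligibility cohort.  Risk comparisons use closed inequality
    (refer at risk >= threshold).
    """
    acr = cohort["acr"].to_numpy(dtype=float)
    if criterion.kind == "nice_previous":
        egfr = cohort["egfr"].to_numpy(dtype=float)
        return (egfr < criterion.egfr_cut) | (acr >= criterion.acr_cut)
    if predictions is None:
        raise ValueError(f"criterion {criterion.kind!r} requires predictions")
    p = np.asarray(predictions, dtype=float)
    refer = p >= criterion.risk_threshold
    if criterion.kind == "hybrid":
        refer = refer | (acr >= criterion.acr_cut)
    return refer


def referral_table(flags, cohort: pd.DataFrame, horizon: float = 5.0,
                   stratum: str | None = None) -> ReferralTable:
    """Count correct, unnecessary and missed referrals over the horizon.

    A KRT case is an observed ``krt`` event within the horizon (patients
    censored earlier count as non-cases, the raw-indicator convention)."""
    flags = np.asarray(flags, dtype=bool)
    case = (
        (cohort["event"].to_numpy() == "krt")
        & (cohort["follow_up_time"].to_numpy(dtype=float) <= horizon)
    )
    correct = int(np.sum(flags & case))
    unnecessary = int(np.sum(flags & ~case))
    missed = int(np.sum(~flags & case))
    return ReferralTable(
        correct=correct,
        unnecessary=unnecessary,
        missed=missed,
        total_referrals=correct + unnecessary,
        stratum=stratum,
    )


def net_benefit(predictions, cohort: pd.DataFrame, threshold: float,
                horizon: float = 5.0, view: str = "km",
                referral_flags=None) -> float:
    """Decision-curve net benefit at one threshold probability.

    NB = TP/n - (FP/n) * p_t/(1-p_t).  TP and FP come from the observed
    event probability within the referred set (KM complement or AJ), so
    censored patients contribute; a fixed referral rule can be evaluated by
    passing explicit ``referral_flags``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    n = len(cohort)
    if referral_flags is None:
        referral_flags = np.asarray(predictions, dtype=float) >= threshold
    referral_flags = np.asarray(referral_flags, dtype=bool)
    n_ref = int(referral_flags.sum())
    if n_ref == 0:
        return 0.0
    sub = cohort[referral_flags]
    risk_ref = observed_risk(sub, horizon, view=view)
    tp = n_ref * risk_ref
    fp = n_ref * (1.0 - risk_ref)
    return float(tp / n - (fp / n) * threshold / (1.0 - threshold))


def decision_curves(models: dict, criteria: dict, cohort: pd.DataFrame,
                    thresholds=None, horizon: float = 5.0,
                    view: str = "km") -> list[NetBenefitCurve]:
    """Net-benefit curves for a set of risk models and fixed criteria.

    ``models``: label -> per-patient predicted risks (aligned with cohort);
    referral at each grid threshold is risk >= p_t.  ``criteria``: label ->
    ReferralCriterion with a fixed referral set (its NB still varies with p_t
    through the false-positive penalty).
    """
    from .core import predict_risk_5y

    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("threshold grid must lie inside (0, 1)")
    curves = []
    for label, preds in models.items():
        p = np.asarray(preds, dtype=float)
        nb = np.array([net_benefit(p, cohort, t, horizon, view) for t in thresholds])
        curves.append(NetBenefitCurve(label, thresholds, nb))
    for label, crit in (criteria or {}).items():
        flags = apply_criterion(crit, cohort)
        nb = np.array([
            net_benefit(None, cohort, t, horizon, view, referral_flags=flags)
            for t in thresholds
        ])
        curves.append(NetBenefitCurve(label, thresholds, nb))
    return curves


def compare_referral_tables(new: ReferralTable, reference: ReferralTable) -> dict:
    """Published comparison conventions between two referral tables.

    Count differences are (new - reference); relative changes are the count
    difference over the *reference* count, in percent.  The denominator
    convention is recorded in the output.
    """
    def rel(a, b):
        return 100.0 * (a - b) / b if b else np.nan

    return {
        "unnecessary_diff": new.unnecessary - reference.unnecessary,
        "unnecessary_pct_change": rel(new.unnecessary, reference.unnecessary),
        "correct_diff": new.correct - reference.correct,
        "correct_pct_change": rel(new.correct, reference.correct),
        "missed_diff": new.missed - reference.missed,
        "missed_pct_change": rel(new.missed, reference.missed),
        "total_diff": new.total_referrals - reference.total_referrals,
        "denominator_convention": "count difference over the reference count",
    }


def referrals_per_case_justified(threshold: float) -> float:
    """Exchange rate implied by a threshold probability: at p_t a clinician
    accepts up to 1/p_t referrals per true KRT case."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return 1.0 / threshold
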