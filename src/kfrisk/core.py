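"""Risk-equation core: survival models, linear predictors, 5-year risk.

The models handled here all share the proportional-hazards prediction form

    risk(5y) = 1 - S0(5) ** exp(LP),

where the linear predictor is built from scaled and centred covariates,

    LP = lp_multiplier * sum_j beta_j * (x_j / scale_j - centre_j),

with the urine albumin-to-creatinine ratio (ACR) log-transformed before
scaling, following the kidney failure risk equation (KFRE) convention.  For a
Fine-Gray (subdistribution) model the same algebra applies with S0(5) read as
the complement of the baseline 5-year cumulative incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurvivalModel",
    "RiskPrediction",
    "MissingCovariateError",
    "InvalidModelError",
    "linear_predictor",
    "predict_risk_5y",
    "risk_group",
    "load_model",
    "save_model",
    "default_kfre_model",
    "RISK_GROUP_BOUNDARIES",
]

#: Risk-group boundaries on the probability scale.  Left-closed, right-open:
#: [0,3%), [3,5%), [5,15%), [15,25%), [25,50%), [50%,100%].
RISK_GROUP_BOUNDARIES = (0.03, 0.05, 0.15, 0.25, 0.50)

COX_CAUSE_SPECIFIC = "cox_cause_specific"
FINE_GRAY = "fine_gray"


class MissingCovariateError(KeyError):
    """A predictor required by the model is absent from the patient data."""


class InvalidModelError(ValueError):
    """The model violates one of its structural invariants."""


@dataclass
class SurvivalModel:
    """A proportional-hazards risk equation for 5-year kidney failure risk.

    Parameters
    ----------
    family
        ``"cox_cause_specific"`` (deaths treated as censoring) or
        ``"fine_gray"`` (subdistribution hazard; the baseline survival is the
        complement of the baseline cumulative incidence at 5 years).
    coefficients
        Map predictor name -> log-(sub)hazard ratio on the scaled/centred
        basis.  Interaction predictors are named ``"a:b"``.
    centring
        Map base-predictor name -> ``(scale, centre)``; the design value is
        ``x/scale - centre`` (after the ACR log transform where applicable).
    acr_log_transform
        Natural-log transform of ACR before scaling/centring.
    acr_unit_factor
        Multiplier applied to ACR (supplied in mg/mmol) before the log, e.g.
        8.84 when the published coefficients expect mg/g.
    baseline_survival_5y
        S0(5), in (0, 1).
    lp_multiplier
        Uniform recalibration/shrinkage factor on the linear predictor.
    intercept_shift
        Additive baseline recalibration on the log-cumulative-hazard scale.
    baseline_stale
        Set when the linear predictor has been rescaled without re-estimating
        the baseline; predictions refuse to run until the baseline is updated.
    """

    family: str
    coefficients: dict[str, float]
    centring: dict[str, tuple[float, float]]
    baseline_survival_5y: float
    acr_log_transform: bool = True
    acr_unit_factor: float = 1.0
    lp_multiplier: float = 1.0
    intercept_shift: float = 0.0
    baseline_stale: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in (COX_CAUSE_SPECIFIC, FINE_GRAY):
            raise InvalidModelError(f"unknown model family {self.family!r}")
        if not 0.0 < self.baseline_survival_5y < 1.0:
            raise InvalidModelError(
                f"baseline_survival_5y must lie in (0,1), got "
                f"{self.baseline_survival_5y}"
            )
        for name in self.coefficients:
            for part in name.split(":"):
                if part not in self.centring:
                    raise InvalidModelError(
                        f"predictor {part!r} has no centring entry"
                    )

    def copy(self, **changes) -> "SurvivalModel":
        out = replace(
            self,
            coefficients=dict(self.coefficients),
            centring=dict(self.centring),
            meta=dict(self.meta),
        )
        for key, val in changes.items():
            setattr(out, key, val)
        return out


@dataclass
class RiskPrediction:
    """Per-patient predicted 5-year risk with its categorical risk group."""

    id: object
    linear_predictor: float
    risk_5y: float
    risk_group: int


# -- raw covariate extraction -------------------------------------------------

_SEX_MALE = {"male": 1.0, "m": 1.0, 1: 1.0, "female": 0.0, "f": 0.0, 0: 0.0}
_ETH_SA = {"south_asian": 1.0, "white": 0.0}


def _raw_column(model: SurvivalModel, data: pd.DataFrame, name: str) -> np.ndarray:
    """Untransformed covariate on the scale the coefficients expect."""
    if name == "sex":
        if "sex" not in data:
            raise MissingCovariateError("sex")
        return data["sex"].map(_SEX_MALE).to_numpy(dtype=float)
    if name == "ethnicity":
        if "ethnicity" not in data:
            raise MissingCovariateError("ethnicity")
        return data["ethnicity"].map(_ETH_SA).to_numpy(dtype=float)
    if name == "acr":
        if "acr" not in data:
            raise MissingCovariateError("acr")
        x = data["acr"].to_numpy(dtype=float) * model.acr_unit_factor
        return np.log(x) if model.acr_log_transform else x
    if name not in data:
        raise MissingCovariateError(name)
    return data[name].to_numpy(dtype=float)


def _design_column(model: SurvivalModel, data: pd.DataFrame, name: str) -> np.ndarray:
    cols = []
    for part in name.split(":"):
        scale, centre = model.centring[part]
        cols.append(_raw_column(model, data, part) / scale - centre)
    out = cols[0]
    for extra in cols[1:]:
        out = out * extra
    return out


def design_matrix(model: SurvivalModel, data: pd.DataFrame) -> pd.DataFrame:
    """Scaled/centred design matrix with one column per model coefficient."""
    return pd.DataFrame(
        {name: _design_column(model, data, name) for name in model.coefficients},
        index=data.index,
    )


def _as_frame(patient) -> pd.DataFrame:
    if isinstance(patient, pd.DataFrame):
        return patient
    if isinstance(patient, pd.Series):
        return patient.to_frame().T
    if isinstance(patient, Mapping):
        return pd.DataFrame([patient])
    # dataclass-like PatientRecord
    return pd.DataFrame([vars(patient)])


def linear_predictor(model: SurvivalModel, patient) -> np.ndarray | float:
    """Linear predictor sum_j beta_j (x_j/scale_j - centre_j), scaled by
    ``model.lp_multiplier``.

    Accepts a cohort DataFrame (returns an array) or a single record
    (mapping / Series / PatientRecord; returns a float).
    """
    data = _as_frame(patient)
    lp = np.zeros(len(data))
    for name, beta in model.coefficients.items():
        lp += beta * _design_column(model, data, name)
    lp *= model.lp_multiplier
    if not isinstance(patient, pd.DataFrame):
        return float(lp[0])
    return lp


def predict_risk_5y(model: SurvivalModel, patient) -> np.ndarray | float:
    """Predicted 5-year risk, 1 - S0(5)^exp(LP + intercept_shift)."""
    if model.baseline_stale:
        raise InvalidModelError(
            "baseline_survival_5y is stale after a linear-predictor rescale; "
            "re-estimate it (update_baseline) before predicting"
        )
    lp = linear_predictor(model, patient)
    risk = 1.0 - model.baseline_survival_5y ** np.exp(
        np.asarray(lp) + model.intercept_shift
    )
    if not isinstance(patient, pd.DataFrame):
        return float(np.asarray(risk).ravel()[0])
    return np.asarray(risk)


def risk_group(risk_5y) -> np.ndarray | int:
    """Categorise 5-year risk into the six conventional KFRE risk groups.

    Groups are left-closed, right-open in percent: [0,3), [3,5), [5,15),
    [15,25), [25,50), [50,100].
    """
    arr = np.asarray(risk_5y, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("risk must lie in [0, 1]")
    groups = np.digitize(arr, RISK_GROUP_BOUNDARIES, right=False) + 1
    if np.isscalar(risk_5y) or arr.ndim == 0:
        return int(groups)
    return groups


def predict(model: SurvivalModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level prediction table: id, linear_predictor, risk_5y, risk_group."""
    lp = linear_predictor(model, cohort)
    risk = 1.0 - model.baseline_survival_5y ** np.exp(lp + model.intercept_shift)
    if model.baseline_stale:
        raise InvalidModelError("stale baseline; run update_baseline first")
    return pd.DataFrame(
        {
            "id": cohort["id"] if "id" in cohort else cohort.index,
            "linear_predictor": lp,
            "risk_5y": risk,
            "risk_group": risk_group(risk),
        },
        index=cohort.index,
    )


# -- model (de)serialisation --------------------------------------------------


def _model_to_dict(model: SurvivalModel) -> dict:
    return {
        "family": model.family,
        "coefficients": dict(model.coefficients),
        "centring": {k: [float(s), float(c)] for k, (s, c) in model.centring.items()},
        "acr_log_transform": bool(model.acr_log_transform),
        "acr_unit_factor": float(model.acr_unit_factor),
        "baseline_survival_5y": float(model.baseline_survival_5y),
        "lp_multiplier": float(model.lp_multiplier),
        "intercept_shift": float(model.intercept_shift),
        "meta": dict(model.meta),
    }


def save_model(model: SurvivalModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def _model_from_dict(raw: dict) -> SurvivalModel:
    return SurvivalModel(
        family=raw["family"],
        coefficients={k: float(v) for k, v in raw["coefficients"].items()},
        centring={k: (float(v[0]), float(v[1])) for k, v in raw["centring"].items()},
        acr_log_transform=bool(raw.get("acr_log_transform", True)),
        acr_unit_factor=float(raw.get("acr_unit_factor", 1.0)),
        baseline_survival_5y=float(raw["baseline_survival_5y"]),
        lp_multiplier=float(raw.get("lp_multiplier", 1.0)),
        intercept_shift=float(raw.get("intercept_shift", 0.0)),
        meta=dict(raw.get("meta", {})),
    )


def load_model(path) -> SurvivalModel:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _model_from_dict(raw)


def default_kfre_model() -> SurvivalModel:
    """The packaged non-North-American 4-variable 5-year KFRE."""
    ref = resources.files("kfrisk") / "configs" / "kfre_non_na_4var.yaml"
    return _model_from_dict(yaml.safe_load(ref.read_text()))
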