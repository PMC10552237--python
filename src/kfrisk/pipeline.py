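"""End-to-end orchestration: validate -> update -> internally validate ->
assess clinical impact, per ethnic stratum and overall."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import impact, metrics, updating
from .core import SurvivalModel, predict_risk_5y
from .impact import ReferralCriterion

__all__ = ["RunConfig", "run_pipeline", "develop_model", "published_referral_tables"]

log = logging.getLogger("kfrisk")


@dataclass
class RunConfig:
    """Run-wide settings; the defaults are the study's conventions
    (5-year horizon, 1000 CI bootstraps, 500 internal-validation bootstraps,
    1-12% decision-curve grid)."""

    horizon: float = 5.0
    view: str = "km"
    n_bootstrap_ci: int = 1000
    n_bootstrap_internal: int = 500
    seed: int = 1
    threshold_grid: tuple = tuple(impact.default_threshold_grid())
    risk_threshold: float = 0.05
    acr_cut: float = 70.0
    stratum_col: str = "ethnicity"
    reselect_interactions_model6: bool = False

    def as_dict(self) -> dict:
        raw = asdict(self)
        raw["threshold_grid"] = [float(t) for t in self.threshold_grid]
        return raw


def _split_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def develop_model(
    cohort: pd.DataFrame,
    config: RunConfig,
    family: str = "cox_cause_specific",
    selected_interactions=None,
):
    """Full model-5/6 development: re-estimation with interaction selection,
    bootstrap internal validation, uniform shrinkage by the optimism-adjusted
    calibration slope, and baseline re-estimation."""
    view = config.view if family == "cox_cause_specific" else "aj"
    if selected_interactions is None:
        result = updating.select_interactions(
            cohort, horizon=config.horizon, family=family
        )
    else:
        model = updating._refit(
            cohort, updating.DEFAULT_PREDICTORS, tuple(selected_interactions),
            None, config.horizon, family,
        )
        result = updating.UpdateResult(
            model=model,
            method=5 if family == "cox_cause_specific" else 6,
            selected_interactions=list(selected_interactions),
        )

    def fit_fn(data):
        return updating._refit(
            data, updating.DEFAULT_PREDICTORS,
            tuple(result.selected_interactions), None, config.horizon, family,
        )

    def metric_fn(model, data):
        return metrics.point_metrics(model, data, config.horizon, view)

    report = updating.internal_validate(
        fit_fn, metric_fn, cohort,
        n_bootstrap=config.n_bootstrap_internal,
        seed=_split_seed(config.seed, 5 if family == "cox_cause_specific" else 6),
    )
    shrink = report.metrics["calibration_slope"]["optimism_adjusted"]
    shrunk = updating.apply_shrinkage(result.model, shrink)
    final = updating.update_baseline(shrunk, cohort, config.horizon, view=view).model
    result.model = final
    result.shrinkage_factor = float(shrink)
    return result, report


def run_pipeline(cohort: pd.DataFrame, base_model: SurvivalModel, config: RunConfig) -> dict:
    """Produce the full result bundle for one cohort.

    Contents: baseline validation reports (overall and per stratum), updated
    models 1-6 (2a/2b, 3a/3b stratified), internal-validation reports for
    models 5 and 6, calibration tables, referral tables under the previous
    NICE, pure-risk and hybrid criteria, and decision curves.  Every artefact
    embeds the config and seed.
    """
    bundle: dict = {"config": config.as_dict(), "stages": {}}
    strata = {"overall": cohort}
    if config.stratum_col in cohort:
        for name, grp in cohort.groupby(config.stratum_col):
            strata[str(name)] = grp.reset_index(drop=True)

    log.info("pipeline start: n=%d, events=%s", len(cohort),
             cohort["event"].value_counts().to_dict())

    # 1. external validation of the base model
    validation = {}
    for name, data in strata.items():
        validation[name] = metrics.validate(
            base_model, data, config.horizon, config.view,
            n_bootstrap=config.n_bootstrap_ci, seed=_split_seed(config.seed, 1),
        ).as_dict()
    bundle["validation"] = validation

    # 2. calibration tables for the base model
    tables = {}
    for name, data in strata.items():
        p = predict_risk_5y(base_model, data)
        tab = metrics.calibration_table(
            p, data["follow_up_time"], data["event"], config.horizon,
            view=config.view, seed=_split_seed(config.seed, 2),
        )
        tables[name] = tab.table.to_dict(orient="records")
    bundle["calibration_tables"] = tables

    # 3. updating ladder
    updates: dict = {"1": updating.UpdateResult(model=base_model, method=1).as_dict()}
    for suffix, stratum in (("a", "white"), ("b", "south_asian")):
        if stratum in strata:
            data = strata[stratum]
            updates["2" + suffix] = updating.update_baseline(
                base_model, data, config.horizon, config.view).as_dict()
            updates["3" + suffix] = updating.recalibrate_slope(
                base_model, data, config.horizon, config.view).as_dict()
    updates["4"] = updating.add_predictor(
        base_model, cohort, "ethnicity", config.horizon, config.view).as_dict()
    res5, rep5 = develop_model(cohort, config, family="cox_cause_specific")
    updates["5"] = res5.as_dict()
    inherit = None if config.reselect_interactions_model6 else res5.selected_interactions
    res6, rep6 = develop_model(
        cohort, config, family="fine_gray", selected_interactions=inherit
    )
    updates["6"] = res6.as_dict()
    bundle["updates"] = updates
    bundle["internal_validation"] = {"5": rep5.as_dict(), "6": rep6.as_dict()}

    # 4. clinical impact on the eligibility cohort
    eligible = cohort[cohort["eligible"] == 1].reset_index(drop=True)
    impact_bundle: dict = {}
    if len(eligible):
        from .core import _model_from_dict

        model5 = _model_from_dict(updates["5"]["model"])
        model6 = _model_from_dict(updates["6"]["model"])
        preds = {
            "model_5": np.asarray(predict_risk_5y(model5, eligible)),
            "model_6": np.asarray(predict_risk_5y(model6, eligible)),
        }
        nice = ReferralCriterion(kind="nice_previous", acr_cut=config.acr_cut)
        hybrid = ReferralCriterion(
            kind="hybrid", risk_threshold=config.risk_threshold, acr_cut=config.acr_cut
        )
        tables = {}
        for label, p in preds.items():
            for crit_label, crit in (("hybrid", hybrid),):
                flags = impact.apply_criterion(crit, eligible, p)
                overall = impact.referral_table(flags, eligible, config.horizon)
                tables[f"{label}_{crit_label}"] = overall.as_dict()
                for name in ("white", "south_asian"):
                    mask = (eligible[config.stratum_col] == name).to_numpy()
                    if mask.any():
                        tables[f"{label}_{crit_label}_{name}"] = impact.referral_table(
                            flags[mask], eligible[mask], config.horizon, stratum=name
                        ).as_dict()
        flags = impact.apply_criterion(nice, eligible)
        tables["nice_previous"] = impact.referral_table(
            flags, eligible, config.horizon).as_dict()
        impact_bundle["referral_tables"] = tables
        curves = impact.decision_curves(
            preds, {"nice_previous": nice}, eligible,
            thresholds=np.asarray(config.threshold_grid),
            horizon=config.horizon, view=config.view,
        )
        impact_bundle["decision_curves"] = pd.concat(
            [c.to_frame() for c in curves], ignore_index=True
        ).to_dict(orient="records")
    bundle["impact"] = impact_bundle
    log.info("pipeline complete")
    return bundle


def published_referral_tables() -> dict:
    """Published referral-criteria counts for the deposited cohort, as
    ReferralTable objects keyed by stratum then criterion."""
    ref = resources.files("kfrisk") / "configs" / "published_referral_counts.yaml"
    raw = yaml.safe_load(ref.read_text())
    out: dict = {}
    for stratum, entries in raw.items():
        out[stratum] = {}
        for crit, cts in entries.items():
            if crit == "n":
                out[stratum]["n"] = cts
                continue
            out[stratum][crit] = impact.ReferralTable(
                correct=cts["correct"],
                unnecessary=cts["unnecessary"],
                missed=cts["missed"],
                total_referrals=cts["total"],
                stratum=stratum,
            )
    return out


def save_bundle(bundle: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1, default=float)
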