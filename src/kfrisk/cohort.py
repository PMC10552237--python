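"""Cohort file I/O and patient-level validation.

The canonical cohort file is a comma-delimited table with a header row and one
row per patient.  Columns mirror :class:`PatientRecord`; the event column takes
the labels ``krt`` (kidney replacement therapy, the primary event), ``death``
(the competing event) and ``censored``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "CohortReadReport",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "COLUMNS",
    "EVENT_LABELS",
    "ETHNICITIES",
]

COLUMNS = [
    "id",
    "age",
    "sex",
    "ethnicity",
    "egfr",
    "acr",
    "diabetes",
    "heart_failure",
    "cardiovascular_disease",
    "hypertension",
    "follow_up_time",
    "event",
    "eligible",
]

EVENT_LABELS = ("krt", "death", "censored")
ETHNICITIES = ("white", "south_asian")
SEXES = ("male", "female")

_NUMERIC = ["age", "egfr", "acr", "follow_up_time"]
_BINARY = ["diabetes", "heart_failure", "cardiovascular_disease", "hypertension", "eligible"]


class CohortError(ValueError):
    """Raised for unreadable or structurally invalid cohort files."""


@dataclass
class PatientRecord:
    """One subject: baseline covariates, follow-up and outcome.

    Units: age in years, eGFR in ml/min/1.73m2, ACR in mg/mmol, follow-up in
    years.  ``eligible`` flags patients not previously known to secondary
    care, in whom referral criteria are assessed.
    """

    id: object
    age: float
    sex: str
    ethnicity: str
    egfr: float
    acr: float
    diabetes: int
    heart_failure: int
    cardiovascular_disease: int
    hypertension: int
    follow_up_time: float
    event: str
    eligible: int

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CohortError(f"patient {self.id}: age must be > 0")
        if not self.egfr > 0:
            raise CohortError(f"patient {self.id}: egfr must be > 0")
        if not self.acr > 0:
            raise CohortError(f"patient {self.id}: acr must be > 0")
        if self.follow_up_time < 0:
            raise CohortError(f"patient {self.id}: negative follow-up time")
        if self.event not in EVENT_LABELS:
            raise CohortError(f"patient {self.id}: unknown event {self.event!r}")

    @property
    def meets_inclusion(self) -> bool:
        """Cohort inclusion rule: established eGFR below 60 ml/min/1.73m2."""
        return self.egfr < 60.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortReadReport:
    """Accounting of rows read, retained and excluded from a cohort file."""

    n_read: int
    n_retained: int
    n_missing_ethnicity: int
    n_other_ethnicity: int
    n_invalid: int
    invalid_lines: list

    @property
    def n_excluded(self) -> int:
        return self.n_read - self.n_retained


def validate_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, types and row invariants; returns typed copy.

    Raises :class:`CohortError` naming the first offending column/row.
    """
    missing = [c for c in COLUMNS if c not in data.columns]
    if missing:
        raise CohortError(f"cohort file missing columns: {missing}")
    out = data.copy()
    for col in _NUMERIC:
        out[col] = pd.to_numeric(out[col], errors="raise")
    for col in _BINARY:
        out[col] = out[col].astype(int)
        if not out[col].isin((0, 1)).all():
            raise CohortError(f"column {col!r} must be binary 0/1")
    bad_event = ~out["event"].isin(EVENT_LABELS)
    if bad_event.any():
        i = out.index[bad_event][0]
        raise CohortError(f"row {i}: unknown event label {out.loc[i, 'event']!r}")
    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        i = out.index[bad_sex][0]
        raise CohortError(f"row {i}: unknown sex label {out.loc[i, 'sex']!r}")
    for col, low in (("age", 0), ("egfr", 0), ("acr", 0)):
        if (out[col] <= low).any():
            i = out.index[out[col] <= low][0]
            raise CohortError(f"row {i}: {col} must be > {low}")
    if (out["follow_up_time"] < 0).any():
        raise CohortError("negative follow_up_time")
    return out


def read_cohort(path, return_report: bool = False):
    """Read a delimited cohort file, excluding unusable rows with accounting.

    Rows with missing ethnicity or an ethnicity outside
    ``{white, south_asian}`` are excluded and counted (the study's analysis
    population is restricted to those two groups); rows violating field
    invariants are rejected with line numbers.

    Returns the retained cohort DataFrame, or ``(cohort, CohortReadReport)``
    when ``return_report`` is set.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortError(f"empty cohort file: {path}") from None
    if len(raw) == 0:
        raise CohortError(f"cohort file has a header but no rows: {path}")
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise CohortError(f"cohort file missing columns: {missing}")

    eth = raw["ethnicity"]
    missing_eth = eth.isna() | (eth.astype(str).str.strip() == "")
    other_eth = ~missing_eth & ~eth.isin(ETHNICITIES)
    keep = ~(missing_eth | other_eth)

    data = raw[keep].copy()
    invalid_lines: list[tuple[int, str]] = []
    # validate row-wise invariants vectorised; collect offending line numbers
    # (+2: header line and 1-based numbering)
    checks = [
        (~data["event"].isin(EVENT_LABELS), "unknown event label"),
        (~data["sex"].isin(SEXES), "unknown sex label"),
        (pd.to_numeric(data["age"], errors="coerce").le(0)
         | pd.to_numeric(data["age"], errors="coerce").isna(), "age must be > 0"),
        (pd.to_numeric(data["egfr"], errors="coerce").le(0)
         | pd.to_numeric(data["egfr"], errors="coerce").isna(), "egfr must be > 0"),
        (pd.to_numeric(data["acr"], errors="coerce").le(0)
         | pd.to_numeric(data["acr"], errors="coerce").isna(), "acr must be > 0"),
        (pd.to_numeric(data["follow_up_time"], errors="coerce").lt(0)
         | pd.to_numeric(data["follow_up_time"], errors="coerce").isna(),
         "follow_up_time must be >= 0"),
    ]
    bad = pd.Series(False, index=data.index)
    for mask, msg in checks:
        for idx in data.index[mask & ~bad]:
            invalid_lines.append((int(idx) + 2, msg))
        bad |= mask
    data = data[~bad]
    data = validate_cohort(data)
    data = data.reset_index(drop=True)

    report = CohortReadReport(
        n_read=len(raw),
        n_retained=len(data),
        n_missing_ethnicity=int(missing_eth.sum()),
        n_other_ethnicity=int(other_eth.sum()),
        n_invalid=int(bad.sum()),
        invalid_lines=sorted(invalid_lines),
    )
    if return_report:
        return data, report
    return data


def write_cohort(data: pd.DataFrame, path) -> None:
    """Write the canonical comma-delimited cohort file."""
    data.to_csv(path, index=False, columns=[c for c in COLUMNS if c in data.columns])


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])
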