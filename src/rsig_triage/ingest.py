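"""Registry cleaning, exclusion rules, and rSIG construction.

The analysis unit is the cleaned record: a pediatric trauma patient with
plausible arrival vitals, a GCS, a binary in-hospital outcome, and the
reverse shock index multiplied by the GCS,

    rSIG = (SBP / HR) * GCS,

a dimensionless score that falls with hypotension, tachycardia and
depressed consciousness — the three bedside hallmarks of a child at risk
of dying in hospital.

Cleaning follows registry conventions: physiologically implausible vitals
(SBP outside [30, 300] mmHg, HR outside [30, 200] bpm; the bounds
themselves are retained) are converted to missing rather than dropped
outright, and rows are then excluded for over-age, non-trauma mechanism,
late arrival (more than six hours from injury), or missing core variables.
Every exclusion is tallied so the flow reconciles exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from numbers import Real

import numpy as np
import pandas as pd

__all__ = [
    "SBP_RANGE",
    "HR_RANGE",
    "GCS_RANGE",
    "ExclusionLog",
    "compute_rsig",
    "clean_vitals",
    "apply_exclusions",
    "read_cohort_csv",
    "write_clean_csv",
]

SBP_RANGE = (30.0, 300.0)  #: plausible systolic blood pressure, mmHg (inclusive)
HR_RANGE = (30.0, 200.0)   #: plausible heart rate, bpm (inclusive)
GCS_RANGE = (3, 15)        #: admissible Glasgow Coma Scale scores

MAX_AGE_YEARS = 18
MAX_ARRIVAL_MINUTES = 360  #: acute trauma: injury within six hours of arrival

#: Column schema of the cleaned analysis dataset.
CLEAN_COLUMNS = ("age", "sbp", "hr", "gcs", "rsig", "outcome")


@dataclass
class ExclusionLog:
    """Counts of rows dropped per reason, plus implausible-field conversions.

    ``implausible_converted`` tallies individual vital fields converted to
    missing, not row drops, so the conservation identity is

        n_input == n_output + sum of row-drop counts.
    """

    over_age: int = 0
    non_trauma_flagged: int = 0
    missing_core_variable: int = 0
    late_arrival: int = 0
    missing_outcome: int = 0
    implausible_converted: int = 0
    dead_on_arrival: int = 0
    transfer_out: int = 0

    ROW_DROP_REASONS = ("over_age", "non_trauma_flagged", "missing_core_variable",
                        "late_arrival", "missing_outcome",
                        "dead_on_arrival", "transfer_out")

    def total_dropped(self) -> int:
        return sum(getattr(self, r) for r in self.ROW_DROP_REASONS)

    def to_frame(self) -> pd.DataFrame:
        rows = [(f.name, getattr(self, f.name)) for f in fields(self)]
        return pd.DataFrame(rows, columns=["reason", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_rsig(sbp, hr, gcs):
    """Reverse shock index times GCS: ``(sbp / hr) * gcs``.

    Accepts scalars or aligned arrays.  Missing inputs or a nonpositive
    heart rate are rejected: the score is undefined there, and upstream
    cleaning should already have removed such rows.
    """
    sbp_a = np.asarray(sbp, dtype=float)
    hr_a = np.asarray(hr, dtype=float)
    gcs_a = np.asarray(gcs, dtype=float)
    if np.any(np.isnan(sbp_a)) or np.any(np.isnan(hr_a)) or np.any(np.isnan(gcs_a)):
        raise ValueError("rSIG requires SBP, HR and GCS to all be present")
    if np.any(hr_a <= 0):
        raise ValueError("rSIG requires a positive heart rate")
    out = sbp_a / hr_a * gcs_a
    if out.ndim == 0 and isinstance(sbp, Real):
        return float(out)
    return out


def clean_vitals(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Convert implausible vitals to missing; return (frame, n converted fields).

    SBP outside [30, 300] mmHg, HR outside [30, 200] bpm and GCS outside
    [3, 15] are treated as missing data; boundary values are retained.
    Total function: all other fields pass through unchanged, and applying
    it twice is the same as applying it once.
    """
    out = records.copy()
    converted = 0
    for col, (lo, hi) in (("sbp", SBP_RANGE), ("hr", HR_RANGE), ("gcs", GCS_RANGE)):
        vals = out[col].to_numpy(dtype=float, copy=True)
        bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
        converted += int(bad.sum())
        vals[bad] = np.nan
        out[col] = vals
    return out, converted


def apply_exclusions(
    records: pd.DataFrame,
    max_arrival_minutes: float = MAX_ARRIVAL_MINUTES,
    mechanism_whitelist: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the inclusion rules and compute rSIG on the retained rows.

    Rows are dropped, in order, for: age above 18 completed years;
    a mechanism outside ``mechanism_whitelist`` (when given; the synthetic
    generator only emits trauma mechanisms, so the default is pass-through);
    a truthy optional ``dead_on_arrival`` / ``transfer_out`` column;
    arrival more than ``max_arrival_minutes`` after injury; a missing
    outcome; and a missing core variable (SBP, HR or GCS).  Implausible
    vitals are converted to missing first, so they surface as
    missing-core-variable exclusions with the conversions tallied
    separately.

    An empty retained set is a warning, not a failure: downstream stages
    decide whether they can proceed.
    """
    df, converted = clean_vitals(records)
    log = ExclusionLog(implausible_converted=converted)

    def drop(mask: np.ndarray, reason: str) -> None:
        setattr(log, reason, getattr(log, reason) + int(mask.sum()))

    keep = np.ones(len(df), dtype=bool)

    age = df["age"].to_numpy()
    m = keep & ((age < 0) | (age > MAX_AGE_YEARS))
    drop(m, "over_age"); keep &= ~m

    if mechanism_whitelist is not None:
        m = keep & ~df["mechanism"].isin(mechanism_whitelist).to_numpy()
        drop(m, "non_trauma_flagged"); keep &= ~m

    for col, reason in (("dead_on_arrival", "dead_on_arrival"),
                        ("transfer_out", "transfer_out")):
        if col in df.columns:
            m = keep & df[col].fillna(False).astype(bool).to_numpy()
            drop(m, reason); keep &= ~m

    arrival = df["time_to_arrival_min"].to_numpy(dtype=float)
    m = keep & (np.isnan(arrival) | (arrival > max_arrival_minutes))
    drop(m, "late_arrival"); keep &= ~m

    m = keep & df["outcome"].isna().to_numpy()
    drop(m, "missing_outcome"); keep &= ~m

    core_missing = (df["sbp"].isna() | df["hr"].isna() | df["gcs"].isna()).to_numpy()
    m = keep & core_missing
    drop(m, "missing_core_variable"); keep &= ~m

    kept = df.loc[keep]
    clean = pd.DataFrame({
        "age": kept["age"].to_numpy(dtype=np.int64),
        "sbp": kept["sbp"].to_numpy(dtype=float),
        "hr": kept["hr"].to_numpy(dtype=float),
        "gcs": kept["gcs"].to_numpy(dtype=np.int64),
        "outcome": (kept["outcome"] == "died").to_numpy(dtype=np.int64),
    })
    if len(clean):
        clean["rsig"] = compute_rsig(clean["sbp"], clean["hr"], clean["gcs"])
    else:
        clean["rsig"] = pd.Series(dtype=float)
        import warnings
        warnings.warn("all records excluded; clean dataset is empty", stacklevel=2)
    clean = clean[list(CLEAN_COLUMNS)].reset_index(drop=True)

    assert len(records) == len(clean) + log.total_dropped()
    return clean, log


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a raw cohort CSV written by the synthetic registry (missing = empty)."""
    return pd.read_csv(path, dtype={"sbp": float, "hr": float, "gcs": float})


def write_clean_csv(clean: pd.DataFrame, path) -> None:
    clean.to_csv(path, index=False)
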