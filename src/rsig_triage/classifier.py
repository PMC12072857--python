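"""Age-specific rSIG triage classification.

Packages an age-band → cutoff table and classifies individual patients:
a patient is high risk iff their rSIG falls strictly below the cutoff of
their age band (a patient exactly at the cutoff is not flagged).  The
recommended published table — derived from the triage-goal optimization on
the three AUC-selected age groups — is

    ages 0-9:   cutoff 13.3
    ages 10-14: cutoff 18.4
    ages 15-18: cutoff 20.9

so, for example, an injured 13-year-old with rSIG 15 is high risk (15 <
18.4) while a 3-year-old with the same rSIG is not (15 >= 13.3): the same
score means different things at different ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import compute_rsig

__all__ = ["CutoffTable", "published_table", "classify", "classify_frame"]

AGE_MIN, AGE_MAX = 0, 18


@dataclass(frozen=True)
class CutoffTable:
    """Ordered (age_min, age_max, cutoff) entries covering ages 0-18."""

    entries: tuple[tuple[int, int, float], ...]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        expected = AGE_MIN
        for lo, hi, cut in self.entries:
            if lo != expected or hi < lo:
                raise ValueError(f"entries must be contiguous and ordered: {self.entries}")
            if cut <= 0:
                raise ValueError("cutoffs must be strictly positive")
            expected = hi + 1
        if not self.entries or self.entries[-1][1] != AGE_MAX:
            raise ValueError(f"entries must cover ages {AGE_MIN}-{AGE_MAX}")

    def lookup(self, age: float) -> float:
        """Cutoff applying to a patient of the given age (completed years).

        Non-integer ages are truncated to completed years.
        """
        years = int(np.floor(age))
        for lo, hi, cut in self.entries:
            if lo <= years <= hi:
                return cut
        raise ValueError(f"age {age} outside table coverage 0-{AGE_MAX}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["age_min", "age_max", "cutoff"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "CutoffTable":
        df = pd.read_csv(path)
        entries = tuple((int(r.age_min), int(r.age_max), float(r.cutoff))
                        for r in df.itertuples())
        return cls(entries, provenance or Path(path).stem)


def published_table() -> CutoffTable:
    """The recommended triage-goal-optimized cutoffs (three AUC-selected bands)."""
    return CutoffTable(((0, 9, 13.3), (10, 14, 18.4), (15, 18, 20.9)),
                       provenance="published")


def classify(
    age: float,
    rsig: float | None = None,
    table: CutoffTable | None = None,
    sbp: float | None = None,
    hr: float | None = None,
    gcs: float | None = None,
) -> tuple[str, float]:
    """Classify one patient; returns ``("high" | "low", applied_cutoff)``.

    Either ``rsig`` or all of ``sbp``/``hr``/``gcs`` must be given (the
    score is then computed from the field vitals).  High risk iff rsig is
    strictly below the band cutoff.
    """
    if table is None:
        table = published_table()
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age must lie in [{AGE_MIN}, {AGE_MAX}], got {age}")
    if rsig is None:
        if sbp is None or hr is None or gcs is None:
            raise ValueError("provide rsig, or all of sbp, hr and gcs")
        rsig = compute_rsig(sbp, hr, gcs)
    if rsig <= 0:
        raise ValueError("rsig must be strictly positive")
    cutoff = table.lookup(age)
    return ("high" if rsig < cutoff else "low"), cutoff


def classify_frame(records: pd.DataFrame, table: CutoffTable | None = None) -> pd.DataFrame:
    """Batch classification: appends ``applied_cutoff`` and ``risk`` columns."""
    if table is None:
        table = published_table()
    out = records.copy()
    cutoffs = np.array([table.lookup(a) for a in out["age"]])
    out["applied_cutoff"] = cutoffs
    out["risk"] = np.where(out["rsig"].to_numpy(dtype=float) < cutoffs, "high", "low")
    return out
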