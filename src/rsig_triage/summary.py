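"""Descriptive cohort summaries (per-outcome medians and IQRs)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cohort_summary", "mortality_rate_pct"]

_VARS = ("sbp", "hr", "gcs", "rsig")


def mortality_rate_pct(n_deaths: int, n_total: int) -> float:
    """In-hospital mortality as a percentage rounded to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_deaths / n_total, 2)


def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation convention (numpy default)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome descriptive table of a cleaned cohort.

    One row per outcome stratum (survived / died) with n, median and IQR
    of SBP, HR, GCS and rSIG; a stratum absent from the data appears with
    n = 0 and missing statistics.  The frame's ``attrs`` carry the
    mortality rate in percent (two decimals).
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    rows = []
    for name, code in (("survived", 0), ("died", 1)):
        sub = records[records["outcome"] == code]
        row: dict = {"outcome": name, "n": len(sub)}
        for var in _VARS:
            if len(sub):
                med, q1, q3 = _quantiles(sub[var].to_numpy(dtype=float))
                row[f"{var}_median"], row[f"{var}_q1"], row[f"{var}_q3"] = med, q1, q3
            else:
                row[f"{var}_median"] = row[f"{var}_q1"] = row[f"{var}_q3"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["mortality_rate_pct"] = mortality_rate_pct(
        int((records["outcome"] == 1).sum()), len(records))
    return out
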