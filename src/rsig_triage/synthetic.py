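"""Seeded synthetic registry cohorts.

Real pediatric trauma registries are access-restricted, so every stage of
the cutoff analysis is exercised against generated cohorts that reproduce
the statistical structure the analysis relies on:

* age-dependent vital-sign reference levels (SBP rising, HR falling with
  age), which is what makes a single rSIG cutoff inappropriate across ages;
* outcome-conditional GCS and hence rSIG distributions — survivors alert
  and haemodynamically normal (rSIG median ~17), deaths comatose and
  shocked (rSIG median ~5);
* a configurable, typically rare, in-hospital mortality rate;
* optional missing / physiologically implausible vital contamination.

Two sampling modes are provided.  The default, outcome-first mode draws the
death label first and vitals conditional on it: calibration to published
per-stratum quantiles is then direct.  The latent-severity mode instead
assigns death probability through band-specific rSIG operating points, so
the true age-band structure is known and partition-search recovery can be
measured against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import (AGES, GCS_VALUES, MECHANISM_WEIGHTS, MECHANISMS,
                     GeneratorConfig)

__all__ = [
    "generate_cohort",
    "contaminate",
    "generate_latent_cohort",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

#: Documented CSV header of a raw cohort; missing vitals are empty fields.
COHORT_COLUMNS = ("age", "sex", "mechanism", "time_to_arrival_min",
                  "sbp", "hr", "gcs", "outcome")

_MALE_FRACTION = 0.67
_ARRIVAL_MEDIAN_SURVIVOR_MIN = 60.0
_ARRIVAL_MEDIAN_DEATH_MIN = 41.0
_ARRIVAL_LOG_SIGMA = 0.85  # lognormal spread giving IQR roughly (30, 94) min

# Generated vitals stay inside these bounds, so the plausibility filter
# downstream is exercised only by explicit contamination.
_SBP_BOUNDS = (40.0, 250.0)
_HR_BOUNDS = (40.0, 190.0)


def _survivor_medians(age: np.ndarray, config: GeneratorConfig):
    sbp0, sbp_slope = config.sbp_curve
    hr0, hr_slope, hr_floor = config.hr_curve
    sbp_med = sbp0 + sbp_slope * age
    hr_med = np.maximum(hr0 + hr_slope * age, hr_floor)
    return sbp_med, hr_med


def _truncated_normal(median: np.ndarray, cv: float, bounds: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    scale = cv * median
    a = (bounds[0] - median) / scale
    b = (bounds[1] - median) / scale
    return truncnorm.rvs(a, b, loc=median, scale=scale, random_state=rng)


def _sample_vitals(age: np.ndarray, died: np.ndarray, config: GeneratorConfig,
                   rng: np.random.Generator):
    sbp_med, hr_med = _survivor_medians(age, config)
    sbp_mult, hr_mult = config.death_shift
    sbp_med = np.where(died, sbp_med * sbp_mult, sbp_med)
    hr_med = np.where(died, np.minimum(hr_med * hr_mult, _HR_BOUNDS[1] - 10.0), hr_med)
    sbp = _truncated_normal(sbp_med, config.vital_cv, _SBP_BOUNDS, rng)
    hr = _truncated_normal(hr_med, config.vital_cv, _HR_BOUNDS, rng)
    return np.round(sbp), np.round(hr)


def _sample_gcs(died: np.ndarray, config: GeneratorConfig,
                rng: np.random.Generator) -> np.ndarray:
    n = died.size
    gcs = np.empty(n, dtype=np.int64)
    values = np.asarray(GCS_VALUES)
    for mask, pmf in ((died, config.gcs_death_pmf), (~died, config.gcs_survivor_pmf)):
        k = int(mask.sum())
        if k:
            gcs[mask] = rng.choice(values, size=k, p=np.asarray(pmf))
    return gcs


def _sample_frame(age, sex, mechanism, arrival, sbp, hr, gcs, outcome) -> pd.DataFrame:
    return pd.DataFrame({
        "age": age.astype(np.int64),
        "sex": sex,
        "mechanism": mechanism,
        "time_to_arrival_min": arrival,
        "sbp": sbp.astype(float),
        "hr": hr.astype(float),
        "gcs": gcs.astype(float),
        "outcome": outcome,
    })


def _common_demographics(n: int, config: GeneratorConfig, rng: np.random.Generator):
    age = rng.choice(np.asarray(AGES), size=n, p=np.asarray(config.age_weights))
    sex = np.where(rng.random(n) < _MALE_FRACTION, "male", "female")
    mechanism = rng.choice(np.asarray(MECHANISMS), size=n, p=np.asarray(MECHANISM_WEIGHTS))
    return age, sex, mechanism


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a raw registry cohort (outcome-first sampling).

    The death label is Bernoulli(``mortality_rate``); SBP/HR/GCS are then
    sampled conditional on outcome and age.  The same ``config`` (including
    ``seed``) always yields the identical DataFrame.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS`; vitals are
    floats so contamination can introduce missing values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    died = rng.random(n) < config.mortality_rate
    age, sex, mechanism = _common_demographics(n, config, rng)

    med = np.where(died, _ARRIVAL_MEDIAN_DEATH_MIN, _ARRIVAL_MEDIAN_SURVIVOR_MIN)
    arrival = np.round(np.exp(np.log(med) + _ARRIVAL_LOG_SIGMA * rng.standard_normal(n)))

    sbp, hr = _sample_vitals(age, died, config, rng)
    gcs = _sample_gcs(died, config, rng)
    outcome = np.where(died, "died", "survived")
    return _sample_frame(age, sex, mechanism, arrival, sbp, hr, gcs, outcome)


def contaminate(records: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Inject missing and implausible vitals into a raw cohort.

    Each of SBP, HR and GCS is independently set missing with
    ``missing_rate`` or replaced with an out-of-range value with
    ``implausible_rate`` (SBP outside [30, 300] mmHg, HR outside
    [30, 200] bpm, GCS outside [3, 15]); the two events are mutually
    exclusive per field.  The input frame is not modified.
    """
    config.validate()
    out = records.copy()
    if config.missing_rate == 0.0 and config.implausible_rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    n = len(out)

    def _implausible(low_pool, high_pool, size):
        low = rng.uniform(*low_pool, size=size)
        high = rng.uniform(*high_pool, size=size)
        return np.round(np.where(rng.random(size) < 0.5, low, high))

    pools = {
        "sbp": ((0.0, 29.0), (301.0, 400.0)),
        "hr": ((0.0, 29.0), (201.0, 300.0)),
        "gcs": ((0.0, 2.0), (16.0, 20.0)),
    }
    for col, (low_pool, high_pool) in pools.items():
        u = rng.random(n)
        miss = u < config.missing_rate
        bad = (~miss) & (u < config.missing_rate + config.implausible_rate)
        vals = out[col].to_numpy(dtype=float, copy=True)
        vals[miss] = np.nan
        k = int(bad.sum())
        if k:
            vals[bad] = _implausible(low_pool, high_pool, k)
        out[col] = vals
    return out


def _solve_intercept(offset: np.ndarray, target_rate: float) -> float:
    """Bisect c so that mean(expit(c + offset)) equals target_rate."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + offset))) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_latent_cohort(
    config: GeneratorConfig,
    boundaries: tuple[int, int] = (6, 12),
    risk_thresholds: tuple[float, ...] = (12.0, 17.0, 22.0),
    event_rate: float = 0.02,
    slope: float = 0.9,
) -> pd.DataFrame:
    """Draw a cohort whose mortality risk follows known age-band thresholds.

    All patients receive survivor-model vitals and GCS; death probability is
    ``expit(c + slope * (threshold_band - rSIG))`` where ``threshold_band``
    is the rSIG operating point of the patient's true age band (bands end at
    ``boundaries`` inclusive) and ``c`` is solved so the cohort event rate
    equals ``event_rate``.  The risk-vs-rSIG curve therefore jumps at the
    true boundaries, which is the structure the age-partition search is
    asked to recover.
    """
    config.validate()
    if len(risk_thresholds) != len(boundaries) + 1:
        raise ValueError("need one risk threshold per band")
    if not 0.0 < event_rate < 1.0:
        raise ValueError("event_rate must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A]))
    n = config.n_patients

    age, sex, mechanism = _common_demographics(n, config, rng)
    arrival = np.round(np.exp(np.log(_ARRIVAL_MEDIAN_SURVIVOR_MIN)
                              + _ARRIVAL_LOG_SIGMA * rng.standard_normal(n)))
    died0 = np.zeros(n, dtype=bool)
    sbp, hr = _sample_vitals(age, died0, config, rng)
    gcs = _sample_gcs(died0, config, rng)
    rsig = sbp / hr * gcs

    edges = np.asarray([-1, *boundaries, 18])
    band = np.searchsorted(edges, age, side="left") - 1
    offset = slope * (np.asarray(risk_thresholds)[band] - rsig)
    c = _solve_intercept(offset, event_rate)
    died = rng.random(n) < expit(c + offset)
    outcome = np.where(died, "died", "survived")
    return _sample_frame(age, sex, mechanism, arrival, sbp, hr, gcs, outcome)


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    """Write a cohort in the documented CSV dialect (missing = empty field)."""
    records.to_csv(path, index=False, columns=list(COHORT_COLUMNS))
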