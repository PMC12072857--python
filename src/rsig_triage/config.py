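"""Configuration for the synthetic registry generator.

The generator emulates a national emergency-department injury registry:
one row per pediatric trauma patient (age 0-18 completed years) with
arrival vitals (SBP, HR), Glasgow Coma Scale, and an in-hospital outcome.
Vitals are sampled conditional on outcome and age; deaths are rare.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

AGES = tuple(range(19))  #: integer ages covered by the registry, completed years
GCS_VALUES = tuple(range(3, 16))  #: admissible Glasgow Coma Scale scores

#: Injury mechanisms emitted by the generator with survivor-cohort frequencies.
MECHANISMS = ("traffic accident", "fall", "blunt", "penetrating", "other")
MECHANISM_WEIGHTS = (0.142, 0.390, 0.369, 0.098, 0.001)


def _default_age_weights() -> tuple[float, ...]:
    # Mildly front-loaded: toddlers over-represented relative to adolescents,
    # giving a cohort median age in the high single digits.
    raw = [1.2] * 7 + [1.0] * 6 + [0.8] * 6
    total = sum(raw)
    return tuple(w / total for w in raw)


def _default_gcs_survivor_pmf() -> tuple[float, ...]:
    # Survivors are overwhelmingly alert: median and both quartiles at 15.
    pmf = [0.002] * 10 + [0.01, 0.02, 0.95]  # GCS 3..12, 13, 14, 15
    return tuple(pmf)


def _default_gcs_death_pmf() -> tuple[float, ...]:
    # Deaths concentrate at deep coma: median 4, quartiles (3, 8).
    #        GCS:   3     4     5     6     7     8     9    10    11    12    13    14    15
    pmf = (0.30, 0.22, 0.08, 0.07, 0.06, 0.05, 0.05, 0.04, 0.03, 0.03, 0.03, 0.02, 0.02)
    return pmf


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic registry cohort.

    Attributes
    ----------
    n_patients:
        Number of raw records to draw.
    mortality_rate:
        Marginal in-hospital death probability (outcome is sampled first).
    age_weights:
        19 nonnegative weights over integer ages 0-18; normalized to sum to 1.
    sbp_curve:
        ``(intercept, slope)`` in mmHg: median survivor SBP at age ``a`` is
        ``intercept + slope * a`` (the standard pediatric reference formula
        90 + 2*age by default).
    hr_curve:
        ``(intercept, slope, floor)`` in bpm: median survivor HR is
        ``max(intercept + slope * a, floor)``.
    vital_cv:
        Coefficient of variation of SBP and HR around their age medians.
    death_shift:
        ``(sbp_multiplier, hr_multiplier)`` applied to the death stratum's
        vital medians (hypotension and tachycardia relative to survivors).
    gcs_death_pmf, gcs_survivor_pmf:
        Probability mass over GCS 3-15 per outcome stratum.
    missing_rate, implausible_rate:
        Per-field contamination probabilities used by :func:`contaminate`.
    seed:
        Seeds every random draw; identical config implies identical cohort.
    """

    n_patients: int = 100_000
    mortality_rate: float = 0.0007
    age_weights: tuple[float, ...] = field(default_factory=_default_age_weights)
    sbp_curve: tuple[float, float] = (90.0, 2.0)
    hr_curve: tuple[float, float, float] = (130.0, -4.0, 70.0)
    vital_cv: float = 0.12
    death_shift: tuple[float, float] = (0.90, 1.15)
    gcs_death_pmf: tuple[float, ...] = field(default_factory=_default_gcs_death_pmf)
    gcs_survivor_pmf: tuple[float, ...] = field(default_factory=_default_gcs_survivor_pmf)
    missing_rate: float = 0.0
    implausible_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 < self.mortality_rate < 1.0:
            raise ValueError(f"mortality_rate must lie in (0, 1), got {self.mortality_rate}")
        if len(self.age_weights) != len(AGES):
            raise ValueError(f"age_weights must have {len(AGES)} entries")
        if any(w < 0 for w in self.age_weights):
            raise ValueError("age_weights must be nonnegative")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise ValueError("age_weights must sum to 1 within 1e-9")
        for name, pmf in (("gcs_death_pmf", self.gcs_death_pmf),
                          ("gcs_survivor_pmf", self.gcs_survivor_pmf)):
            if len(pmf) != len(GCS_VALUES):
                raise ValueError(f"{name} must have {len(GCS_VALUES)} entries (GCS 3-15)")
            if any(p < 0 for p in pmf):
                raise ValueError(f"{name} must be nonnegative")
            if abs(sum(pmf) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        for name, rate in (("missing_rate", self.missing_rate),
                           ("implausible_rate", self.implausible_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.missing_rate + self.implausible_rate > 1.0:
            raise ValueError("missing_rate + implausible_rate must not exceed 1 per field")
        if self.vital_cv <= 0:
            raise ValueError("vital_cv must be positive")
        sbp_mult, hr_mult = self.death_shift
        if not (0 < sbp_mult < 1):
            raise ValueError("death_shift SBP multiplier must lie in (0, 1)")
        if hr_mult <= 1:
            raise ValueError("death_shift HR multiplier must exceed 1")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GeneratorConfig":
        kwargs = dict(mapping)
        for key in ("age_weights", "sbp_curve", "hr_curve", "death_shift",
                    "gcs_death_pmf", "gcs_survivor_pmf"):
            if key in kwargs and isinstance(kwargs[key], Sequence):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a flat YAML or JSON key-value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)
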