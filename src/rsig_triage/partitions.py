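"""Exhaustive search over contiguous age partitions.

Because pediatric vital-sign reference ranges drift with age, a single
rSIG cutoff cannot serve all of 0-18 years.  The search enumerates every
contiguous partition of the integer ages 0-18 into two or three bands and
scores each partition with a logistic regression of in-hospital death on
rSIG that has a separate intercept and slope per band (2k parameters for
k bands).  Lower AIC means a better fit; the AUC of the fitted
probabilities measures discrimination.  Both criteria are reported and the
best partition under each is selected.

Per-band fits use Newton/IRLS (relative log-likelihood tolerance 1e-8,
at most 100 iterations).  A band whose deaths and survivors are perfectly
(or quasi-) separated on rSIG has no finite maximum-likelihood estimate;
such bands fall back to a Firth-penalized fit and the score is flagged.
A band with only one outcome class cannot be scored at all and marks the
partition unevaluable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import fit_logistic_1d

__all__ = [
    "AgePartition",
    "PartitionScore",
    "enumerate_partitions",
    "score_partition",
    "score_all_partitions",
    "select_best",
    "heatmap_matrix",
]

AGE_MIN, AGE_MAX = 0, 18


@dataclass(frozen=True)
class AgePartition:
    """Contiguous bands of integer ages covering 0-18, inclusive ends."""

    bands: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.bands) not in (2, 3):
            raise ValueError("a partition must have 2 or 3 bands")
        expected_lo = AGE_MIN
        for lo, hi in self.bands:
            if lo != expected_lo or hi < lo:
                raise ValueError(f"bands must be contiguous and ordered: {self.bands}")
            expected_lo = hi + 1
        if self.bands[-1][1] != AGE_MAX:
            raise ValueError(f"bands must cover ages {AGE_MIN}-{AGE_MAX}: {self.bands}")

    @property
    def k(self) -> int:
        return len(self.bands)

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Last age of each band except the final one."""
        return tuple(hi for _, hi in self.bands[:-1])

    @classmethod
    def from_boundaries(cls, boundaries: tuple[int, ...]) -> "AgePartition":
        lows = (AGE_MIN, *(b + 1 for b in boundaries))
        highs = (*boundaries, AGE_MAX)
        return cls(tuple(zip(lows, highs)))

    def band_index(self, age) -> np.ndarray:
        """Band membership (0-based) for integer ages; -1 outside 0-18."""
        age = np.asarray(age)
        edges = np.asarray([lo for lo, _ in self.bands] + [AGE_MAX + 1])
        idx = np.searchsorted(edges, age, side="right") - 1
        idx = np.where((age < AGE_MIN) | (age > AGE_MAX), -1, idx)
        return idx

    def label(self) -> str:
        return " / ".join(f"{lo}-{hi}" for lo, hi in self.bands)


@dataclass(frozen=True)
class PartitionScore:
    partition: AgePartition
    aic: float
    auc: float
    log_likelihood: float
    n_per_band: tuple[int, ...]
    deaths_per_band: tuple[int, ...]
    evaluable: bool
    penalized_bands: tuple[int, ...] = ()


def enumerate_partitions(k: int) -> list[AgePartition]:
    """All contiguous k-band partitions of ages 0-18, lexicographic by boundary.

    There are 18 two-band partitions (one internal boundary among ages
    0..17) and C(18, 2) = 153 three-band partitions.
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    return [AgePartition.from_boundaries(bs)
            for bs in combinations(range(AGE_MIN, AGE_MAX), k - 1)]


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney AUC of a higher-is-positive score.
    from .cutoffs import mann_whitney_auc
    return mann_whitney_auc(scores, labels, higher_is_positive=True)


def score_partition(records: pd.DataFrame, partition: AgePartition) -> PartitionScore:
    """Fit the band-specific logistic model and report AIC and AUC.

    ``records`` is a cleaned analysis frame (columns ``age``, ``rsig``,
    ``outcome`` with outcome 1 = death).  AIC is ``2 * 2k - 2 * llf``; the
    AUC is the rank-based AUC of fitted death probabilities.  If any band
    lacks deaths or survivors the score is returned with ``evaluable``
    False and NaN metrics.
    """
    age = records["age"].to_numpy()
    rsig = records["rsig"].to_numpy(dtype=float)
    y = records["outcome"].to_numpy(dtype=float)
    band = partition.band_index(age)
    if np.any(band < 0):
        raise ValueError("records contain ages outside 0-18; clean first")

    n_per_band, deaths_per_band = [], []
    llf = 0.0
    fitted = np.empty_like(rsig)
    penalized = []
    evaluable = True
    for b in range(partition.k):
        mask = band == b
        yb = y[mask]
        xb = rsig[mask]
        n_per_band.append(int(mask.sum()))
        deaths_per_band.append(int(yb.sum()))
        if yb.size == 0 or yb.sum() == 0 or yb.sum() == yb.size:
            evaluable = False
            continue
        fit = fit_logistic_1d(xb, yb)
        llf += fit.llf
        fitted[mask] = expit(fit.beta[0] + fit.beta[1] * xb)
        if fit.penalized:
            penalized.append(b)
    if not evaluable:
        return PartitionScore(partition, float("nan"), float("nan"), float("nan"),
                              tuple(n_per_band), tuple(deaths_per_band), False)
    aic = 2.0 * (2 * partition.k) - 2.0 * llf
    auc = _rank_auc(fitted, y.astype(np.int64))
    return PartitionScore(partition, aic, auc, llf, tuple(n_per_band),
                          tuple(deaths_per_band), True, tuple(penalized))


def score_all_partitions(records: pd.DataFrame, k: int) -> list[PartitionScore]:
    return [score_partition(records, p) for p in enumerate_partitions(k)]


def select_best(scores: list[PartitionScore]) -> tuple[AgePartition, AgePartition]:
    """(lowest-AIC partition, highest-AUC partition) among evaluable scores.

    Ties resolve to the earliest partition in enumeration order, which is
    the input order produced by :func:`score_all_partitions`.
    """
    evaluable = [s for s in scores if s.evaluable]
    if not evaluable:
        raise ValueError("no evaluable partition scores")
    by_aic = min(evaluable, key=lambda s: s.aic).partition
    by_auc = max(evaluable, key=lambda s: s.auc).partition
    return by_aic, by_auc


def heatmap_matrix(scores: list[PartitionScore], metric: str) -> pd.DataFrame:
    """Boundary-indexed matrix of a partition metric, for heatmap export.

    Three-band scores fill a strictly upper-triangular 18x18 matrix indexed
    by (first boundary age, second boundary age); two-band scores fill a
    single row indexed by the boundary age.  Cells outside the domain are
    NaN; unevaluable partitions are also NaN (their occupancy can be told
    apart by the returned frame's attrs["unevaluable"] list).
    """
    if metric not in ("aic", "auc"):
        raise ValueError(f"metric must be 'aic' or 'auc', got {metric!r}")
    ks = {s.partition.k for s in scores}
    if len(ks) != 1:
        raise ValueError("scores must all come from the same k")
    k = ks.pop()
    bounds = list(range(AGE_MIN, AGE_MAX))  # 0..17
    unevaluable = []
    if k == 2:
        mat = pd.DataFrame(np.nan, index=["cutpoint"], columns=bounds)
        for s in scores:
            (b1,) = s.partition.boundaries
            mat.loc["cutpoint", b1] = getattr(s, metric)
            if not s.evaluable:
                unevaluable.append((b1,))
    else:
        mat = pd.DataFrame(np.nan, index=bounds, columns=bounds)
        for s in scores:
            b1, b2 = s.partition.boundaries
            mat.loc[b1, b2] = getattr(s, metric)
            if not s.evaluable:
                unevaluable.append((b1, b2))
    mat.attrs["unevaluable"] = unevaluable
    mat.index.name = "first_boundary_age"
    mat.columns.name = "second_boundary_age" if k == 3 else "boundary_age"
    return mat
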