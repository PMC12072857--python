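"""Cutoff derivation: ROC/Youden analysis and triage-goal optimization.

rSIG is a low-is-sick score, so throughout this module a patient is
test-positive (flagged high risk) iff their rSIG is *strictly below* the
cutoff; a patient exactly at the cutoff is not flagged.  Two cutoff
derivations are offered per age band:

* **Youden** — the cutoff maximizing sensitivity + specificity - 1 over
  thresholds placed at midpoints between consecutive distinct observed
  rSIG values (observed-value resolution, not a fixed grid);
* **triage-goal optimization** — a 0.1-unit grid sweep minimizing the
  summed exceedance of the field-triage targets: under-triage (the
  false-negative rate) below 5% and over-triage (the false-positive rate)
  below 35%.  Ties resolve to the lowest combined under- plus over-triage
  rate, then to the smallest cutoff.

The overall discrimination of a deployed cutoff table (a dichotomized
predictor) is the binary-classifier AUC (sensitivity + specificity) / 2,
with a stratified percentile-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .partitions import AgePartition

__all__ = [
    "RocCurve",
    "CutoffResult",
    "TriageRates",
    "build_roc",
    "mann_whitney_auc",
    "empirical_auc",
    "binary_classifier_auc",
    "youden_cutoff",
    "triage_rates",
    "optimize_triage_cutoff",
    "combined_evaluation",
    "bootstrap_auc_ci",
]

UNDER_TRIAGE_GOAL_PCT = 5.0   #: ACS target: under-triage below 5%
OVER_TRIAGE_GOAL_PCT = 35.0   #: ACS target: over-triage below 35%
DEFAULT_STEP = 0.1


@dataclass(frozen=True)
class RocCurve:
    """Operating points of the lower-is-positive rSIG test.

    ``thresholds`` run from -inf to +inf; at threshold t a case is positive
    iff score < t, so sensitivity is non-decreasing and specificity
    non-increasing in t.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass(frozen=True)
class TriageRates:
    """Under-triage = 100*(1 - sensitivity); over-triage = 100*(1 - specificity)."""

    under_triage_pct: float
    over_triage_pct: float


@dataclass(frozen=True)
class CutoffResult:
    band: tuple[int, int] | None
    cutoff: float
    method: str  # "youden" | "triage_optimized"
    sensitivity: float
    specificity: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    youden_index: float | None = None

    @property
    def triage(self) -> TriageRates:
        return TriageRates(100.0 * (1.0 - self.sensitivity),
                           100.0 * (1.0 - self.specificity))


def _check_two_classes(labels: np.ndarray) -> None:
    pos = int(labels.sum())
    if pos == 0 or pos == labels.size:
        raise ValueError("both outcome classes must be present")


def build_roc(scores, labels) -> RocCurve:
    """ROC of the lower-is-positive test at observed-value resolution.

    Thresholds are the midpoints between consecutive distinct observed
    scores plus -inf/+inf sentinels, so every achievable confusion matrix
    appears exactly once.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    # positive iff score < t: count of class members strictly below t
    sens = np.searchsorted(pos_sorted, thresholds, side="left") / pos_sorted.size
    fpr = np.searchsorted(neg_sorted, thresholds, side="left") / neg_sorted.size
    return RocCurve(thresholds, sens, 1.0 - fpr)


def mann_whitney_auc(scores, labels, higher_is_positive: bool) -> float:
    """Rank-based AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)
    r1 = float(ranks[labels == 1].sum())
    # U counts pairs where the positive case scores higher (ties half)
    u = r1 - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return auc if higher_is_positive else 1.0 - auc


def empirical_auc(scores, labels) -> float:
    """AUC of rSIG for death: P(random death scores below a random survivor),
    ties counted one half.  Equals the trapezoidal area under the
    lower-is-positive ROC polygon."""
    return mann_whitney_auc(scores, labels, higher_is_positive=False)


def binary_classifier_auc(sens: float, spec: float) -> float:
    """AUC of a dichotomized predictor: (sensitivity + specificity) / 2."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sens + spec) / 2.0


def youden_cutoff(roc: RocCurve, band: tuple[int, int] | None = None) -> CutoffResult:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Ties resolve to the smaller cutoff (fewer patients flagged).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    i = int(np.argmax(j))  # argmax takes the first (= smallest threshold) tie
    return CutoffResult(band=band, cutoff=float(roc.thresholds[i]), method="youden",
                        sensitivity=float(roc.sensitivity[i]),
                        specificity=float(roc.specificity[i]),
                        youden_index=float(j[i]))


def triage_rates(scores, labels, cutoff: float) -> TriageRates:
    """Under-/over-triage of the rule "high risk iff rSIG < cutoff", in percent."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    under = 100.0 * float((pos >= cutoff).mean())
    over = 100.0 * float((neg < cutoff).mean())
    return TriageRates(under, over)


def _grid(scores: np.ndarray, step: float) -> np.ndarray:
    lo = np.floor(scores.min())
    hi = np.ceil(scores.max()) + step
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def optimize_triage_cutoff(
    scores,
    labels,
    step: float = DEFAULT_STEP,
    under_goal: float = UNDER_TRIAGE_GOAL_PCT,
    over_goal: float = OVER_TRIAGE_GOAL_PCT,
    band: tuple[int, int] | None = None,
) -> CutoffResult:
    """Sweep cutoffs on a ``step`` grid and minimize triage-goal exceedance.

    The objective at cutoff c is
    ``max(UT(c) - under_goal, 0) + max(OT(c) - over_goal, 0)``; among
    minimizers the one with the lowest UT(c) + OT(c) wins, and any
    remaining tie goes to the smallest cutoff.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    grid = _grid(scores, step)
    pos_sorted = np.sort(scores[labels == 1])
    neg_sorted = np.sort(scores[labels == 0])
    n_flagged_pos = np.searchsorted(pos_sorted, grid, side="left")
    n_flagged_neg = np.searchsorted(neg_sorted, grid, side="left")
    # exact count ratios: a rate equal to its goal must not register as
    # exceedance through floating-point round-off
    under = 100.0 * (pos_sorted.size - n_flagged_pos) / pos_sorted.size
    over = 100.0 * n_flagged_neg / neg_sorted.size
    sens = n_flagged_pos / pos_sorted.size
    fpr = n_flagged_neg / neg_sorted.size
    objective = np.maximum(under - under_goal, 0.0) + np.maximum(over - over_goal, 0.0)
    best = objective == objective.min()
    summed = under + over
    best &= summed == summed[best].min()
    i = int(np.flatnonzero(best)[0])  # smallest cutoff among remaining ties
    return CutoffResult(band=band, cutoff=float(grid[i]), method="triage_optimized",
                        sensitivity=float(sens[i]), specificity=float(1.0 - fpr[i]))


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                     statistic="auc") -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the continuous rSIG AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    stats = np.empty(n_boot)
    lab = np.concatenate([np.ones(pos.size, dtype=np.int64),
                          np.zeros(neg.size, dtype=np.int64)])
    for b in range(n_boot):
        sample = np.concatenate([rng.choice(pos, pos.size, replace=True),
                                 rng.choice(neg, neg.size, replace=True)])
        stats[b] = empirical_auc(sample, lab)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def combined_evaluation(
    records: pd.DataFrame,
    partition: AgePartition,
    cutoffs: tuple[float, ...],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[TriageRates, float, tuple[float, float]]:
    """Pooled performance of per-band cutoffs over the whole age range.

    Each record is classified high-risk iff its rSIG falls below its own
    band's cutoff; under-/over-triage are pooled over all records, and the
    overall AUC is the binary-classifier AUC of the pooled sensitivity and
    specificity, with a stratified percentile-bootstrap 95% CI (deaths and
    survivors resampled separately).
    """
    if len(cutoffs) != partition.k:
        raise ValueError("need exactly one cutoff per band")
    band = partition.band_index(records["age"].to_numpy())
    if np.any(band < 0):
        raise ValueError("record age outside all bands")
    rsig = records["rsig"].to_numpy(dtype=float)
    y = records["outcome"].to_numpy(dtype=np.int64)
    _check_two_classes(y)
    flagged = rsig < np.asarray(cutoffs, dtype=float)[band]

    pos, neg = flagged[y == 1], flagged[y == 0]
    sens = float(pos.mean())
    spec = float(1.0 - neg.mean())
    rates = TriageRates(100.0 * (1.0 - sens), 100.0 * (1.0 - spec))
    auc = binary_classifier_auc(sens, spec)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        s = rng.choice(pos, pos.size, replace=True).mean()
        f = rng.choice(neg, neg.size, replace=True).mean()
        boots[b] = binary_classifier_auc(float(s), float(1.0 - f))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return rates, auc, (float(lo), float(hi))
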