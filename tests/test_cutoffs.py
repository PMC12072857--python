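"""ROC construction, Youden and triage-optimized cutoffs vs exhaustive oracles."""

import numpy as np
import pandas as pd
import pytest

from rsig_triage import (AgePartition, binary_classifier_auc, build_roc,
                         combined_evaluation, empirical_auc,
                         optimize_triage_cutoff, triage_rates, youden_cutoff)
from rsig_triage.cutoffs import bootstrap_auc_ci

from conftest import random_scores_labels

# ---------------------------------------------------------------------------
# independent oracles: direct confusion-matrix enumeration, trapezoid area,
# and full-grid objective scans
# ---------------------------------------------------------------------------


def oracle_rates(scores, labels, cutoff):
    """Hand-counted confusion matrix of the rule: positive iff score < cutoff."""
    tp = fn = fp = tn = 0
    for s, y in zip(scores, labels):
        flagged = s < cutoff
        if y == 1:
            tp, fn = tp + flagged, fn + (not flagged)
        else:
            fp, tn = fp + flagged, tn + (not flagged)
    return 100.0 * fn / (tp + fn), 100.0 * fp / (fp + tn)


def oracle_youden(scores, labels):
    """Best (smallest) cutoff over every achievable threshold, by brute force."""
    uniq = np.unique(scores)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best_j, best_c = -np.inf, None
    for c in cands:
        ut, ot = oracle_rates(scores, labels, c)
        j = (1 - ut / 100) + (1 - ot / 100) - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_c, best_j


def oracle_triage_optimum(scores, labels, step, under_goal, over_goal):
    lo = np.floor(scores.min())
    hi = np.ceil(scores.max()) + step
    n = int(round((hi - lo) / step)) + 1
    best = None
    for c in np.round(lo + step * np.arange(n), 10):
        ut, ot = oracle_rates(scores, labels, c)
        key = (max(ut - under_goal, 0) + max(ot - over_goal, 0), ut + ot, c)
        if best is None or key < best:
            best = key
    return best[2]


def oracle_trapezoid_auc(scores, labels):
    roc = build_roc(scores, labels)
    fpr = 1.0 - roc.specificity
    return float(np.trapezoid(roc.sensitivity, fpr))


# ---------------------------------------------------------------------------


class TestBuildRoc:
    def test_separable_has_perfect_operating_point(self):
        roc = build_roc([1, 2, 10, 11], [1, 1, 0, 0])
        assert np.any((roc.sensitivity == 1.0) & (roc.specificity == 1.0))

    def test_endpoints(self):
        roc = build_roc([5, 6, 7, 8], [1, 0, 1, 0])
        assert roc.sensitivity[0] == 0.0 and roc.specificity[0] == 1.0
        assert roc.sensitivity[-1] == 1.0 and roc.specificity[-1] == 0.0

    def test_all_equal_scores_only_sentinels(self):
        roc = build_roc([5, 5, 5], [1, 0, 1])
        assert list(roc.thresholds) == [-np.inf, np.inf]
        assert list(zip(roc.sensitivity, roc.specificity)) == [(0.0, 1.0), (1.0, 0.0)]

    def test_monotone_operating_points(self, rng):
        scores, labels = random_scores_labels(rng, 200)
        roc = build_roc(scores, labels)
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(roc.specificity) <= 0)

    def test_six_point_set_matches_exhaustive_enumeration(self):
        scores = np.array([3.0, 5.0, 5.0, 8.0, 12.0, 20.0])
        labels = np.array([1, 1, 0, 1, 0, 0])
        roc = build_roc(scores, labels)
        for t, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            if np.isfinite(t):
                ut, ot = oracle_rates(scores, labels, t)
                assert sens == pytest.approx(1 - ut / 100)
                assert spec == pytest.approx(1 - ot / 100)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_roc([1, 2, 3], [1, 1, 1])


class TestEmpiricalAuc:
    def test_separable_is_one(self):
        assert empirical_auc([1, 2, 10, 11], [1, 1, 0, 0]) == 1.0

    def test_identical_distributions_half(self):
        assert empirical_auc([4, 4, 4, 4], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_equals_trapezoid_area(self, rng):
        for _ in range(50):
            scores, labels = random_scores_labels(rng, int(rng.integers(8, 60)))
            scores = np.round(scores, 1)  # force ties
            assert empirical_auc(scores, labels) == pytest.approx(
                oracle_trapezoid_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores, labels = random_scores_labels(rng, 100)
            assert empirical_auc(scores, labels) == pytest.approx(
                metrics.roc_auc_score(labels, -scores), abs=1e-12)


class TestBinaryClassifierAuc:
    @pytest.mark.parametrize("sens,spec,expected", [
        (1.0, 1.0, 1.0),
        (0.3, 0.7, 0.5),  # on the chance line
        (0.8, 0.2, 0.5),
    ])
    def test_closed_form(self, sens, spec, expected):
        assert binary_classifier_auc(sens, spec) == pytest.approx(expected)

    def test_equals_rank_auc_of_binary_indicator(self, rng):
        scores, labels = random_scores_labels(rng, 300)
        cutoff = 12.0
        flagged = (scores < cutoff).astype(float)
        rates = triage_rates(scores, labels, cutoff)
        sens = 1 - rates.under_triage_pct / 100
        spec = 1 - rates.over_triage_pct / 100
        # low indicator value (not flagged) means low risk: lower-is-positive
        assert binary_classifier_auc(sens, spec) == pytest.approx(
            empirical_auc(-flagged, labels), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binary_classifier_auc(1.2, 0.5)


class TestTriageRates:
    def test_cutoff_below_all_scores(self):
        r = triage_rates([5, 6, 7, 8], [1, 0, 1, 0], cutoff=1.0)
        assert r.under_triage_pct == 100.0 and r.over_triage_pct == 0.0

    def test_cutoff_above_all_scores(self):
        r = triage_rates([5, 6, 7, 8], [1, 0, 1, 0], cutoff=100.0)
        assert r.under_triage_pct == 0.0 and r.over_triage_pct == 100.0

    def test_eight_record_hand_count(self):
        scores = [2.0, 4.0, 9.0, 9.5, 10.0, 15.0, 18.0, 25.0]
        labels = [1, 1, 1, 0, 1, 0, 0, 0]
        r = triage_rates(scores, labels, cutoff=9.5)
        # deaths below 9.5: {2, 4, 9} of 4 -> UT 25%; survivors below: none of 4
        assert r.under_triage_pct == pytest.approx(25.0)
        assert r.over_triage_pct == pytest.approx(0.0)

    def test_at_cutoff_not_flagged(self):
        r = triage_rates([10.0, 20.0], [1, 0], cutoff=10.0)
        assert r.under_triage_pct == 100.0  # the death sits exactly at the cutoff

    def test_complement_identity(self, rng):
        scores, labels = random_scores_labels(rng, 150)
        for cutoff in np.percentile(scores, [10, 50, 90]):
            r = triage_rates(scores, labels, cutoff)
            ut, ot = oracle_rates(scores, labels, cutoff)
            assert r.under_triage_pct == pytest.approx(ut)
            assert r.over_triage_pct == pytest.approx(ot)


class TestYoudenCutoff:
    def test_perfect_separation_index_one(self):
        res = youden_cutoff(build_roc([1, 2, 10, 11], [1, 1, 0, 0]))
        assert res.youden_index == pytest.approx(1.0)
        assert 2 < res.cutoff < 10

    def test_null_scores_index_near_zero(self, rng):
        scores = rng.normal(10, 3, 2000)
        labels = (rng.random(2000) < 0.3).astype(int)
        res = youden_cutoff(build_roc(scores, labels))
        assert res.youden_index < 0.12

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            scores, labels = random_scores_labels(rng, 50)
            scores = np.round(scores, 1)
            res = youden_cutoff(build_roc(scores, labels))
            c, j = oracle_youden(scores, labels)
            assert res.youden_index == pytest.approx(j, abs=1e-12)
            assert res.cutoff == pytest.approx(c)


class TestOptimizeTriageCutoff:
    def test_feasible_case_zero_objective(self, rng):
        scores, labels = random_scores_labels(rng, 400, signal=2.0)
        res = optimize_triage_cutoff(scores, labels)
        r = res.triage
        assert max(r.under_triage_pct - 5, 0) + max(r.over_triage_pct - 35, 0) == 0

    def test_matches_grid_oracle(self, rng):
        for _ in range(30):
            scores, labels = random_scores_labels(rng, int(rng.integers(10, 80)))
            res = optimize_triage_cutoff(scores, labels)
            assert res.cutoff == pytest.approx(
                oracle_triage_optimum(scores, labels, 0.1, 5, 35))

    def test_tie_breaks_to_lowest_summed_rates(self):
        # deaths all below 4, survivors all above 30: every grid cutoff in
        # (4, 30] achieves UT=0, OT=0; the tie then goes to the smallest cutoff
        scores = np.array([2.0, 3.0, 30.0, 31.0, 40.0])
        labels = np.array([1, 1, 0, 0, 0])
        res = optimize_triage_cutoff(scores, labels)
        ut, ot = oracle_rates(scores, labels, res.cutoff)
        assert (ut, ot) == (0.0, 0.0)
        assert res.cutoff == pytest.approx(3.1)  # smallest zero-objective gridpoint

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            optimize_triage_cutoff([1, 2, 3], [1, 0, 0], step=0.0)


class TestCombinedEvaluation:
    def _clean(self, rng, n=4000):
        age = rng.integers(0, 19, n)
        y = (rng.random(n) < 0.08).astype(np.int64)
        rsig = np.where(y == 1, rng.normal(6 + 0.2 * age, 2),
                        rng.normal(14 + 0.5 * age, 3))
        return pd.DataFrame({"age": age, "rsig": np.abs(rsig) + 0.1, "outcome": y})

    def test_identical_cutoffs_reduce_to_single_group(self, rng):
        df = self._clean(rng)
        part = AgePartition.from_boundaries((6, 12))
        rates, auc, _ = combined_evaluation(df, part, (12.0, 12.0, 12.0), n_boot=50)
        single = triage_rates(df["rsig"], df["outcome"], 12.0)
        assert rates.under_triage_pct == pytest.approx(single.under_triage_pct, abs=1e-12)
        assert rates.over_triage_pct == pytest.approx(single.over_triage_pct, abs=1e-12)
        assert auc == pytest.approx(
            binary_classifier_auc(1 - single.under_triage_pct / 100,
                                  1 - single.over_triage_pct / 100), abs=1e-12)

    def test_pooled_under_triage_is_death_weighted_band_mean(self, rng):
        df = self._clean(rng)
        part = AgePartition.from_boundaries((6, 12))
        cuts = (10.0, 14.0, 18.0)
        rates, _, _ = combined_evaluation(df, part, cuts, n_boot=50)
        total_deaths = weighted = 0
        for (lo, hi), c in zip(part.bands, cuts):
            sub = df[(df["age"] >= lo) & (df["age"] <= hi)]
            deaths = int(sub["outcome"].sum())
            band_rates = triage_rates(sub["rsig"], sub["outcome"], c)
            weighted += deaths * band_rates.under_triage_pct
            total_deaths += deaths
        assert rates.under_triage_pct == pytest.approx(weighted / total_deaths)

    def test_cutoff_count_must_match_bands(self, rng):
        with pytest.raises(ValueError):
            combined_evaluation(self._clean(rng),
                                AgePartition.from_boundaries((6, 12)), (10.0, 14.0))

    def test_ci_brackets_estimate(self, rng):
        df = self._clean(rng)
        part = AgePartition.from_boundaries((9,))
        rates, auc, (lo, hi) = combined_evaluation(df, part, (12.0, 16.0),
                                                   n_boot=200, seed=5)
        assert lo <= auc <= hi
        assert hi - lo < 0.2


class TestBootstrapCi:
    def test_deterministic_under_seed(self, rng):
        scores, labels = random_scores_labels(rng, 300)
        a = bootstrap_auc_ci(scores, labels, n_boot=100, seed=3)
        b = bootstrap_auc_ci(scores, labels, n_boot=100, seed=3)
        assert a == b

    def test_brackets_point_estimate(self, rng):
        scores, labels = random_scores_labels(rng, 500)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=200, seed=1)
        assert lo <= empirical_auc(scores, labels) <= hi
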