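import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tops.metrics import (
    aggregate_folds,
    auc,
    calibration,
    concordance_index,
    cross_validate,
    sensitivity_at_specificity,
    specificity_at_sensitivity,
)
from tops.synthetic import generate_cohort, scenario_single_split


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration: 1 if positive above, 1/2 for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def brute_force_cindex(scores, times, events):
    """Harrell comparability: shorter time must be an event; equal times
    with both events count 1/2."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                den += 1
                num += (
                    1.0 if scores[i] > scores[j]
                    else 0.5 if scores[i] == scores[j] else 0.0
                )
            elif j > i and times[i] == times[j] and events[i] == events[j] == 1:
                den += 1
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestAUC:
    def test_worked_four_point_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            auc([0.1, 0.2], [1, 1])

    @given(
        st.lists(
            st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), st.integers(0, 1)),
            min_size=4,
            max_size=30,
        ).filter(lambda r: len({l for _, l in r}) == 2)
    )
    def test_matches_pair_enumeration(self, rows):
        scores = [s for s, _ in rows]
        labels = [l for _, l in rows]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        s = rng.choice([0.1, 0.3, 0.5, 0.9], 200)
        y = rng.integers(0, 2, 200)
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestConcordance:
    def test_worked_censored_example(self):
        # 4 comparable pairs, 3 concordant
        assert concordance_index(
            [0.9, 0.2, 0.5, 0.6], [2, 4, 3, 5], [1, 1, 0, 1]
        ) == 0.75

    def test_perfect_ranking_no_censoring(self):
        assert concordance_index([0.9, 0.6, 0.3], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="no comparable pairs"):
            concordance_index([0.5, 0.6], [1, 2], [0, 0])

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([0.1, 0.3, 0.5, 0.7]),
                st.integers(1, 8),
                st.integers(0, 1),
            ),
            min_size=3,
            max_size=25,
        )
    )
    def test_matches_pair_enumeration(self, rows):
        s = [r[0] for r in rows]
        t = [float(r[1]) for r in rows]
        e = [r[2] for r in rows]
        try:
            expected = brute_force_cindex(s, t, e)
        except ValueError:
            with pytest.raises(ValueError):
                concordance_index(s, t, e)
            return
        assert concordance_index(s, t, e) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_lifelines_on_distinct_times(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        n = 150
        t = rng.permutation(n).astype(float) + 1  # distinct times
        s = rng.uniform(size=n)
        e = rng.integers(0, 2, n)
        e[t.argmin()] = 1  # ensure a comparable pair
        expected = lifelines.utils.concordance_index(t, -s, e)
        assert concordance_index(s, t, e) == pytest.approx(expected, abs=1e-12)

    def test_direction_agrees_with_auc_without_censoring(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.exponential(365, 60)
            s = np.clip(0.5 - 0.3 * (t / t.max()) + rng.normal(0, 0.1, 60), 0, 1)
            e = np.ones(60, dtype=int)
            label = (t <= 365).astype(int)
            if len(np.unique(label)) < 2:
                continue
            a = auc(s, label)
            c = concordance_index(s, t, e)
            if abs(a - 0.5) > 0.05:
                assert (a - 0.5) * (c - 0.5) > 0


class TestCalibration:
    def test_constant_wellcalibrated_scores(self):
        rng = np.random.default_rng(0)
        y = rng.binomial(1, 0.3, 20000)
        rep = calibration(np.full(20000, 0.3), y)
        assert rep.rho < 0.02
        assert rep.n == 20000

    def test_maximally_miscalibrated_single_bin(self):
        rep = calibration(np.full(50, 0.9), np.zeros(50))
        assert len(rep.bins) == 1
        assert rep.rho == pytest.approx(0.9)

    def test_zero_rho_on_constructed_fixture(self):
        # two bins whose mean score equals the observed rate exactly
        scores = np.array([0.25] * 4 + [0.75] * 4)
        labels = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        rep = calibration(scores, labels, n_bins=2)
        assert rep.rho == pytest.approx(0.0, abs=1e-12)

    def test_bin_counts_conserve_n_and_cis_bounded(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(size=1000)
        y = rng.binomial(1, s)
        rep = calibration(s, y)
        assert rep.n == 1000
        for b in rep.bins:
            assert 0 <= b["ci_lower"] <= b["observed_rate"] <= b["ci_upper"] <= 1


class TestOperatingPoints:
    def test_perfect_classifier(self):
        op = sensitivity_at_specificity([0.9, 0.8, 0.1], [1, 1, 0], 0.8)
        assert op.sensitivity == 1.0

    def test_five_point_example(self):
        op = sensitivity_at_specificity(
            [0.1, 0.2, 0.6, 0.7, 0.8], [0, 0, 0, 1, 1], 0.8
        )
        assert op.threshold > 0.6
        assert op.sensitivity == 1.0
        assert op.true_positives == 2 and op.true_negatives == 3

    def test_mirror_contract(self):
        op = specificity_at_sensitivity(
            [0.1, 0.2, 0.6, 0.7, 0.8], [0, 0, 0, 1, 1], 0.8
        )
        assert op.sensitivity >= 0.8
        assert op.specificity == 1.0

    def test_uninformative_scores_sensitivity_complements_target(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(size=10000)
        y = rng.integers(0, 2, 10000)
        op = sensitivity_at_specificity(s, y, 0.8)
        assert op.sensitivity == pytest.approx(0.2, abs=0.05)

    def test_agrees_with_full_threshold_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 30)
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            target = rng.uniform(0.1, 0.9)
            op = sensitivity_at_specificity(s, y, target)
            # oracle: scan all cutoffs, keep smallest reaching the target
            best = None
            for c in sorted(set(s)) + [np.inf]:
                tn = ((s < c) & (y == 0)).sum()
                if tn / (y == 0).sum() >= target:
                    best = c
                    break
            assert op.threshold == best


@pytest.fixture(scope="module")
def small_cv():
    sc = generate_cohort(scenario_single_split(2500, seed=0))
    table = pd.concat([sc.covariates(), sc.cohort[["time", "event"]]], axis=1)
    report = cross_validate(
        table,
        horizons=[365.0, 1095.0],
        k=5,
        seed=0,
        build_params={"max_splits": 0},  # root-only trees keep this fast
    )
    return table, report


class TestCrossValidation:
    def test_fold_partition_and_shape(self, small_cv):
        table, report = small_cv
        assert report.folds == 5
        for values in report.per_fold.values():
            assert len(values) == 5
        assert set(report.mean) == {
            "auc_365d", "auc_1095d", "cindex_365d", "cindex_1095d", "cindex_mean",
        }

    def test_deterministic_given_seed(self, small_cv):
        table, report = small_cv
        again = cross_validate(
            table, horizons=[365.0, 1095.0], k=5, seed=0,
            build_params={"max_splits": 0},
        )
        assert report.to_dict() == again.to_dict()

    def test_aggregation_matches_per_fold_values(self, small_cv):
        _, report = small_cv
        mean, std = aggregate_folds(report.per_fold)
        for k in report.mean:
            assert report.mean[k] == pytest.approx(np.mean(report.per_fold[k]))
            assert report.std[k] == pytest.approx(np.std(report.per_fold[k]))
            assert report.std[k] >= 0

    def test_era_mode_disjoint_train_test(self):
        sc = generate_cohort(scenario_single_split(2500, seed=1))
        table = pd.concat([sc.covariates(), sc.cohort[["time", "event"]]], axis=1)
        table["listing_date"] = pd.to_datetime("2000-01-01") + pd.to_timedelta(
            np.random.default_rng(0).integers(0, 5000, len(table)), unit="D"
        )
        report = cross_validate(
            table, horizons=[1095.0], seed=0,
            build_params={"max_splits": 0},
            date_column="listing_date",
            train_range=("2000-01-01", "2006-12-31"),
            test_range=("2007-01-01", "2013-12-31"),
        )
        assert report.folds == 1
        assert all(v == 0.0 for v in report.std.values())

    def test_era_mode_requires_date_column(self):
        sc = generate_cohort(scenario_single_split(1200, seed=2))
        table = pd.concat([sc.covariates(), sc.cohort[["time", "event"]]], axis=1)
        with pytest.raises(ValueError, match="date column"):
            cross_validate(
                table, horizons=[1095.0],
                train_range=("2000-01-01", "2005-01-01"),
                test_range=("2006-01-01", "2010-01-01"),
            )
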