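"""Performance metrics: worked examples, published-table anchors, identities."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathcal import (
    GroupEvaluation,
    accuracy_percent,
    evaluate_group,
    evaluate_overall,
    evaluate_predictions,
    mae,
    mse,
    r_squared,
    rmse,
    rsd,
    sd,
    split_dataset,
)
from breathcal.util import round_half_up

pairs_strategy = st.lists(
    st.tuples(
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=0, max_value=300),
    ),
    min_size=2,
    max_size=30,
)


class TestErrorMetrics:
    def test_hand_computed_example(self):
        a, p = [10, 10, 10], [9, 10, 11]
        assert mse(a, p) == pytest.approx(2 / 3)
        assert rmse(a, p) == pytest.approx(math.sqrt(2 / 3))
        assert mae(a, p) == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        a = [4, 10, 20]
        assert mse(a, a) == rmse(a, a) == mae(a, a) == 0.0

    def test_single_pair(self):
        assert mae([4], [3.98]) == pytest.approx(0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse([], [])

    @settings(derandomize=True, max_examples=100)
    @given(pairs=pairs_strategy)
    def test_rmse_is_root_of_mse_and_dominates_mae(self, pairs):
        a, p = zip(*pairs)
        assert rmse(a, p) == pytest.approx(math.sqrt(mse(a, p)), rel=1e-12)
        assert mae(a, p) <= rmse(a, p) + 1e-12

    def test_agrees_with_stdlib_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(1, 20)
            a = rng.uniform(0, 200, n)
            p = rng.uniform(0, 200, n)
            errs = [pi - ai for ai, pi in zip(a, p)]
            assert mse(a, p) == pytest.approx(statistics.fmean(e * e for e in errs))
            assert mae(a, p) == pytest.approx(statistics.fmean(abs(e) for e in errs))


class TestRSquared:
    def test_perfect_is_one(self):
        assert r_squared([0, 10, 20], [0, 10, 20]) == 1.0

    def test_mean_prediction_is_zero(self):
        a = [0.0, 10.0, 20.0]
        assert r_squared(a, [10.0, 10.0, 10.0]) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert r_squared([0, 10, 20], [0, 9, 21]) == pytest.approx(0.99)

    def test_constant_actuals_rejected(self):
        with pytest.raises(ValueError):
            r_squared([5, 5, 5], [4, 5, 6])


class TestAccuracy:
    @pytest.mark.parametrize(
        "actual,predicted,expected",
        [
            (10, 10, 100.0),
            (10, 9.28, 92.8),
            (0, 0, 100.0),
            (0, 0.5, 0.0),
            (25, 24.66, 98.64),
        ],
    )
    def test_values(self, actual, predicted, expected):
        assert accuracy_percent(actual, predicted) == pytest.approx(expected)

    def test_absolute_error_keeps_accuracy_at_most_100(self):
        assert accuracy_percent(10, 12) == pytest.approx(80.0)  # not 120


class TestDispersion:
    def test_hand_computed(self):
        assert sd([9, 10, 11]) == pytest.approx(1.0)
        assert rsd([9, 10, 11]) == pytest.approx(10.0)

    def test_constant_values(self):
        assert sd([5, 5, 5]) == 0.0
        assert rsd([5, 5, 5]) == 0.0

    def test_published_row_relation(self):
        # sd 0.35 at mean 24.8 -> RSD 1.41%
        assert round_half_up(100 * 0.35 / 24.8, 2) == 1.41

    def test_undefined_cases_signalled(self):
        with pytest.raises(ValueError):
            sd([1.0])
        with pytest.raises(ValueError):
            rsd([0.0, 0.0])

    def test_matches_stdlib_oracle(self, rng):
        for _ in range(200):
            v = rng.uniform(1, 100, rng.integers(2, 15))
            assert sd(v) == pytest.approx(statistics.stdev(v))


class TestGroupEvaluation:
    def test_hand_computed_group(self):
        g = evaluate_group(10, [9, 10, 11])
        assert g.mean_predicted == pytest.approx(10.0)
        assert g.avg_accuracy == pytest.approx(100 - 100 * (2 / 3) / 10)
        assert g.mae == pytest.approx(2 / 3)
        assert g.sd == pytest.approx(1.0)
        assert g.rsd == pytest.approx(10.0)

    def test_zero_concentration_all_correct(self):
        g = evaluate_group(0, [0, 0, 0])
        assert g.avg_accuracy == 100.0
        assert g.mse == g.mae == g.rmse == 0.0

    def test_perfectly_repeatable_predictions(self):
        g = evaluate_group(50, [50.0] * 4)
        assert g.avg_accuracy == 100.0 and g.rsd == 0.0

    def test_accuracy_identity_with_mae(self, rng):
        for _ in range(100):
            actual = rng.uniform(1, 200)
            preds = rng.uniform(0, 250, rng.integers(1, 10))
            g = evaluate_group(actual, preds)
            assert g.avg_accuracy == pytest.approx(100 - 100 * g.mae / actual)

    def test_single_prediction_has_undefined_spread(self):
        g = evaluate_group(10, [9.5])
        assert math.isnan(g.sd) and math.isnan(g.rsd)


def _group(actual, acc, mse_, mae_):
    return GroupEvaluation(
        actual_concentration=actual, n=5, mean_predicted=actual,
        avg_accuracy=acc, mse=mse_, mae=mae_, rmse=math.sqrt(mse_),
        sd=float("nan"), rsd=float("nan"),
    )


class TestOverallAggregation:
    def test_experimental_table_aggregation(self):
        groups = [
            _group(25, 98.64, 0.15, 0.34),
            _group(75, 97.78, 4.67, 1.67),
            _group(125, 98.58, 4.93, 1.77),
            _group(180, 97.65, 21.16, 4.24),
        ]
        rep = evaluate_overall(groups)
        assert round_half_up(rep.overall_accuracy, 2) == 98.16
        assert round_half_up(rep.overall_mse, 2) == 7.73
        assert round_half_up(rep.overall_rmse, 2) == 2.78

    def test_single_group_passthrough(self):
        rep = evaluate_overall([_group(50, 99.0, 4.0, 1.5)])
        assert rep.overall_accuracy == 99.0
        assert rep.overall_mse == 4.0
        assert rep.overall_rmse == 2.0
        assert rep.overall_mae == 1.5

    def test_pooled_r2_and_table(self):
        a = np.array([0, 0, 10, 10, 20, 20], dtype=float)
        p = np.array([0, 0, 9, 11, 21, 19], dtype=float)
        rep = evaluate_predictions(a, p)
        assert rep.overall_r2 == pytest.approx(r_squared(a, p))
        df = rep.to_dataframe()
        assert list(df["ActualConcentration"]) == [0.0, 10.0, 20.0, "Overall"]

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            evaluate_overall([])


class TestSplitDataset:
    def test_design_sizes(self):
        train, valid = split_dataset(list(range(200)), 0.9, seed=1)
        assert len(train) == 180 and len(valid) == 20

    def test_half_split_of_two(self):
        train, valid = split_dataset([1, 2], 0.5, seed=0)
        assert len(train) == 1 and len(valid) == 1

    def test_partition_and_determinism(self):
        items = list(range(57))
        t1, v1 = split_dataset(items, 0.9, seed=9)
        t2, v2 = split_dataset(items, 0.9, seed=9)
        assert (t1, v1) == (t2, v2)
        assert sorted(t1 + v1) == items
        assert set(t1).isdisjoint(v1)

    def test_fraction_range_enforced(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], 1.0)
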