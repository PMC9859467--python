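"""Zero-threshold classifier and linear calibration (Model/Results)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathcal import (
    BreathAlcoholModel,
    BreathAlcoholResults,
    CalibrationPoint,
    FeatureVector,
    SensorTrace,
    SimulationParams,
    ThresholdParams,
    classify_zero,
    extract_features,
    generate_dataset,
    generate_trace,
    zero_rule,
)


def make_features(mode10, max30, avg20, min30=0.0):
    avg30 = avg20  # avg30 plays no role in the rules
    return FeatureVector(
        mode10, max30, min30, avg20, avg30, max30 - avg20, max30 - avg30
    )


class TestZeroClassifier:
    @pytest.mark.parametrize(
        "mode10,max30,avg20,expected_rule",
        [
            (0, 0, 0, 1),        # no signal change at all
            (0, 4, 1, 2),        # no sustained early response
            (5, 10, 5, 3),       # isolated spike: ratio 0.5 < 0.8
            (4, 4, 3.4, 4),      # plateau but insufficient peak: diff 0.6 < 1
            (38, 40, 35, 0),     # genuine response falls through all rules
        ],
    )
    def test_rule_firing(self, mode10, max30, avg20, expected_rule):
        f = make_features(mode10, max30, avg20)
        assert zero_rule(f) == expected_rule
        assert classify_zero(f) == (expected_rule != 0)

    def test_rule_order_is_fixed(self):
        # satisfies rules 1-4 simultaneously; rule 1 must win
        f = make_features(0, 0, 0)
        assert zero_rule(f) == 1

    @pytest.mark.parametrize(
        "mode10,max30,avg20,expected",
        [
            (8, 10, 9.5, 4),  # ratio exactly 0.8 falls through; diff 0.5 < 1 -> rule 4
            (8, 10, 8.9, 0),  # ratio exactly 0.8, diff 1.1 >= 1 -> quantify
            (9, 10, 9.0, 0),  # diff exactly 1 falls through (strict inequality)
        ],
    )
    def test_strict_boundaries(self, mode10, max30, avg20, expected):
        assert zero_rule(make_features(mode10, max30, avg20)) == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        mode10=st.floats(min_value=0, max_value=100),
        max30=st.floats(min_value=0, max_value=100),
        avg20=st.floats(min_value=0, max_value=100),
    )
    def test_exactly_one_branch_fires(self, mode10, max30, avg20):
        f = make_features(mode10, max30, avg20)
        assert zero_rule(f) in (0, 1, 2, 3, 4)

    def test_custom_thresholds(self):
        f = make_features(5, 10, 5)
        assert not classify_zero(f, ThresholdParams(ratio_threshold=0.4))

    def test_default_zero_traces_always_classified_zero(self, default_params):
        traces = [generate_trace(0, default_params, seed=s) for s in range(100)]
        assert all(classify_zero(extract_features(t)) for t in traces)


class TestCalibrationFit:
    def test_exact_identity_line(self):
        res = BreathAlcoholModel(
            [CalibrationPoint(10, 10), CalibrationPoint(20, 20)]
        ).fit()
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovery(self):
        peaks = [24, 104, 204]
        pts = [CalibrationPoint(0.5 * p - 2, p) for p in peaks]
        res = BreathAlcoholModel(pts).fit()
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(-2.0)
        assert res.fitted_peak_range == (24, 204)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(10, 500, size=10)
        y = 0.37 * x + rng.normal(0, 2, size=10)
        pts = [CalibrationPoint(max(yi, 0), xi) for xi, yi in zip(x, y)]
        res = BreathAlcoholModel(pts).fit()
        X = np.column_stack([np.ones_like(x), x])
        yy = np.array([p.concentration for p in pts])
        beta = np.linalg.solve(X.T @ X, X.T @ yy)
        assert res.intercept == pytest.approx(beta[0], abs=1e-9)
        assert res.slope == pytest.approx(beta[1], abs=1e-9)

    def test_zero_point_excluded_by_default(self):
        pts = [CalibrationPoint(0, 5), CalibrationPoint(10, 10), CalibrationPoint(20, 20)]
        res = BreathAlcoholModel(pts).fit()
        assert res.slope == pytest.approx(1.0)  # unaffected by the (5, 0) point
        res_with_zero = BreathAlcoholModel(pts, exclude_zero=False).fit()
        assert res_with_zero.slope != pytest.approx(1.0)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            BreathAlcoholModel([CalibrationPoint(10, 10)]).fit()
        with pytest.raises(ValueError):
            BreathAlcoholModel(
                [CalibrationPoint(10, 7), CalibrationPoint(20, 7)]
            ).fit()


class TestPrediction:
    @pytest.fixture()
    def line(self):
        peaks = [24, 104, 204]
        return BreathAlcoholModel(
            [CalibrationPoint(0.5 * p - 2, p) for p in peaks]
        ).fit()

    def test_point_prediction(self, line):
        assert line.predict(104) == pytest.approx(50.0)

    def test_negative_prediction_clamped_to_zero(self, line):
        assert line.predict(2) == 0.0

    def test_prediction_clamped_to_sensor_ceiling(self):
        res = BreathAlcoholModel(
            [CalibrationPoint(10, 10), CalibrationPoint(20, 20)]
        ).fit()
        assert res.predict(350) == 300.0

    def test_monotone_in_peak_for_positive_slope(self, line):
        grid = np.linspace(0, 900, 50)
        preds = line.predict(grid)
        assert np.all(np.diff(preds) >= 0)


class TestQuantify:
    def test_all_zero_trace_is_zero_classified(self):
        res = BreathAlcoholModel(
            [CalibrationPoint(10, 10), CalibrationPoint(20, 20)]
        ).fit()
        reading = res.quantify(SensorTrace(readings=np.zeros(30, dtype=int)))
        assert reading.is_zero_classified and reading.value == 0 and reading.rule == 1

    def test_noiseless_round_trip_recovers_concentrations(self, noiseless_dataset):
        res = BreathAlcoholModel.from_traces(noiseless_dataset).fit()
        for tr in noiseless_dataset:
            got = res.quantify(tr)
            if tr.true_concentration == 0:
                assert got.is_zero_classified
            else:
                # within one ADC quantization step mapped through the slope
                assert abs(got.value - tr.true_concentration) <= res.slope

    def test_noiseless_50_recovers_50(self, noiseless_dataset):
        res = BreathAlcoholModel.from_traces(noiseless_dataset).fit()
        tr = generate_trace(50, SimulationParams(noise_amplitude=0), seed=3)
        assert res.quantify(tr).value == pytest.approx(50, abs=0.5)

    def test_quantify_many_shape(self, noiseless_dataset):
        res = BreathAlcoholModel.from_traces(noiseless_dataset).fit()
        df = res.quantify_many(noiseless_dataset[:10])
        assert list(df.columns) == [
            "trial_id", "true_concentration", "predicted", "is_zero_classified", "rule",
        ]
        assert len(df) == 10


class TestResultsSurface:
    @pytest.fixture()
    def fitted(self, noiseless_dataset):
        return BreathAlcoholModel.from_traces(noiseless_dataset).fit()

    def test_params_and_bse(self, fitted):
        assert set(fitted.params.index) == {"intercept", "slope"}
        assert fitted.bse["slope"] < 0.01  # near-exact synthetic calibration

    def test_summary_mentions_fit(self, fitted):
        text = fitted.summary()
        assert "slope" in text and "R^2" in text

    def test_json_round_trip(self, fitted, tmp_path):
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = BreathAlcoholResults.load(path)
        assert loaded.slope == fitted.slope
        assert loaded.intercept == fitted.intercept
        assert loaded.fitted_peak_range == fitted.fitted_peak_range
        assert loaded.model.exclude_zero == fitted.model.exclude_zero
        assert loaded.predict(100) == fitted.predict(100)
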