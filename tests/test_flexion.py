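"""Feature extraction, significance selection and the flexion surrogate."""

import numpy as np
import pandas as pd
import pytest

import rpmgait as rg
from rpmgait.flexion import predict_training


@pytest.fixture(scope="module")
def small_training():
    """Compact noise-free dataset for fast pipeline checks."""
    p = rg.FlexionSimParams(noise_sd=0.0, duration=25, seed=31)
    sensors, trace = rg.generate_flexion_dataset(p)
    ts = rg.build_training_set(sensors, trace, hop=0.5)
    return sensors, trace, ts


class TestExtractFeatures:
    def test_constant_window(self):
        vec = rg.extract_features({"ch": np.full(100, 2.5)}, 100.0)
        assert vec["ch__mean"] == 2.5
        assert vec["ch__sd"] == 0.0
        assert vec["ch__trend_slope"] == pytest.approx(0.0, abs=1e-9)
        assert vec["ch__range"] == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        w = {"a": rng.normal(size=200), "b": rng.normal(size=200)}
        v1 = rg.extract_features(w, 100.0)
        v2 = rg.extract_features(w, 100.0)
        pd.testing.assert_series_equal(v1, v2)

    def test_sine_dominant_frequency(self):
        fs, f0 = 1000.0, 25.0
        t = np.arange(1000) / fs
        vec = rg.extract_features({"s": np.sin(2 * np.pi * f0 * t)}, fs)
        assert abs(vec["s__dominant_freq"] - f0) <= fs / len(t)  # within one bin

    def test_vector_length_and_ordering(self):
        bank = rg.default_feature_bank()
        w = {"b": np.arange(10.0), "a": np.arange(10.0)}
        vec = rg.extract_features(w, 10.0, bank)
        assert len(vec) == 2 * len(bank.features)
        assert list(vec.index[: len(bank.features)]) == [
            f"a__{f.name}" for f in bank.features
        ]

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            rg.extract_features({"x": np.array([1.0])}, 10.0)

    def test_duplicate_feature_names_rejected(self):
        f = rg.default_feature_bank().features
        with pytest.raises(ValueError, match="unique"):
            rg.FeatureBankConfig(features=f + (f[0],))


class TestSelectSignificantFeatures:
    def test_target_copy_selected_constant_never(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=60)
        X = pd.DataFrame(
            {
                "copy_of_target": y,
                "constant": np.ones(60),
                "noise": rng.normal(size=60),
            }
        )
        selected = rg.select_significant_features(X, y)
        assert "copy_of_target" in selected
        assert "constant" not in selected

    def test_all_constant_warns_empty(self):
        X = pd.DataFrame({"a": np.ones(20), "b": np.zeros(20)})
        with pytest.warns(UserWarning):
            assert rg.select_significant_features(X, np.arange(20.0)) == []

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError):
            rg.select_significant_features(X, np.arange(5.0))


class TestTrainSurrogate:
    def test_constant_target_predicts_constant(self, small_training):
        _, _, ts = small_training
        const = rg.TrainingSet(ts.windows, np.full(len(ts), 42.0), ts.sample_rate)
        with pytest.warns(UserWarning):  # nothing associates with a constant target
            model = rg.train_surrogate(const, seed=1)
        np.testing.assert_allclose(predict_training(model, const), 42.0)

    def test_top_k_geq_selected_is_identity(self, small_training):
        _, _, ts = small_training
        m_all = rg.train_surrogate(ts, top_k=10**6, seed=2)
        m_same = rg.train_surrogate(ts, top_k=len(m_all.feature_names), seed=2)
        assert m_all.feature_names == m_same.feature_names

    def test_reduction_keeps_fit_quality(self, small_training):
        _, _, ts = small_training
        m_all = rg.train_surrogate(ts, top_k=10**6, seed=3)
        m_red = rg.train_surrogate(ts, top_k=50, seed=3)
        err_all = np.sqrt(np.mean((predict_training(m_all, ts) - ts.targets) ** 2))
        err_red = np.sqrt(np.mean((predict_training(m_red, ts) - ts.targets) ** 2))
        assert err_red <= max(1.2 * err_all, err_all + 0.5)

    def test_deterministic_given_seed(self, small_training):
        _, _, ts = small_training
        m1 = rg.train_surrogate(ts, seed=4)
        m2 = rg.train_surrogate(ts, seed=4)
        assert m1.feature_names == m2.feature_names
        np.testing.assert_array_equal(predict_training(m1, ts), predict_training(m2, ts))

    def test_insufficient_windows_rejected(self, small_training):
        _, _, ts = small_training
        tiny = rg.TrainingSet(ts.windows[:5], ts.targets[:5], ts.sample_rate)
        with pytest.raises(ValueError, match="10"):
            rg.train_surrogate(tiny)


class TestPredictFlexion:
    def test_trace_correlation_and_range(self, small_training):
        sensors, trace, ts = small_training
        model = rg.train_surrogate(ts, seed=5)
        pred = rg.predict_flexion(model, sensors, hop=0.25)
        truth = np.interp(pred["time"], trace["time"], trace["flexion_deg"])
        assert np.corrcoef(pred["angle_deg"], truth)[0, 1] > 0.9
        lo, hi = model.target_range
        assert pred["angle_deg"].between(lo - 1e-9, hi + 1e-9).all()

    def test_missing_thigh_sensor_rejected(self, small_training):
        sensors, _, ts = small_training
        model = rg.train_surrogate(ts, seed=6)
        ankle_only = {k: v for k, v in sensors.items() if k[1] is rg.SensorLocation.ANKLE}
        with pytest.raises(ValueError, match="thigh"):
            rg.predict_flexion(model, ankle_only)

    def test_model_archive_roundtrip(self, small_training, tmp_path):
        sensors, _, ts = small_training
        model = rg.train_surrogate(ts, seed=7)
        path = tmp_path / "model.pkl"
        rg.save_model(model, path)
        back = rg.load_model(path)
        assert back.feature_names == model.feature_names
        np.testing.assert_array_equal(
            predict_training(back, ts), predict_training(model, ts)
        )


class TestMaxFlexion:
    def test_constant_trace(self):
        trace = pd.DataFrame(
            {"time": [0, 1, 2], "angle_deg": [90.0] * 3, "activity": ["walk"] * 3}
        )
        assert rg.max_flexion(trace) == 90.0

    def test_sinusoid_closed_form(self):
        t = np.linspace(0, 10, 2000)
        trace = pd.DataFrame(
            {"time": t, "angle_deg": 60 + 30 * np.sin(2 * np.pi * 0.5 * t), "activity": "walk"}
        )
        assert rg.max_flexion(trace) == pytest.approx(90.0, abs=0.01)

    def test_max_over_segments_is_max_of_segment_maxima(self):
        walk = pd.DataFrame({"time": [0, 1], "angle_deg": [50.0, 70.0], "activity": "walk"})
        sts = pd.DataFrame({"time": [2, 3], "angle_deg": [85.0, 95.0], "activity": "sit_to_stand"})
        both = pd.concat([walk, sts], ignore_index=True)
        assert rg.max_flexion(both) == max(
            rg.max_flexion(both, "walk"), rg.max_flexion(both, "sit_to_stand")
        )
        assert rg.max_flexion(both, "sit_to_stand") == 95.0

    def test_empty_segment_rejected(self):
        trace = pd.DataFrame({"time": [0], "angle_deg": [50.0], "activity": ["walk"]})
        with pytest.raises(ValueError):
            rg.max_flexion(trace, "sit_to_stand")
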