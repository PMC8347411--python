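"""Synthetic generators: gait sessions, recovery cohorts, flexion data, PROMs."""

import numpy as np
import pytest

import rpmgait as rg
from rpmgait.session import CHANNEL_NAMES


class TestGaitSession:
    def test_bit_identical_under_fixed_seed(self):
        p = rg.GaitParams(duration=10, seed=42)
        a = rg.generate_gait_session(p)
        b = rg.generate_gait_session(p)
        for s1, s2 in zip(a[:2], b[:2]):
            for c in CHANNEL_NAMES:
                np.testing.assert_array_equal(s1.channels[c], s2.channels[c])
        assert a[2].steps == b[2].steps

    def test_step_count_is_cadence_times_minutes(self, clean_gait):
        _, _, _, truth = clean_gait  # cadence 100, duration 60 s
        assert len(truth.steps[rg.Limb.OPERATIVE]) == 100
        assert len(truth.steps[rg.Limb.NON_OPERATIVE]) == 100

    def test_session_shape_and_rate(self, clean_gait):
        params, op, nonop, _ = clean_gait
        for sess in (op, nonop):
            assert sess.sample_rate == params.sample_rate
            assert sess.n_samples == int(params.duration * params.sample_rate)

    def test_asymmetry_factor_is_exact_peak_mean_ratio(self):
        p = rg.GaitParams(cadence=100, duration=60, asymmetry_factor=0.8, noise_sd=0, seed=5)
        _, _, truth = rg.generate_gait_session(p)
        ratio = truth.peaks(rg.Limb.OPERATIVE).mean() / truth.peaks(rg.Limb.NON_OPERATIVE).mean()
        assert ratio == pytest.approx(0.8)

    def test_spike_peak_equals_ground_truth(self, clean_gait):
        _, op, _, truth = clean_gait
        mag = rg.resultant_acceleration(op)
        for t, peak in truth.steps[rg.Limb.OPERATIVE][:10]:
            i = int(round(t * op.sample_rate))
            lo, hi = max(i - 30, 0), i + 30
            assert mag[lo:hi].max() == pytest.approx(peak, rel=1e-3)

    def test_step_times_strictly_increasing(self, noisy_gait):
        _, _, _, truth = noisy_gait
        for limb in rg.Limb:
            assert np.all(np.diff(truth.times(limb)) > 0)

    @pytest.mark.parametrize(
        "kwargs", [{"duration": 0}, {"cadence": -5}, {"sample_rate": 0}, {"asymmetry_factor": 0}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rg.GaitParams(**kwargs)


class TestRecoveryCohort:
    def test_session_pair_count(self):
        params = rg.default_recovery_params(n_patients=5, seed=1)
        gait = rg.GaitParams(duration=5)
        cohort = rg.generate_recovery_cohort(params, gait)
        assert len(cohort) == 5 * len(params.weeks)

    def test_increasing_multiplier_gives_increasing_weekly_load(self):
        params = rg.default_recovery_params(n_patients=2, seed=2)
        gait = rg.GaitParams(cadence=100, duration=30, noise_sd=0)
        cohort = rg.generate_recovery_cohort(params, gait)
        weekly = {}
        for cs in cohort:
            ev = rg.detect_steps(
                rg.resultant_acceleration(cs.non_operative), gait.sample_rate
            )
            weekly.setdefault(cs.week, []).append(rg.session_metrics(ev).impact_load)
        means = [np.mean(weekly[w]) for w in params.weeks]
        assert np.all(np.diff(means) > 0)

    def test_symmetric_construction_recovers_zero_asymmetry(self):
        weeks = (rg.WeekLabel.W2, rg.WeekLabel.W3)
        params = rg.RecoveryTrajectoryParams(
            weeks=weeks,
            load_multiplier={w: 1.0 for w in weeks},
            asymmetry_factor={w: 1.0 for w in weeks},
            n_patients=1,
            seed=3,
        )
        gait = rg.GaitParams(cadence=100, duration=60, noise_sd=0)
        for cs in rg.generate_recovery_cohort(params, gait):
            m = {}
            for limb, sess in (("op", cs.operative), ("nonop", cs.non_operative)):
                ev = rg.detect_steps(rg.resultant_acceleration(sess), gait.sample_rate)
                m[limb] = rg.session_metrics(ev)
            r = rg.impact_load_asymmetry(m["op"], m["nonop"])
            assert abs(r.asymmetry_pct) < 3.0

    def test_empty_weeks_rejected(self):
        with pytest.raises(ValueError, match="weeks"):
            rg.RecoveryTrajectoryParams(
                weeks=(), load_multiplier={}, asymmetry_factor={}, n_patients=1
            )


class TestFlexionDataset:
    def test_ground_truth_max_is_offset_plus_amplitude(self):
        p = rg.FlexionSimParams(amplitude_deg=30, offset_deg=60, duration=10, seed=1)
        _, trace = rg.generate_flexion_dataset(p)
        assert trace["flexion_deg"].max() == pytest.approx(90.0, abs=0.01)
        assert rg.max_flexion(trace) == pytest.approx(90.0, abs=0.01)

    def test_zero_amplitude_constant_trace(self):
        p = rg.FlexionSimParams(amplitude_deg=0, offset_deg=45, duration=5, seed=1)
        _, trace = rg.generate_flexion_dataset(p)
        np.testing.assert_allclose(trace["flexion_deg"], 45.0)

    def test_deterministic_under_seed(self):
        p = rg.FlexionSimParams(duration=5, seed=9)
        s1, t1 = rg.generate_flexion_dataset(p)
        s2, t2 = rg.generate_flexion_dataset(p)
        assert t1.equals(t2)
        for key in s1:
            for c in CHANNEL_NAMES:
                np.testing.assert_array_equal(s1[key].channels[c], s2[key].channels[c])

    def test_four_sensors_with_target_rate_trace(self):
        p = rg.FlexionSimParams(duration=5, seed=1)
        sensors, trace = rg.generate_flexion_dataset(p)
        assert set(sensors) == {(l, s) for l in rg.Limb for s in rg.SensorLocation}
        assert len(trace) == int(5 * p.target_rate)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            rg.FlexionSimParams(amplitude_deg=-1)


class TestPromsResponses:
    def _fixed_params(self, probs, oks_item, n=3):
        weeks = (rg.WeekLabel.W2, rg.WeekLabel.W3)
        return rg.RecoveryTrajectoryParams(
            weeks=weeks,
            load_multiplier={w: 1.0 for w in weeks},
            asymmetry_factor={w: 1.0 for w in weeks},
            proms={
                w: rg.PromsWeekParams(
                    oks_item_mean=oks_item, eq5d_level_probs=probs, eqvas_mean=80
                )
                for w in weeks
            },
            n_patients=n,
            seed=4,
        )

    def test_ceiling_trajectory_scores_48(self):
        df = rg.generate_proms_responses(self._fixed_params((1.0, 0.0, 0.0), 4.0))
        scores = [rg.score_oks(list(r)) for r in df[[f"oks_{i}" for i in range(1, 13)]].to_numpy()]
        assert all(s == 48 for s in scores)

    def test_full_health_state_gives_index_one(self):
        df = rg.generate_proms_responses(self._fixed_params((1.0, 0.0, 0.0), 4.0))
        assert set(df["eq5d_state"]) == {"11111"}
        assert all(rg.score_eq5d_index(s) == 1.0 for s in df["eq5d_state"])

    def test_responses_in_legal_ranges(self):
        df = rg.generate_proms_responses(rg.default_recovery_params(n_patients=4, seed=6))
        items = df[[f"oks_{i}" for i in range(1, 13)]].to_numpy()
        assert items.min() >= 0 and items.max() <= 4
        assert df["eq_vas"].between(0, 100).all()
        assert df["eq5d_state"].str.fullmatch("[123]{5}").all()

    def test_deterministic_under_seed(self):
        p = rg.default_recovery_params(n_patients=2, seed=8)
        assert rg.generate_proms_responses(p).equals(rg.generate_proms_responses(p))

    def test_mean_scores_follow_configured_trajectory(self):
        df = rg.generate_proms_responses(rg.default_recovery_params(n_patients=40, seed=9))
        item_cols = [f"oks_{i}" for i in range(1, 13)]
        means = df.groupby("week")[item_cols].sum().sum(axis=1) / 40
        # expected weekly OKS = 12 * configured item mean
        assert means["preop"] == pytest.approx(12 * 2.13, abs=2.0)
        assert means["W12"] == pytest.approx(12 * 3.24, abs=2.0)
        assert means["W12"] > means["preop"]
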