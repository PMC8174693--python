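"""Signal chain: VM, still windows, auto-calibration, ENMO, aggregation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acticut.cohort import (
    SimulationConfig,
    simulate_calibration_session,
    simulate_participants,
    simulate_raw_signal,
)
from acticut.protocol import ProtocolStage
from acticut.signal import (
    CalibrationCoefficients,
    EpochSeries,
    InsufficientDataError,
    RawTriaxialSignal,
    aggregate_to_minute,
    apply_calibration,
    autocalibrate,
    compute_enmo,
    detect_still_windows,
    stage_last_minute_value,
    vector_magnitude,
)


def _signal(samples, rate=30.0, placement="hip_correct", start=0.0):
    return RawTriaxialSignal(placement, rate, np.asarray(samples, float), start)


class TestVectorMagnitude:
    @pytest.mark.parametrize("xyz,expected", [
        ((3, 4, 12), 13.0),
        ((0, 0, 0), 0.0),
        ((100, 100, 100), np.sqrt(30000.0)),
    ])
    def test_examples(self, xyz, expected):
        assert vector_magnitude(*xyz) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            vector_magnitude(-1, 2, 3)

    @given(st.tuples(*[
        st.one_of(st.just(0.0), st.floats(1e-3, 1e5)) for _ in range(3)]))
    @settings(max_examples=100, deadline=None)
    def test_dominates_each_axis(self, xyz):
        vm = vector_magnitude(*xyz)
        assert vm >= max(xyz) - 1e-9
        assert (vm == 0) == (max(xyz) == 0)


class TestStillWindows:
    def test_constant_signal_is_one_window(self):
        sig = _signal(np.tile([0.0, 0.0, 1.0], (900, 1)))
        wins = detect_still_windows(sig)
        assert len(wins) == 1
        assert wins[0].start_idx == 0 and wins[0].stop_idx == 900

    def test_high_amplitude_sinusoid_has_none(self):
        t = np.arange(900) / 30.0
        sig = _signal(np.column_stack([np.sin(2 * np.pi * t),
                                       np.zeros_like(t), np.ones_like(t)]))
        assert detect_still_windows(sig) == []

    def test_short_signal_returns_empty(self):
        assert detect_still_windows(_signal(np.zeros((10, 3)))) == []

    def test_generator_still_segments_recovered(self, default_config, rng):
        sig, _, _ = simulate_calibration_session(default_config, rng,
                                                 n_still_windows=12)
        wins = detect_still_windows(sig)
        assert 11 <= len(wins) <= 13


class TestAutocalibration:
    def test_already_calibrated_is_fixed_point(self, default_config, rng):
        cfg = default_config.copy()
        cfg.gain_error = 0.0
        cfg.offset_error_g = 0.0
        sig, _, _ = simulate_calibration_session(cfg, rng)
        coef = autocalibrate(sig)
        assert coef.source == "autocalibrated"
        assert np.allclose(coef.gain, 1.0, atol=0.005)
        assert np.allclose(coef.offset, 0.0, atol=0.003)
        assert coef.post_error < 1e-3

    def test_recovers_injected_miscalibration(self, default_config):
        gain_true = np.array([1.02, 0.98, 1.01])
        offset_true = np.array([0.05, -0.03, 0.02])
        cfg = default_config.copy()
        cfg.gain_error = 0.0
        cfg.offset_error_g = 0.0
        true_sig, _, _ = simulate_calibration_session(cfg, np.random.default_rng(1))
        observed = RawTriaxialSignal(
            "calibration", true_sig.rate,
            true_sig.samples * gain_true + offset_true)
        coef = autocalibrate(observed)
        # correction must invert the distortion: gain ~ 1/g, offset ~ -o/g
        assert np.allclose(coef.gain, 1.0 / gain_true, atol=0.01)
        assert np.allclose(coef.offset, -offset_true / gain_true, atol=0.005)

    def test_backup_used_when_stills_lack_diversity(self):
        sig = _signal(np.tile([0.0, 0.0, 1.0], (3000, 1)))  # one orientation
        backup = CalibrationCoefficients([0.01, 0.0, 0.0], [1.0, 1.0, 1.0],
                                         0.004, "autocalibrated")
        coef = autocalibrate(sig, backup=backup)
        assert coef.source == "backup"
        assert np.allclose(coef.offset, backup.offset)

    def test_identity_with_warning_when_no_backup(self):
        sig = _signal(np.tile([0.0, 0.0, 1.0], (3000, 1)))
        with pytest.warns(UserWarning, match="still windows"):
            coef = autocalibrate(sig)
        assert coef.source == "identity"
        assert np.allclose(coef.gain, 1.0) and np.allclose(coef.offset, 0.0)

    def test_round_trip_restores_unit_norms(self, default_config, rng):
        sig, _, _ = simulate_calibration_session(default_config, rng)
        coef = autocalibrate(sig)
        cal = apply_calibration(sig, coef)
        norms = [np.linalg.norm(w.mean) for w in detect_still_windows(cal)]
        assert np.all(np.abs(np.array(norms) - 1.0) < 0.01)


class TestApplyCalibration:
    def test_identity_leaves_signal_unchanged(self):
        sig = _signal(np.random.default_rng(0).normal(size=(60, 3)))
        out = apply_calibration(sig, CalibrationCoefficients.identity())
        assert np.array_equal(out.samples, sig.samples)

    def test_offset_only_on_zero_signal(self):
        sig = _signal(np.zeros((30, 3)))
        coef = CalibrationCoefficients([0.1, -0.2, 0.3], [1, 1, 1], 0.0, "backup")
        out = apply_calibration(sig, coef)
        assert np.allclose(out.samples, [0.1, -0.2, 0.3])


class TestEnmo:
    def test_stationary_calibrated_signal_is_zero(self):
        sig = _signal(np.tile([0.0, 0.0, 1.0], (300, 1)))
        assert np.all(compute_enmo(sig).values == 0.0)

    def test_constant_norm_closed_form(self):
        u = np.array([1.0, 2.0, 2.0]) / 3.0
        sig = _signal(np.tile(1.05 * u, (300, 1)))
        assert np.allclose(compute_enmo(sig).values, 50.0, atol=1e-9)

    def test_axis_permutation_invariance(self):
        rngl = np.random.default_rng(4)
        samples = rngl.normal(0, 0.5, (300, 3)) + [0, 0, 1]
        a = compute_enmo(_signal(samples)).values
        b = compute_enmo(_signal(samples[:, [2, 0, 1]])).values
        c = compute_enmo(_signal(samples * [-1, 1, -1])).values
        assert np.allclose(a, b) and np.allclose(a, c)

    def test_trailing_partial_second_dropped(self):
        sig = _signal(np.tile([0.0, 0.0, 1.05], (75, 1)))  # 2.5 s at 30 Hz
        with pytest.warns(UserWarning, match="partial second"):
            series = compute_enmo(sig)
        assert series.values.shape == (2,)

    def test_generator_round_trip(self, default_config):
        st_ = ProtocolStage("cleaning", "everyday", 240.0, 3.0, start_s=0.0)
        p = simulate_participants(default_config)[0]
        sig = simulate_raw_signal(p, st_, "hip_correct", default_config,
                                  np.random.default_rng(8), true_enmo_mg=82.0)
        val = stage_last_minute_value(compute_enmo(sig), st_)
        assert val == pytest.approx(82.0, abs=2.0)


class TestAggregation:
    def test_counts_minute_is_sum(self):
        s = EpochSeries("hip_correct", "vm_counts", 1.0, np.full(60, 10.0))
        out = aggregate_to_minute(s, "sum_counts")
        assert out.values.tolist() == [600.0]

    def test_mg_minute_is_mean(self):
        s = EpochSeries("hip_correct", "enmo_mg", 1.0, np.full(60, 82.0))
        assert aggregate_to_minute(s, "mean_mg").values.tolist() == [82.0]

    def test_incomplete_minute_dropped(self):
        s = EpochSeries("hip_correct", "vm_counts", 1.0, np.ones(90))
        out = aggregate_to_minute(s, "sum_counts")
        assert out.values.shape == (1,)

    def test_sum_equals_exact_sum(self, rng):
        vals = rng.uniform(0, 50, 240)
        s = EpochSeries("hip_correct", "vm_counts", 1.0, vals)
        out = aggregate_to_minute(s, "sum_counts")
        expect = vals.reshape(4, 60).sum(axis=1)
        assert np.allclose(out.values, expect, rtol=1e-9)


class TestStageLastMinute:
    def _stage(self, start=0.0, dur=240.0):
        return ProtocolStage("treadmill_3.0", "treadmill", dur, 2.8, start_s=start)

    def test_constant_counts(self):
        s = EpochSeries("hip_correct", "vm_counts", 1.0, np.full(240, 10.0))
        assert stage_last_minute_value(s, self._stage()) == 600.0

    def test_ramp_then_plateau_mg(self):
        vals = np.concatenate([np.linspace(0, 82, 180), np.full(60, 82.0)])
        s = EpochSeries("hip_correct", "enmo_mg", 1.0, vals)
        assert stage_last_minute_value(s, self._stage()) == pytest.approx(82.0)

    def test_insufficient_overlap_raises(self):
        s = EpochSeries("hip_correct", "vm_counts", 1.0, np.ones(59))
        with pytest.raises(InsufficientDataError, match="treadmill_3.0"):
            stage_last_minute_value(s, self._stage(dur=59.0))
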