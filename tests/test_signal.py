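"""Filters, cropping, tightening-onset detection and stripping extraction."""

import math

import numpy as np
import pytest

from bonescrew import (
    NoMotionError,
    NoTighteningError,
    SegmentBounds,
    SignalError,
    TorqueTrace,
    crop_recording,
    detect_tightening_onset,
    measure_true_stripping_torque,
    median_filter,
    moving_average,
    position_to_rotation,
    segment_trace,
)

DEG = math.pi / 180.0


def make_trace(torque, rotation=None, position=None, fs=1000.0):
    n = len(torque)
    time = np.arange(n) / fs
    if rotation is None:
        rotation = np.linspace(0.0, 50.0, n)
    if position is None:
        rotation = np.asarray(rotation, dtype=float)
        position = 2.75 * rotation / (2.0 * np.pi)
    return TorqueTrace(time=time, torque=np.asarray(torque, dtype=float),
                       rotation=np.asarray(rotation, dtype=float),
                       position=np.asarray(position, dtype=float),
                       sample_rate=fs)


class TestTraceValidation:
    def test_rejects_short_and_ragged(self):
        with pytest.raises(SignalError):
            make_trace([1.0])
        with pytest.raises(SignalError):
            TorqueTrace(time=np.arange(3.0), torque=np.zeros(2),
                        rotation=np.zeros(3), position=np.zeros(3),
                        sample_rate=1.0)

    def test_rejects_non_uniform_time(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(SignalError):
            TorqueTrace(time=t, torque=np.zeros(4), rotation=np.zeros(4),
                        position=np.zeros(4), sample_rate=1.0)


class TestFilters:
    def test_moving_average_hand_example(self):
        np.testing.assert_allclose(
            moving_average(np.array([0.0, 0.0, 3.0, 0.0, 0.0]), 3),
            [0.0, 1.0, 1.0, 1.0, 0.0])

    @pytest.mark.parametrize("filt", [moving_average, median_filter])
    def test_constant_preserved_and_window_one_identity(self, filt):
        x = np.full(20, 4.2)
        np.testing.assert_array_equal(filt(x, 5), x)
        y = np.arange(10.0)
        np.testing.assert_array_equal(filt(y, 1), y)

    def test_median_removes_isolated_spike(self):
        x = np.full(21, 2.0)
        x[10] = 50.0
        np.testing.assert_array_equal(median_filter(x, 3), 2.0)

    def test_median_of_ramp_unchanged_in_interior(self):
        x = np.arange(15.0)
        y = median_filter(x, 3)
        np.testing.assert_array_equal(y[1:-1], x[1:-1])
        # shrinking edge windows: two-sample medians at the ends
        assert y[0] == 0.5 and y[-1] == 13.5

    @pytest.mark.parametrize("filt", [moving_average, median_filter])
    def test_commutes_with_additive_constant(self, filt):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        np.testing.assert_allclose(filt(x + 7.0, 5), filt(x, 5) + 7.0,
                                   rtol=0, atol=1e-12)

    def test_moving_average_is_linear(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=40), rng.normal(size=40)
        np.testing.assert_allclose(
            moving_average(2.0 * x + 3.0 * y, 7),
            2.0 * moving_average(x, 7) + 3.0 * moving_average(y, 7),
            atol=1e-12)

    def test_window_exceeding_length_raises(self):
        with pytest.raises(SignalError):
            moving_average(np.zeros(5), 9)


class TestPositionToRotation:
    def test_constant_position_maps_to_zero(self):
        np.testing.assert_array_equal(
            position_to_rotation(np.full(5, 3.3), 2.75), 0.0)

    def test_one_pitch_is_one_turn(self):
        phi = position_to_rotation(np.array([1.0, 1.0 + 2.75]), 2.75)
        assert phi[1] == pytest.approx(2.0 * math.pi, rel=1e-14)

    def test_thirty_mm_advance(self):
        phi = position_to_rotation(np.array([0.0, 30.0]), 2.75)
        assert phi[1] == pytest.approx(2.0 * math.pi * 30.0 / 2.75, rel=1e-14)
        assert phi[1] == pytest.approx(68.544, abs=5e-4)

    def test_invalid_pitch(self):
        with pytest.raises(SignalError):
            position_to_rotation(np.zeros(3), 0.0)


class TestCrop:
    def test_start_index_on_linear_ramp(self):
        # 0..9.9 deg in 0.1 deg steps; first sample strictly past 1 deg
        rotation = np.arange(100) * 0.1 * DEG
        trace = make_trace(np.zeros(100), rotation=rotation)
        _, start, _ = crop_recording(trace)
        assert start == 11

    def test_end_on_plateau(self):
        rotation = np.concatenate([np.linspace(0, 20 * DEG, 50),
                                   np.full(30, 20 * DEG)])
        trace = make_trace(np.zeros(80), rotation=rotation)
        cropped, start, end = crop_recording(trace)
        # first sample within 1 deg of the max
        assert rotation[end] >= 19 * DEG
        assert rotation[end - 1] < 19 * DEG
        assert len(cropped) == end - start + 1

    def test_no_motion_raises(self):
        trace = make_trace(np.zeros(50), rotation=np.zeros(50))
        with pytest.raises(NoMotionError):
            crop_recording(trace)


def ramp_trace(n_slow=40000, n_fast=1500, slow=0.01, steep=20.0, fs=1000.0,
               scale=1.0):
    """Slow linear torque rise then a much steeper rise (known onset)."""
    torque = np.concatenate([
        np.arange(n_slow) * slow,
        n_slow * slow + np.arange(1, n_fast + 1) * slow * steep,
    ]) * scale
    rotation = np.arange(n_slow + n_fast) * (math.pi / fs)  # 30 RPM
    return make_trace(torque, rotation=rotation, fs=fs), n_slow / fs


class TestTighteningOnset:
    def test_detects_slope_change_within_half_second(self):
        trace, onset_time = ramp_trace()
        idx = detect_tightening_onset(trace)
        assert abs(trace.time[idx] - onset_time) <= 0.5

    def test_constant_slope_never_crosses(self):
        trace, _ = ramp_trace(n_slow=22000, n_fast=1, steep=1.0)
        with pytest.raises(NoTighteningError):
            detect_tightening_onset(trace)

    def test_invariant_to_torque_rescaling(self):
        t1, _ = ramp_trace(scale=1.0)
        t2, _ = ramp_trace(scale=137.0)
        assert detect_tightening_onset(t1) == detect_tightening_onset(t2)

    def test_blanking_skips_engagement_spike(self):
        trace, onset_time = ramp_trace()
        # a violent spike inside the first 2 revolutions must be ignored
        torque = trace.torque.copy()
        torque[2000:2100] += 500.0
        spiked = make_trace(torque, rotation=trace.rotation)
        idx = detect_tightening_onset(spiked)
        assert abs(spiked.time[idx] - onset_time) <= 0.5


class TestStrippingTorque:
    def test_plateau_maximum(self):
        torque = np.concatenate([np.linspace(0, 3000, 5000),
                                 np.full(200, 3000.0),
                                 np.linspace(3000, 900, 2000)])
        trace = make_trace(torque)
        tau, idx = measure_true_stripping_torque(trace)
        assert tau == pytest.approx(3000.0, rel=1e-12)
        # argmax at the plateau (the filtered signal may reach the plateau
        # value one window-half early on the ramp shoulder)
        assert 4980 <= idx <= 5200

    def test_single_sample_spike_suppressed(self):
        torque = np.concatenate([np.linspace(0, 3000, 5000),
                                 np.full(200, 3000.0),
                                 np.linspace(3000, 900, 2000)])
        torque[1000] = 30000.0
        trace = make_trace(torque)
        tau, _ = measure_true_stripping_torque(trace)
        assert tau == pytest.approx(3000.0, rel=1e-12)


class TestSegmentBounds:
    def test_ordering_enforced(self):
        with pytest.raises(SignalError):
            SegmentBounds(start_idx=5, tightening_idx=4, stripping_idx=6,
                          end_idx=7)

    def test_compose_on_synthetic_phases(self):
        fs = 1000.0
        n = 35000
        rotation = np.concatenate([np.zeros(1000),
                                   np.arange(n - 1000) * (math.pi / fs)])
        torque = np.concatenate([
            np.zeros(1000),
            np.arange(30000) * 0.01,
            300.0 + np.arange(1000) * 2.0,
            np.full(500, 2300.0),
            np.linspace(2300.0, 700.0, 2500),
        ])
        trace = make_trace(torque, rotation=rotation, fs=fs)
        cropped, bounds = segment_trace(trace)
        assert bounds.start_idx < bounds.tightening_idx \
            <= bounds.stripping_idx <= bounds.end_idx
        # onset near sample 31000, stripping peak inside the plateau
        assert abs(bounds.tightening_idx - 31000) <= 500
        assert 31900 <= bounds.stripping_idx <= 32700
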