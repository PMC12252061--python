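"""Trace container, filters, cropping and phase segmentation.

A recorded insertion has four phases: engagement (narrow; the screw bites and
slips), insertion (model-governed torque growth), tightening (head contact,
steep torque rise) and stripping (peak then collapse of the formed threads).
This module crops a raw recording to the moving portion, finds the tightening
onset from the smoothed torque derivative, and extracts the empirical
stripping torque.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import NoMotionError, NoTighteningError, SignalError

__all__ = [
    "TorqueTrace",
    "SegmentBounds",
    "SegmentationParams",
    "moving_average",
    "median_filter",
    "position_to_rotation",
    "crop_recording",
    "detect_tightening_onset",
    "measure_true_stripping_torque",
    "segment_trace",
]

DEG = np.pi / 180.0


@dataclass(frozen=True)
class TorqueTrace:
    """Uniformly sampled insertion recording (internal units).

    Arrays: ``time`` (s), ``torque`` (N·mm), ``rotation`` (rad, encoder),
    ``position`` (mm, draw-wire). ``sample_rate`` (Hz) must match the time
    grid, which is validated to be uniform within 1 ppm.
    """

    time: np.ndarray
    torque: np.ndarray
    rotation: np.ndarray
    position: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        arrays = (self.time, self.torque, self.rotation, self.position)
        n = len(self.time)
        if n < 2:
            raise SignalError("trace needs at least 2 samples")
        if any(len(a) != n for a in arrays):
            raise SignalError("trace arrays must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise SignalError("time must be strictly increasing")
        mean_dt = float(dt.mean())
        if np.max(np.abs(dt - mean_dt)) > 1e-6 * mean_dt:
            raise SignalError("time grid not uniform within 1 ppm")
        if not np.isclose(self.sample_rate, 1.0 / mean_dt, rtol=1e-6):
            raise SignalError("sample_rate inconsistent with time grid")

    def __len__(self) -> int:
        return len(self.time)

    def window(self, start: int, stop: int) -> "TorqueTrace":
        """Contiguous sub-trace ``[start, stop)`` (views, not copies)."""
        if not 0 <= start < stop <= len(self):
            raise SignalError(f"bad window [{start}, {stop}) for n={len(self)}")
        return replace(self, time=self.time[start:stop],
                       torque=self.torque[start:stop],
                       rotation=self.rotation[start:stop],
                       position=self.position[start:stop])


@dataclass(frozen=True)
class SegmentBounds:
    """Phase-delimiting sample indices, all relative to the same trace."""

    start_idx: int
    tightening_idx: int
    stripping_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if not (self.start_idx < self.tightening_idx
                <= self.stripping_idx <= self.end_idx):
            raise SignalError(
                f"segment indices out of order: start={self.start_idx}, "
                f"tightening={self.tightening_idx}, "
                f"stripping={self.stripping_idx}, end={self.end_idx}")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters (defaults follow the rig protocol)."""

    start_threshold: float = 1.0 * DEG   # rad past rest before "moving"
    end_threshold: float = 1.0 * DEG     # rad short of max rotation = "stopped"
    ma_window_s: float = 1.0             # torque smoothing for the derivative
    multiplier: float = 6.0              # threshold = multiplier * percentile
    percentile: float = 90.0             # of the smoothed derivative
    median_window_s: float = 0.03        # stripping-peak median filter
    blanking_revolutions: float = 2.0    # skip engagement spikes after start


def _odd_window(window: int, n: int, name: str) -> int:
    if window < 1:
        raise SignalError(f"{name} window must be >= 1")
    if window % 2 == 0:
        window += 1  # centered filters need an odd span
    if window > n:
        raise SignalError(f"{name} window {window} exceeds signal length {n}")
    return window


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean; even windows are widened to the next odd count.

    Edges use shrinking (asymmetric) windows so output length equals input
    length and no padding values are invented.
    """
    x = np.asarray(x, dtype=float)
    window = _odd_window(int(window), x.size, "moving_average")
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def median_filter(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median with the same window/edge policy as the mean."""
    x = np.asarray(x, dtype=float)
    window = _odd_window(int(window), x.size, "median_filter")
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def position_to_rotation(position: np.ndarray, pitch: float) -> np.ndarray:
    """Equivalent rotation (rad) from axial advance: 2π·(pos − pos[0])/p.

    During engagement the encoder rotation outpaces axial advance (thread
    slip), so the draw-wire position is the reliable depth signal; this
    converts it to the rotation the model expects.
    """
    if pitch <= 0:
        raise SignalError("pitch must be > 0")
    position = np.asarray(position, dtype=float)
    return 2.0 * np.pi * (position - position[0]) / pitch


def crop_recording(
    trace: TorqueTrace,
    start_threshold: float = 1.0 * DEG,
    end_threshold: float = 1.0 * DEG,
) -> tuple[TorqueTrace, int, int]:
    """Crop to the moving portion of the recording.

    Start = first sample strictly more than ``start_threshold`` from the rest
    rotation; end = first sample within ``end_threshold`` of the maximum
    rotation (insertion stopped). Returns (cropped trace, start_idx, end_idx)
    with indices into the original trace; the crop is ``[start, end]``
    inclusive.
    """
    if start_threshold <= 0 or end_threshold <= 0:
        raise SignalError("crop thresholds must be > 0")
    rot = trace.rotation
    moved = np.abs(rot - rot[0]) > start_threshold
    if not moved.any():
        raise NoMotionError("rotation never passes the start threshold")
    start = int(np.argmax(moved))
    stopped = rot >= rot.max() - end_threshold
    end = int(np.argmax(stopped))
    if end <= start:
        raise SignalError("crop end precedes crop start")
    return trace.window(start, end + 1), start, end


def detect_tightening_onset(
    trace: TorqueTrace,
    ma_window_s: float = 1.0,
    multiplier: float = 6.0,
    percentile: float = 90.0,
    blanking_revolutions: float = 2.0,
) -> int:
    """Tightening onset index of a cropped trace.

    The torque is smoothed with a centered moving average of ``ma_window_s``
    seconds, numerically differentiated (central differences, per sample),
    and the onset is the first sample — after a blanking period of
    ``blanking_revolutions`` encoder revolutions that skips engagement
    spikes — where the derivative exceeds ``multiplier`` times its
    ``percentile``-th percentile over the whole cropped trace. The threshold
    is relative, so the detector is invariant to torque rescaling.
    """
    n = len(trace)
    window = max(1, round(ma_window_s * trace.sample_rate))
    smoothed = moving_average(trace.torque, window)
    deriv = np.gradient(smoothed)
    threshold = multiplier * np.percentile(deriv, percentile)
    blank_until = trace.rotation[0] + blanking_revolutions * 2.0 * np.pi
    eligible = (trace.rotation > blank_until) & (deriv > threshold)
    if not eligible.any():
        raise NoTighteningError(
            "torque derivative never exceeds "
            f"{multiplier:g} x P{percentile:g} after blanking")
    idx = int(np.argmax(eligible))
    if idx >= n:  # pragma: no cover - argmax bound
        raise NoTighteningError("onset past end of trace")
    return idx


def measure_true_stripping_torque(
    trace: TorqueTrace, median_window_s: float = 0.03
) -> tuple[float, int]:
    """Empirical stripping torque: max of the median-filtered torque.

    The short median filter (default 0.03 s) suppresses single-sample sensor
    spikes so the reported maximum is the mechanical peak. Returns
    (torque N·mm, argmax index).
    """
    window = max(1, round(median_window_s * trace.sample_rate))
    filtered = median_filter(trace.torque, window)
    idx = int(np.argmax(filtered))
    return float(filtered[idx]), idx


def segment_trace(
    trace: TorqueTrace, params: SegmentationParams | None = None
) -> tuple[TorqueTrace, SegmentBounds]:
    """Full segmentation: crop, tightening onset, stripping peak.

    Returns the cropped trace and bounds indexed into the *original* trace.
    The insertion segment used for identification is
    ``[start + blanking, tightening)``.
    """
    p = params or SegmentationParams()
    cropped, start, end = crop_recording(
        trace, p.start_threshold, p.end_threshold)
    onset = detect_tightening_onset(
        cropped, p.ma_window_s, p.multiplier, p.percentile,
        p.blanking_revolutions)
    _, strip = measure_true_stripping_torque(cropped, p.median_window_s)
    strip = max(strip, onset)  # a pre-onset spike cannot be the strip point
    bounds = SegmentBounds(
        start_idx=start,
        tightening_idx=start + onset,
        stripping_idx=start + strip,
        end_idx=end,
    )
    return cropped, bounds
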