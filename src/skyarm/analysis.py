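"""Kinematic evaluation pipeline: filtering, jerk and amplitude metrics.

Simulated and measured marker trajectories are scored identically:

1. zero-phase second-order Butterworth low-pass filter (5 Hz cut-off at
   100 Hz sampling by default);
2. jerk as the third central finite difference of position, low-pass
   filtered again;
3. all series divided into drive cycles and averaged phase-locked to the
   known oscillation frequency;
4. mean sum of squared jerk per arm part over the mean cycle, and the
   amplitude (half peak-to-peak per direction) of the mean one-cycle
   hand trajectory.

Jerk — the third time derivative of position — is the vibration metric:
a hand that is well isolated from the shaking base has a smaller mean
squared jerk than the base itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from numpy.typing import NDArray

from .simulate import PARTS, OscillationSpec, TrajectoryRecord

__all__ = [
    "JerkSummary",
    "AmplitudeSummary",
    "lowpass",
    "jerk_series",
    "jerk_times",
    "mean_sum_squared_jerk",
    "cycle_average",
    "trajectory_amplitude",
    "analyze_record",
    "summary_frame",
]

#: samples trimmed from each end by the three central-difference stencils
JERK_TRIM = 3

#: phase samples in the averaged one-cycle trajectory
CYCLE_SAMPLES = 128


@dataclass(frozen=True)
class JerkSummary:
    """Mean sum of squared jerk [m²/s⁶] per arm part over the window."""

    shoulder: float
    elbow: float
    wrist: float
    hand: float

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARTS}


@dataclass(frozen=True)
class AmplitudeSummary:
    """Amplitude of the mean one-cycle hand trajectory, per direction.

    ``horizontal``/``vertical`` are half peak-to-peak (the convention in
    which a sinusoid A·sin(ωt) has amplitude A); the full peak-to-peak
    ranges are also kept since "amplitude" is ambiguous in parts of the
    motor-control literature.
    """

    horizontal: float
    vertical: float
    horizontal_peak_to_peak: float
    vertical_peak_to_peak: float


def lowpass(series: NDArray, cutoff: float = 5.0, rate: float = 100.0) -> NDArray:
    """Zero-phase (forward–backward) second-order Butterworth low-pass.

    Accepts a 1-D series or a (T, d) array filtered column-wise.
    """
    if rate <= 2.0 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz must exceed twice the cutoff {cutoff} Hz")
    arr = np.asarray(series, dtype=float)
    b, a = signal.butter(2, cutoff, fs=rate)
    padlen = 3 * max(len(a), len(b))
    if arr.shape[0] <= padlen:
        raise ValueError(
            f"series too short for filtering: {arr.shape[0]} samples <= padlen {padlen}"
        )
    return signal.filtfilt(b, a, arr, axis=0)


def _central_diff(arr: NDArray, rate: float) -> NDArray:
    """(x[i+1] − x[i−1]) / (2 dt); trims one sample from each end."""
    return (arr[2:] - arr[:-2]) * (0.5 * rate)


def jerk_series(positions: NDArray, rate: float = 100.0, cutoff: float = 5.0) -> NDArray:
    """Jerk [m/s³] of a position series via filter → d³/dt³ → filter.

    The third derivative is three applications of the central first
    difference (exact for cubic polynomials); the stencil loses
    ``JERK_TRIM`` samples at each end, so the output has ``T − 6`` rows
    aligned with ``jerk_times``.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2 * JERK_TRIM + 10:
        raise ValueError(f"position series too short for jerk: {pos.shape[0]} samples")
    smooth = lowpass(pos, cutoff=cutoff, rate=rate)
    d3 = _central_diff(_central_diff(_central_diff(smooth, rate), rate), rate)
    return lowpass(d3, cutoff=cutoff, rate=rate)


def jerk_times(time: NDArray) -> NDArray:
    """Time stamps matching ``jerk_series`` output (interior samples)."""
    return np.asarray(time, dtype=float)[JERK_TRIM:-JERK_TRIM]


def mean_sum_squared_jerk(
    jerk: NDArray, time: NDArray, window: tuple[float, float]
) -> float:
    """Time-average of ``j_x² + j_y²`` over ``window`` [m²/s⁶]."""
    j = np.atleast_2d(np.asarray(jerk, dtype=float).T).T
    t = np.asarray(time, dtype=float)
    if j.shape[0] != t.shape[0]:
        raise ValueError("jerk and time must have equal length")
    mask = (t >= window[0]) & (t <= window[1])
    if not np.any(mask):
        raise ValueError(f"window {window} contains no samples")
    return float(np.mean(np.sum(j[mask] ** 2, axis=1)))


def cycle_average(
    positions: NDArray,
    time: NDArray,
    spec: OscillationSpec,
    window: tuple[float, float],
    n_phase: int = CYCLE_SAMPLES,
) -> NDArray:
    """Mean one-cycle trajectory, phase-locked to the drive oscillation.

    The window is cut into consecutive whole periods 1/frequency starting
    at its left edge, each period is resampled (linear interpolation)
    onto a common phase grid of ``n_phase`` points, and the cycles are
    averaged pointwise.  Requires at least five whole cycles.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float).T).T
    t = np.asarray(time, dtype=float)
    period = 1.0 / spec.frequency
    t0, t1 = window
    n_cycles = int(np.floor((t1 - t0) / period))
    if n_cycles < 5:
        raise ValueError(f"window {window} spans only {n_cycles} cycles; need >= 5")
    phase = np.arange(n_phase) / n_phase  # [0, 1)
    out = np.zeros((n_phase, pos.shape[1]))
    for i in range(n_cycles):
        sample_t = t0 + (i + phase) * period
        for d in range(pos.shape[1]):
            out[:, d] += np.interp(sample_t, t, pos[:, d])
    out /= n_cycles
    return out


def trajectory_amplitude(mean_cycle: NDArray) -> AmplitudeSummary:
    """Per-direction amplitude of a mean one-cycle trajectory."""
    cyc = np.atleast_2d(np.asarray(mean_cycle, dtype=float).T).T
    if cyc.shape[0] == 0:
        raise ValueError("mean cycle is empty")
    span = cyc.max(axis=0) - cyc.min(axis=0)
    return AmplitudeSummary(
        horizontal=float(span[0] / 2),
        vertical=float(span[1] / 2) if span.shape[0] > 1 else 0.0,
        horizontal_peak_to_peak=float(span[0]),
        vertical_peak_to_peak=float(span[1]) if span.shape[0] > 1 else 0.0,
    )


def analyze_record(
    record: TrajectoryRecord,
    spec: OscillationSpec,
    window: tuple[float, float] = (30.0, 90.0),
    cutoff: float = 5.0,
) -> tuple[JerkSummary, AmplitudeSummary]:
    """Full pipeline on one trajectory record.

    Returns the per-part jerk summary and the hand-trajectory amplitude,
    both computed from mean one-cycle data over the steady-state window:
    every series (jerk included) is divided into drive cycles and
    averaged phase-locked before the metric is taken, so components that
    are not phase-locked to the oscillation — measurement noise above
    all — average out instead of biasing the squared-jerk metric.
    """
    rate = record.rate
    jt = jerk_times(record.time)
    jerks = {}
    for part in PARTS:
        j = jerk_series(record.positions[part], rate=rate, cutoff=cutoff)
        mean_j = cycle_average(j, jt, spec, window)
        jerks[part] = float(np.mean(np.sum(mean_j**2, axis=1)))
    mean_cycle = cycle_average(record.positions["hand"], record.time, spec, window)
    return JerkSummary(**jerks), trajectory_amplitude(mean_cycle)


def summary_frame(jerk: JerkSummary, amplitude: AmplitudeSummary) -> pd.DataFrame:
    """Tabular summary: one row per arm part plus amplitude rows."""
    rows = [
        {"quantity": "mean_sum_squared_jerk", "item": part, "value": val, "units": "m^2/s^6"}
        for part, val in jerk.as_dict().items()
    ]
    rows += [
        {"quantity": "hand_amplitude", "item": "horizontal", "value": amplitude.horizontal, "units": "m"},
        {"quantity": "hand_amplitude", "item": "vertical", "value": amplitude.vertical, "units": "m"},
        {"quantity": "hand_peak_to_peak", "item": "horizontal", "value": amplitude.horizontal_peak_to_peak, "units": "m"},
        {"quantity": "hand_peak_to_peak", "item": "vertical", "value": amplitude.vertical_peak_to_peak, "units": "m"},
    ]
    return pd.DataFrame(rows)
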