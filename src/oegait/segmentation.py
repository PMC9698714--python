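"""Step detection, steady-state window selection and dominant-period estimation.

A trunk IMU cannot observe foot-ground contact directly; steps are taken as
the prominent peaks of the band-passed vertical acceleration, which fires
once per step.  Steady-state selection drops the first two and last two
steps of each walking bout (gait initiation/termination transients) and, for
out-and-back walkway protocols, splits the walk at the turn and excludes a
guard window around it.  Energy averages are taken over an integer number of
strides so that the zero-mean cross terms cancel exactly, so every segment's
end is snapped to a stride boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .errors import (DegenerateInputError, InsufficientDataError,
                     InsufficientGaitError, ParameterError)

DEFAULT_PROMINENCE = 0.5     # m/s^2
DEFAULT_MIN_SEPARATION = 0.25  # s; no human step is faster
TRIM_STEPS = 2               # steps dropped at each end of a bout
TURN_GUARD_S = 1.0           # hard exclusion around a detected turn


@dataclass
class GaitSegment:
    """A steady-state walking window spanning an integer number of strides."""

    start_s: float
    end_s: float                 # snapped to start_s + n_periods * stride_period
    step_events: np.ndarray      # kept (trimmed) step event times, s
    step_period: float           # mean step time T, s
    n_periods: int               # number of strides (ML cycles) in [start, end]
    bout_events: np.ndarray | None = None  # untrimmed events of the walking bout

    def __post_init__(self) -> None:
        self.step_events = np.asarray(self.step_events, dtype=float)
        if self.bout_events is None:
            self.bout_events = self.step_events
        else:
            self.bout_events = np.asarray(self.bout_events, dtype=float)
        if self.step_events.size < 4:
            raise InsufficientGaitError("segment needs >= 4 step events")
        if not (0.2 < self.step_period < 2.0):
            raise InsufficientGaitError(
                f"step period {self.step_period:.3f} s outside (0.2, 2) s")

    @property
    def stride_period(self) -> float:
        return 2.0 * self.step_period

    @property
    def n_steps(self) -> int:
        return int(self.step_events.size)

    def sample_slice(self, t: np.ndarray) -> slice:
        """Index slice of [start_s, end_s) in the time base ``t``."""
        i0 = int(np.searchsorted(t, self.start_s, side="left"))
        i1 = int(np.searchsorted(t, self.end_s, side="left"))
        return slice(i0, i1)

    def stride_boundaries(self) -> np.ndarray:
        """Times of the stride boundaries spanning the segment."""
        return self.start_s + self.stride_period * np.arange(self.n_periods + 1)


def detect_steps(accel_vt: np.ndarray, rate: float, *,
                 prominence: float = DEFAULT_PROMINENCE,
                 min_separation: float = DEFAULT_MIN_SEPARATION) -> np.ndarray:
    """Step event times from peaks of band-passed vertical acceleration.

    Returns one event per step.  Raises InsufficientGaitError when fewer
    than four peaks are found (no usable gait in the recording).
    """
    accel_vt = np.asarray(accel_vt, dtype=float)
    peaks, _ = _sig.find_peaks(accel_vt, prominence=prominence,
                               distance=max(1, int(round(min_separation * rate))))
    if peaks.size < 4:
        raise InsufficientGaitError(
            f"only {peaks.size} step events detected (need >= 4)")
    return peaks / rate


def _smoothed_speed_envelope(ap_velocity: np.ndarray, rate: float) -> np.ndarray:
    """Moving-average |AP oscillatory velocity| over ~1 s windows."""
    win = max(1, int(round(rate)))
    kernel = np.ones(win) / win
    return np.convolve(np.abs(ap_velocity), kernel, mode="same")


def _detect_turn_time(ap_velocity: np.ndarray, t: np.ndarray, rate: float) -> float:
    """Turn = minimum of the smoothed AP speed envelope near mid-recording."""
    env = _smoothed_speed_envelope(ap_velocity, rate)
    n = env.size
    lo, hi = int(0.2 * n), int(0.8 * n)
    return float(t[lo + int(np.argmin(env[lo:hi]))])


def _build_segment(events: np.ndarray, t_end: float,
                   bout_events: np.ndarray | None = None) -> GaitSegment:
    events = np.asarray(events, dtype=float)
    step_period = float(np.mean(np.diff(events)))
    stride = 2.0 * step_period
    start = float(events[0])
    span = float(events[-1] - events[0])
    n = int(round(span / stride)) if span > 0 else 0
    n = max(n, 1)
    while start + n * stride > t_end and n > 1:
        n -= 1
    return GaitSegment(start_s=start, end_s=start + n * stride,
                       step_events=events, step_period=step_period,
                       n_periods=n, bout_events=bout_events)


def select_steady_state(recording_span: tuple[float, float],
                        step_events: np.ndarray,
                        turn_policy: str = "none", *,
                        turn_time: float | None = None,
                        ap_velocity: np.ndarray | None = None,
                        t: np.ndarray | None = None,
                        rate: float | None = None,
                        trim_steps: int = TRIM_STEPS,
                        min_strides: int = 2,
                        turn_guard_s: float = TURN_GUARD_S) -> list[GaitSegment]:
    """Select steady-state gait segments from detected step events.

    ``turn_policy``:
      * ``"none"``  — single walking bout; trim ``trim_steps`` steps at each end.
      * ``"time"``  — out-and-back walk; split at ``turn_time``.
      * ``"auto"``  — out-and-back; the turn is found as the minimum of the
        smoothed AP-velocity magnitude near mid-recording (requires
        ``ap_velocity``, ``t`` and ``rate``).

    Steps inside ±``turn_guard_s`` of the turn are discarded outright before
    the per-half trimming.
    """
    events = np.asarray(step_events, dtype=float)
    t_end = float(recording_span[1])

    if turn_policy == "none":
        halves = [events]
    elif turn_policy in ("time", "auto"):
        if turn_policy == "auto":
            if ap_velocity is None or t is None or rate is None:
                raise ParameterError("turn_policy='auto' needs ap_velocity, t, rate")
            turn_time = _detect_turn_time(np.asarray(ap_velocity), np.asarray(t), rate)
        if turn_time is None:
            raise ParameterError("turn_policy='time' needs turn_time")
        keep = np.abs(events - turn_time) > turn_guard_s
        halves = [events[keep & (events < turn_time)],
                  events[keep & (events > turn_time)]]
    else:
        raise ParameterError(f"unknown turn_policy {turn_policy!r}")

    segments: list[GaitSegment] = []
    for half in halves:
        if half.size <= 2 * trim_steps:
            continue
        kept = half[trim_steps:half.size - trim_steps]
        if kept.size < 4 or (kept.size - 1) < 2 * min_strides:
            continue
        segments.append(_build_segment(kept, t_end, bout_events=half))
    if not segments:
        raise InsufficientGaitError(
            "no steady-state segment left after trimming "
            f"({events.size} steps detected)")
    return segments


def dominant_periods(vel, segment: GaitSegment, *,
                     f_lo: float = 0.3, f_hi: float = 5.0,
                     min_strides: int = 8,
                     axes: tuple[str, ...] = ("ap", "ml", "vt")) -> dict[str, float]:
    """Per-axis dominant oscillation period within the segment, in seconds.

    The period is the inverse of the frequency of the largest spectral peak
    of the oscillatory velocity in [f_lo, f_hi] Hz, refined by quadratic
    interpolation around the peak bin of a zero-padded, Hann-windowed FFT.
    In normal gait the ML period equals the stride period and the VT/AP
    periods equal the step period (half the stride).
    """
    if segment.n_periods < min_strides:
        raise InsufficientDataError(
            f"dominant_periods needs >= {min_strides} strides, "
            f"segment has {segment.n_periods}")
    sl = segment.sample_slice(vel.t)
    fs = 1.0 / vel.dt
    out: dict[str, float] = {}
    for axis in axes:
        x = vel.component(axis)[sl]
        x = (x - x.mean()) * np.hanning(x.size)
        nfft = int(2 ** np.ceil(np.log2(x.size * 8)))
        spec = np.abs(np.fft.rfft(x, nfft))
        freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
        band = (freqs >= f_lo) & (freqs <= f_hi)
        mag = spec[band]
        if mag.size < 3 or mag.max() <= 10.0 * np.median(mag):
            raise DegenerateInputError(
                f"no dominant spectral peak above the noise floor on axis {axis}")
        k = int(np.argmax(mag))
        k = min(max(k, 1), mag.size - 2)
        # quadratic vertex through the three bins around the maximum
        y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        f_peak = freqs[band][k] + delta * (freqs[1] - freqs[0])
        out[axis] = 1.0 / float(f_peak)
    return out
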