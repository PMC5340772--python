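"""Evoked field-potential quantification and LTP time courses.

Two standard measures are taken from each sweep:

* fEPSP slope — the maximum slope (mV/ms) of a sliding 1 ms linear fit on the
  initial rising phase, reported as a magnitude;
* population-spike amplitude — the vertical distance from the line joining the
  two positive peaks flanking the spike to the spike minimum (tangent method).

Time courses average five sweeps per time point and normalize each series so
the mean of the six baseline points is 100%. Stimulation intensity for an
experiment is the tested intensity whose input-output response is closest to
40% of the maximum response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.signal import savgol_filter

from .synth import EvokedSweep

__all__ = [
    "fepsp_slope",
    "ps_amplitude",
    "io_select_intensity",
    "LTPTimecourse",
    "ltp_timecourse",
    "normalize_to_baseline",
    "fit_plasticity",
]

logger = logging.getLogger(__name__)


def _smoothed(x: np.ndarray, fs_hz: float, window_ms: float = 0.7) -> np.ndarray:
    """Savitzky-Golay (order 2) smoothing; preserves linear segments exactly."""
    win = int(round(window_ms * fs_hz / 1000.0))
    win = max(5, win + 1 if win % 2 == 0 else win)
    if win >= len(x):
        return x
    return savgol_filter(x, win, polyorder=2)


def _tent_vertex(raw: np.ndarray, idx: int, fs_hz: float,
                 inner_ms: float = 0.2, outer_ms: float = 0.8) -> tuple[float, float]:
    """Refine an extremum as the intersection of its two flank lines.

    Fits a least-squares line to each flank of the approximately located
    extremum and intersects them: exact for piecewise-linear extrema and
    noise-averaging otherwise. Returns (index position, value); falls back to
    the raw sample when the flanks are nearly parallel or truncated.
    """
    n_in = max(1, int(round(inner_ms * fs_hz / 1000.0)))
    n_out = max(n_in + 2, int(round(outer_ms * fs_hz / 1000.0)))
    lo, hi = idx - n_out, idx + n_out + 1
    if lo < 0 or hi > len(raw):
        return float(idx), float(raw[idx])
    xl = np.arange(idx - n_out, idx - n_in + 1)
    xr = np.arange(idx + n_in, idx + n_out + 1)
    ml, bl = np.polyfit(xl, raw[xl], 1)
    mr, br = np.polyfit(xr, raw[xr], 1)
    if abs(ml - mr) < 1e-12:
        return float(idx), float(raw[idx])
    x_star = (br - bl) / (ml - mr)
    if not (idx - n_out <= x_star <= idx + n_out):
        return float(idx), float(raw[idx])
    return float(x_star), float(ml * x_star + bl)


def fepsp_slope(sweep: EvokedSweep, fit_window_ms: float = 1.0,
                search_ms: float = 10.0) -> float:
    """Maximum 1 ms sliding-fit slope (mV/ms) of the initial rising phase.

    1 ms least-squares lines slide over the raw samples between the stimulus
    and the first major positive peak (located on a lightly smoothed copy).
    The reported value is the median of the upper half of the sliding slopes:
    on a linear rising segment every interior window estimates the same
    maximal slope, so this equals the strict maximum noise-free while avoiding
    its upward selection bias on noisy sweeps. Raises if no rising phase is
    found.
    """
    fs = sweep.fs_hz
    i_stim = int(round(sweep.stim_time_s * fs))
    i_end = min(len(sweep.samples), i_stim + int(round(search_ms * fs / 1000.0)))
    raw = sweep.samples[i_stim:i_end]
    seg = _smoothed(sweep.samples, fs)[i_stim:i_end]
    if len(seg) < 4:
        raise ValueError("sweep too short after the stimulus")
    i_peak = int(np.argmax(seg))
    if i_peak < 2 or seg[i_peak] <= 0:
        raise ValueError("no rising phase found after the stimulus")
    n_fit = max(3, int(round(fit_window_ms * fs / 1000.0)) + 1)
    rise = raw[: i_peak + 1]
    if len(rise) < n_fit:
        n_fit = len(rise)
    t_ms = np.arange(n_fit) / fs * 1000.0
    t_c = t_ms - t_ms.mean()
    denom = float(t_c @ t_c)
    slopes = np.array([
        float(t_c @ (rise[s:s + n_fit] - rise[s:s + n_fit].mean())) / denom
        for s in range(0, len(rise) - n_fit + 1)
    ])
    top = np.sort(slopes)[-max(1, len(slopes) // 2):]
    best = float(np.median(top))
    if best <= 0:
        raise ValueError("no positive-going rising segment found")
    return best


def ps_amplitude(sweep: EvokedSweep, search_ms: float = 15.0,
                 min_prominence_frac: float = 0.05,
                 locate_smooth_ms: float = 1.5) -> float:
    """Population-spike amplitude (mV) by the tangent method.

    Locates the first positive peak, the subsequent spike minimum and the
    second positive peak on a lightly smoothed copy, then measures from the
    line joining the two peaks down to the minimum (values read from the raw
    sweep at the located samples). Raises when no spike trough flanked by two
    positive peaks exists.
    """
    from scipy.signal import find_peaks

    fs = sweep.fs_hz
    i_stim = int(round(sweep.stim_time_s * fs))
    i_end = min(len(sweep.samples), i_stim + int(round(search_ms * fs / 1000.0)))
    raw = sweep.samples[i_stim:i_end]
    seg = _smoothed(sweep.samples, fs, locate_smooth_ms)[i_stim:i_end]
    rng_amp = float(seg.max() - seg.min())
    if rng_amp <= 0:
        raise ValueError("flat sweep: no evoked response")
    peaks, _ = find_peaks(seg, prominence=min_prominence_frac * rng_amp)
    if len(peaks) < 2:
        raise ValueError("no spike minimum between two flanking positive peaks")
    # first peak = highest; second = most prominent later peak with a dip between
    p1 = int(peaks[np.argmax(seg[peaks])])
    later = peaks[peaks > p1]
    if len(later) == 0:
        p1 = int(peaks[0])
        later = peaks[peaks > p1]
        if len(later) == 0:
            raise ValueError("no spike minimum between two flanking positive peaks")
    p2 = int(later[0])
    trough = p1 + int(np.argmin(seg[p1:p2 + 1]))
    if trough in (p1, p2):
        raise ValueError("no local minimum between the flanking peaks")
    x1, v1 = _tent_vertex(raw, p1, fs)
    x2, v2 = _tent_vertex(raw, p2, fs)
    xt, vt = _tent_vertex(raw, trough, fs)
    line_at_trough = v1 + (v2 - v1) * (xt - x1) / (x2 - x1)
    amp = line_at_trough - vt
    if amp <= 0:
        raise ValueError("trough does not undercut the line joining the flanking peaks")
    return amp


def io_select_intensity(responses: Mapping[float, float], target_frac: float = 0.40) -> float:
    """Stimulation intensity whose response is closest to 40% of the maximum.

    ``responses`` maps tested intensity (uA) to response magnitude. Ties go to
    the lower intensity; all-zero responses are rejected.
    """
    if len(responses) < 2:
        raise ValueError("need responses at >= 2 intensities")
    if any(v < 0 for v in responses.values()):
        raise ValueError("responses must be non-negative")
    max_resp = max(responses.values())
    if max_resp == 0:
        raise ValueError("all responses are zero")
    target = target_frac * max_resp
    best = min(sorted(responses), key=lambda ua: (abs(responses[ua] - target), ua))
    return best


@dataclass
class LTPTimecourse:
    """Baseline-normalized evoked measures over the recording schedule."""

    timepoints_min: list[float]
    fepsp_pct: list[float]
    ps_pct: list[float]
    n_sweeps_per_point: int
    baseline_points: int
    dropped_timepoints: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.timepoints_min, "fepsp_pct": self.fepsp_pct,
                             "ps_pct": self.ps_pct})

    def value_at(self, t_min: float, series: str = "fepsp_pct") -> float:
        arr = np.asarray(self.timepoints_min)
        i = int(np.argmin(np.abs(arr - t_min)))
        return getattr(self, series)[i]


def ltp_timecourse(sweeps: Sequence[tuple[float, Sequence[EvokedSweep]]],
                   n_sweeps_per_point: int = 5,
                   baseline_points: int = 6) -> LTPTimecourse:
    """Build an LTP time course from (time_min, sweeps) pairs.

    Each point is the mean measure of its sweeps; both series are normalized
    so the mean of the ``baseline_points`` earliest (pre-HFS) points is 100%.
    Points where a sweep fails to yield a measure are dropped with a log entry.
    """
    t_out, slopes, amps, dropped = [], [], [], []
    for t_min, point in sorted(sweeps, key=lambda p: p[0]):
        if len(point) < n_sweeps_per_point:
            logger.warning("timepoint %.1f min: only %d sweeps, dropped", t_min, len(point))
            dropped.append(t_min)
            continue
        try:
            s = float(np.mean([fepsp_slope(sw) for sw in point]))
            a = float(np.mean([ps_amplitude(sw) for sw in point]))
        except ValueError as err:
            logger.warning("timepoint %.1f min dropped: %s", t_min, err)
            dropped.append(t_min)
            continue
        t_out.append(t_min)
        slopes.append(s)
        amps.append(a)
    n_base = sum(1 for t in t_out if t < 0)
    if n_base < baseline_points:
        raise ValueError(f"need >= {baseline_points} baseline time points, got {n_base}")
    return LTPTimecourse(
        timepoints_min=t_out,
        fepsp_pct=normalize_to_baseline(slopes, baseline_points),
        ps_pct=normalize_to_baseline(amps, baseline_points),
        n_sweeps_per_point=n_sweeps_per_point,
        baseline_points=baseline_points,
        dropped_timepoints=dropped,
    )


def normalize_to_baseline(values: Sequence[float], baseline_points: int = 6) -> list[float]:
    """Express a series as % of the mean of its first ``baseline_points`` values.

    Idempotent: applying it to an already-normalized series is the identity.
    """
    if len(values) < baseline_points:
        raise ValueError(f"need >= {baseline_points} values")
    base = float(np.mean(values[:baseline_points]))
    if base <= 0:
        raise ValueError("non-positive baseline mean")
    return [100.0 * v / base for v in values]


def fit_plasticity(timecourse: LTPTimecourse, series: str = "fepsp_pct",
                   max_tau_min: float = 1e5) -> tuple[float, float]:
    """Least-squares recovery of (potentiation_factor, decay_tau_min).

    Fits ``f(t) = 1 + (P - 1) exp(-t / tau)`` to the post-HFS fraction-of-
    baseline series. A tau at the ``max_tau_min`` bound indicates persistent
    potentiation within the fitted horizon.
    """
    t = np.asarray([tm for tm in timecourse.timepoints_min if tm >= 0], dtype=float)
    y = np.asarray([v / 100.0 for tm, v in zip(timecourse.timepoints_min,
                                               getattr(timecourse, series)) if tm >= 0])
    if len(t) < 3:
        raise ValueError("need >= 3 post-HFS points to fit the decay model")

    def model(tt, p, tau):
        return 1.0 + (p - 1.0) * np.exp(-tt / tau)

    p0 = (max(float(y.max()), 1.01), 200.0)
    popt, _ = optimize.curve_fit(model, t, y, p0=p0,
                                 bounds=([1.0, 1.0], [10.0, max_tau_min]), maxfev=10000)
    return float(popt[0]), float(popt[1])
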