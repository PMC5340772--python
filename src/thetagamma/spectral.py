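"""Notch filtering, FFT power spectra and baseline-relative band power.

Band power is summarized per canonical band (delta 2-4, theta 4-10, alpha
10-12, beta 12-28, gamma 30-100 Hz; half-open intervals [low, high) so the
shared endpoints are unambiguous) and expressed both absolutely (V^2 scale,
here uV^2/Hz means over the band) and as a percentage of the pre-HFS baseline
window — the baseline is 100% per band by construction. Individual theta
frequencies (5-10 Hz integers) are profiled the same way against the same
frequency in baseline.

Spectra are Welch estimates with a Hann taper and NFFT = 2048; the mains
notch is a zero-phase (forward-backward) Butterworth band-stop designed at
48.5-55 Hz, applied before any spectral or coupling analysis since the
coupling measure downstream is phase-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import Epoch

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "PowerSpectrum",
    "notch_filter",
    "power_spectrum",
    "band_power",
    "epoch_band_powers",
    "relative_power",
    "band_power_table",
    "theta_profile",
    "THETA_PROFILE_FREQS",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"band {self.name!r} needs 0 < f_low < f_high, "
                             f"got [{self.f_low}, {self.f_high})")


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 10.0),
    BandDefinition("alpha", 10.0, 12.0),
    BandDefinition("beta", 12.0, 28.0),
    BandDefinition("gamma", 30.0, 100.0),
)

THETA_PROFILE_FREQS: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0, 9.0, 10.0)

NOTCH_BAND_HZ = (48.5, 55.0)


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on an NFFT grid."""

    freqs: np.ndarray
    power: np.ndarray
    nfft: int
    fs_hz: float

    @property
    def df(self) -> float:
        return self.fs_hz / self.nfft

    def total_power(self) -> float:
        """Integrated PSD (approximates signal variance, Parseval)."""
        return float(np.sum(self.power) * self.df)


def notch_filter(samples: np.ndarray, fs_hz: float,
                 band_hz: tuple[float, float] = NOTCH_BAND_HZ, order: int = 2) -> np.ndarray:
    """Zero-phase IIR band-stop around the mains frequency.

    Butterworth design with the stated band edges, applied forward-backward
    (filtfilt) so net phase distortion is zero and output length equals input
    length.
    """
    if fs_hz <= 2.0 * band_hz[1]:
        raise ValueError(f"fs_hz={fs_hz} too low for a band-stop up to {band_hz[1]} Hz")
    x = np.asarray(samples, dtype=float)
    sos = sps.butter(order, band_hz, btype="bandstop", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def power_spectrum(samples: np.ndarray | Epoch, fs_hz: float | None = None,
                   nfft: int = 2048) -> PowerSpectrum:
    """Welch PSD (Hann taper, 50% overlap, NFFT-point grid).

    Signals longer than NFFT are segment-averaged; shorter ones are
    zero-padded to the NFFT grid.
    """
    if isinstance(samples, Epoch):
        fs_hz = samples.fs_hz
        x = samples.samples
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when samples is a plain array")
        x = np.asarray(samples, dtype=float)
    if nfft <= 0:
        raise ValueError(f"nfft must be positive, got {nfft}")
    if len(x) == 0:
        raise ValueError("empty signal")
    nperseg = min(nfft, len(x))
    freqs, pxx = sps.welch(x, fs=fs_hz, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, nfft=nfft, detrend="constant",
                           scaling="density")
    return PowerSpectrum(freqs=freqs, power=pxx, nfft=nfft, fs_hz=float(fs_hz))


def band_power(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Mean PSD over the half-open band [f_low, f_high)."""
    sel = (spectrum.freqs >= band.f_low) & (spectrum.freqs < band.f_high)
    if not np.any(sel):
        raise ValueError(f"no spectral bins fall inside band {band.name!r} "
                         f"[{band.f_low}, {band.f_high}) Hz")
    return float(np.mean(spectrum.power[sel]))


def epoch_band_powers(epochs: Sequence[Epoch],
                      bands: Sequence[BandDefinition] = CANONICAL_BANDS,
                      nfft: int = 2048, notch: bool = True) -> pd.DataFrame:
    """Per-epoch absolute band power (long table).

    Columns: window, sub_window_index, band, absolute_power.
    """
    rows = []
    for ep in epochs:
        x = notch_filter(ep.samples, ep.fs_hz) if notch else ep.samples
        spec = power_spectrum(x, ep.fs_hz, nfft=nfft)
        for band in bands:
            rows.append({
                "window": ep.window_label,
                "sub_window_index": ep.sub_window_index,
                "band": band.name,
                "absolute_power": band_power(spec, band),
            })
    return pd.DataFrame(rows)


def relative_power(window_rows: pd.DataFrame, baseline_rows: pd.DataFrame) -> pd.DataFrame:
    """Baseline-relative band power per window.

    ``relative_pct = 100 * mean(window epochs) / mean(baseline epochs)`` per
    band; errors if any baseline band power is zero. Input frames are
    epoch-level tables as produced by :func:`epoch_band_powers`.
    """
    base = baseline_rows.groupby("band")["absolute_power"].mean()
    for band_name, val in base.items():
        if val <= 0:
            raise ValueError(f"zero baseline power in band {band_name!r}")
    mean = (window_rows.groupby(["window", "band"], as_index=False)["absolute_power"]
            .mean().rename(columns={"absolute_power": "absolute_power_v2"}))
    mean["relative_power_pct"] = [
        100.0 * row.absolute_power_v2 / base[row.band] for row in mean.itertuples()
    ]
    return mean


def band_power_table(epochs_by_window: Mapping[str, Sequence[Epoch]],
                     bands: Sequence[BandDefinition] = CANONICAL_BANDS,
                     nfft: int = 2048, notch: bool = True,
                     baseline_label: str = "pre") -> pd.DataFrame:
    """Absolute and baseline-relative band power for all analysis windows."""
    if baseline_label not in epochs_by_window:
        raise ValueError(f"baseline window {baseline_label!r} missing")
    all_rows = pd.concat(
        [epoch_band_powers(eps, bands=bands, nfft=nfft, notch=notch)
         for eps in epochs_by_window.values()],
        ignore_index=True,
    )
    baseline_rows = all_rows[all_rows["window"] == baseline_label]
    return relative_power(all_rows, baseline_rows)


def theta_profile(epochs_by_window: Mapping[str, Sequence[Epoch]],
                  frequencies: Iterable[float] = THETA_PROFILE_FREQS,
                  half_width_hz: float = 0.5, nfft: int = 2048,
                  notch: bool = True, baseline_label: str = "pre") -> pd.DataFrame:
    """Relative power of individual theta frequencies vs the baseline window.

    Per-frequency power is the mean of PSD bins within ``half_width_hz`` of the
    frequency, normalized to that same frequency's baseline value (in %).
    Requires spectral resolution fs/nfft <= 1 Hz.
    """
    freqs = list(frequencies)
    if baseline_label not in epochs_by_window:
        raise ValueError(f"baseline window {baseline_label!r} missing")

    def _window_means(eps: Sequence[Epoch]) -> dict[float, float]:
        per_freq: dict[float, list[float]] = {f: [] for f in freqs}
        for ep in eps:
            if ep.fs_hz / nfft > 1.0 + 1e-9:
                raise ValueError(
                    f"spectral resolution {ep.fs_hz / nfft:.2f} Hz too coarse for a "
                    "per-frequency theta profile (need <= 1 Hz)"
                )
            x = notch_filter(ep.samples, ep.fs_hz) if notch else ep.samples
            spec = power_spectrum(x, ep.fs_hz, nfft=nfft)
            for f in freqs:
                sel = np.abs(spec.freqs - f) <= half_width_hz
                if not np.any(sel):
                    raise ValueError(f"no spectral bins within {half_width_hz} Hz of {f} Hz")
                per_freq[f].append(float(np.mean(spec.power[sel])))
        return {f: float(np.mean(v)) for f, v in per_freq.items()}

    base = _window_means(epochs_by_window[baseline_label])
    for f, val in base.items():
        if val <= 0:
            raise ValueError(f"zero baseline power at {f} Hz")
    rows = []
    for label, eps in epochs_by_window.items():
        means = base if label == baseline_label else _window_means(eps)
        for f in freqs:
            rows.append({"window": label, "freq_hz": f,
                         "absolute_power_v2": means[f],
                         "relative_power_pct": 100.0 * means[f] / base[f]})
    return pd.DataFrame(rows)
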