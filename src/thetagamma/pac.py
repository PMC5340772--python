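"""Envelope-to-signal-correlation (ESC) phase-amplitude coupling.

ESC measures cross-frequency coupling as the Pearson correlation between the
low-frequency *filtered signal* and the *amplitude envelope* of a faster band.
Both are obtained from a complex Morlet wavelet filter bank (default width 7
cycles): the real part of the convolution is the band-filtered signal, its
magnitude the instantaneous amplitude. Raw ESC is a signed correlation in
[-1, 1]; a positive score means the fast envelope is largest near the slow
wave's positive peak.

Raw scores are normalized against a surrogate null built by circular block
shuffling of the envelope (cut at a random point, swap the two segments):
this preserves the envelope's autocorrelation while destroying its alignment
with the slow wave. The reported score is z = (raw - mean_surr) / sd_surr.

Comodulograms evaluate every ordered pair on a grid of center-frequency bins
(full grid 3-98 Hz in 5 Hz steps, +/- 2 Hz nominal bin half-width; gamma grid
33-98 Hz). Only pairs with slow center < fast center are computed; the rest
are null markers. Wavelet edge cones (one temporal SD of the slower wavelet)
are trimmed before correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Epoch

__all__ = [
    "WaveletSpec",
    "FrequencyBinGrid",
    "FULL_GRID",
    "GAMMA_GRID",
    "Comodulogram",
    "CouplingTimecourse",
    "morlet_filter",
    "esc",
    "surrogate_normalize",
    "comodulogram",
    "comodulogram_mean",
    "theta_gamma_score",
    "hfs_coupling_timecourse",
    "DegenerateInputWarning",
]

logger = logging.getLogger(__name__)


class DegenerateInputWarning(UserWarning):
    """A correlation input was constant; the score is defined as 0."""


@dataclass(frozen=True)
class WaveletSpec:
    """Complex Morlet wavelet: center frequency and width in cycles."""

    center_freq_hz: float
    width_cycles: float = 7.0

    def __post_init__(self) -> None:
        if self.width_cycles <= 0:
            raise ValueError(f"width_cycles must be positive, got {self.width_cycles}")
        if self.center_freq_hz <= 0:
            raise ValueError(f"center_freq_hz must be positive, got {self.center_freq_hz}")

    def sigma_t(self) -> float:
        """Temporal SD of the Gaussian envelope, seconds."""
        return self.width_cycles / (2.0 * np.pi * self.center_freq_hz)


@dataclass(frozen=True)
class FrequencyBinGrid:
    """Center-frequency bins (Hz) with a nominal +/- half-width."""

    centers: tuple[float, ...]
    half_width_hz: float = 2.0

    def __post_init__(self) -> None:
        if len(self.centers) == 0:
            raise ValueError("grid needs at least one center frequency")
        if list(self.centers) != sorted(self.centers):
            raise ValueError("grid centers must be sorted ascending")


#: Full comodulogram grid: 3-98 Hz in 5 Hz increments (20 centers).
FULL_GRID = FrequencyBinGrid(centers=tuple(float(f) for f in range(3, 99, 5)))
#: Gamma grid: 33-98 Hz in 5 Hz increments (14 centers).
GAMMA_GRID = FrequencyBinGrid(centers=tuple(float(f) for f in range(33, 99, 5)))


def morlet_filter(samples: np.ndarray, fs_hz: float, spec: WaveletSpec) -> np.ndarray:
    """Band-filter a signal with a complex Morlet wavelet (analytic output).

    Output has the input's length; its real part is the band-filtered signal,
    magnitude the instantaneous amplitude, angle the instantaneous phase. The
    wavelet is scaled so that a unit-amplitude sinusoid at the center frequency
    has envelope 1.0 away from the edges.
    """
    if spec.center_freq_hz >= fs_hz / 2.0:
        raise ValueError(
            f"center frequency {spec.center_freq_hz} Hz is at or above Nyquist "
            f"({fs_hz / 2.0} Hz)"
        )
    x = np.asarray(samples, dtype=float)
    sigma = spec.sigma_t()
    half = int(np.ceil(4.0 * sigma * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    gauss = np.exp(-t ** 2 / (2.0 * sigma ** 2))
    # unit gain (envelope 1) for a unit cosine at the center frequency
    amp = 2.0 / (sigma * np.sqrt(2.0 * np.pi) * fs_hz)
    wavelet = amp * gauss * np.exp(2j * np.pi * spec.center_freq_hz * t)
    from scipy.signal import fftconvolve
    return fftconvolve(x, wavelet, mode="same")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("constant series in ESC; returning 0", DegenerateInputWarning,
                      stacklevel=3)
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def esc(signal_low: np.ndarray, envelope_high: np.ndarray) -> float:
    """Raw envelope-to-signal correlation: Pearson r in [-1, 1].

    ``signal_low`` is the low-frequency band-filtered signal (real);
    ``envelope_high`` the amplitude envelope of the faster band. Constant
    inputs yield 0 with a :class:`DegenerateInputWarning`.
    """
    a = np.asarray(signal_low, dtype=float)
    b = np.asarray(envelope_high, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signal_low and envelope_high must be 1-D of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    return _pearson(a, b)


#: Smallest allowed surrogate shift, as a fraction of the series length.
#: Cuts very close to either end of the series barely move the envelope and
#: would let surrogates nearly reproduce the original alignment; excluding
#: near-zero lags is standard for time-shift surrogate nulls.
MIN_SHIFT_FRAC = 0.1


def _shuffled_escs(signal_low: np.ndarray, envelope_high: np.ndarray,
                   n_shuffles: int, rng: np.random.Generator,
                   min_shift_frac: float = MIN_SHIFT_FRAC) -> np.ndarray:
    """ESC of circular block-swapped envelopes against the fixed slow signal.

    Swapping the two segments of the envelope at cut point k is a circular
    shift by k, so the correlations at every shift come from a single FFT
    circular cross-correlation; the ``n_shuffles`` sampled cuts index into it.
    """
    n = len(signal_low)
    a = signal_low - signal_low.mean()
    e = envelope_high - envelope_high.mean()
    na = np.linalg.norm(a)
    ne = np.linalg.norm(e)
    if na == 0.0 or ne == 0.0:
        return np.zeros(n_shuffles)
    m = max(1, int(min_shift_frac * n))
    cuts = rng.integers(m, n - m + 1, size=n_shuffles)
    # corr_at_shift[k] = sum_t a[t] * e[(t + k) % n]
    corr_all = np.fft.irfft(np.fft.rfft(e) * np.conj(np.fft.rfft(a)), n=n)
    return corr_all[cuts % n] / (na * ne)


def surrogate_normalize(raw_esc: float, signal_low: np.ndarray, envelope_high: np.ndarray,
                        n_shuffles: int = 200, seed: int | np.random.Generator = 0,
                        min_shift_frac: float = MIN_SHIFT_FRAC) -> float:
    """Surrogate-normalized ESC: z = (raw - mean_surrogate) / sd_surrogate.

    Surrogates cut the envelope at a random point (at least ``min_shift_frac``
    of the length away from either end) and swap the two segments (circular
    block shuffle), preserving autocorrelation while destroying phase-envelope
    alignment. Deterministic for a fixed seed.
    """
    if n_shuffles < 2:
        raise ValueError(f"n_shuffles must be >= 2, got {n_shuffles}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(signal_low, dtype=float)
    b = np.asarray(envelope_high, dtype=float)
    surr = _shuffled_escs(a, b, n_shuffles, rng, min_shift_frac)
    sd = surr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate surrogate distribution (zero SD)")
    return float((raw_esc - surr.mean()) / sd)


@dataclass
class Comodulogram:
    """ESC scores over (fast envelope bin x slow signal bin).

    ``z[i, j]`` is the surrogate-normalized score for envelope center
    ``env_centers[i]`` against slow-signal center ``sig_centers[j]``;
    cells with slow >= fast are NaN (null markers). ``raw`` keeps the
    unnormalized correlations for audit. ``notch_flags[i, j]`` marks cells
    whose envelope bin overlaps the mains notch band.
    """

    env_centers: tuple[float, ...]
    sig_centers: tuple[float, ...]
    z: np.ndarray
    raw: np.ndarray
    n_shuffles: int
    notch_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    window_label: str = ""
    sub_window_index: int = -1
    #: across-epoch t statistic (epoch-pooled maps only) and its dof
    t: np.ndarray | None = None
    n_epochs: int = 1

    def argmax_pair(self) -> tuple[float, float]:
        """(envelope_center, signal_center) of the maximal z cell."""
        zz = np.where(np.isnan(self.z), -np.inf, self.z)
        i, j = np.unravel_index(int(np.argmax(zz)), zz.shape)
        return self.env_centers[i], self.sig_centers[j]

    def to_frame(self, which: str = "z") -> pd.DataFrame:
        mat = self.z if which == "z" else self.raw
        return pd.DataFrame(mat, index=list(self.env_centers),
                            columns=list(self.sig_centers))


def _filter_bank(x: np.ndarray, fs_hz: float, centers: tuple[float, ...],
                 width_cycles: float) -> dict[float, np.ndarray]:
    return {c: morlet_filter(x, fs_hz, WaveletSpec(c, width_cycles)) for c in centers}


def _edge_trim_samples(center_low_hz: float, width_cycles: float, fs_hz: float) -> int:
    return int(np.ceil(WaveletSpec(center_low_hz, width_cycles).sigma_t() * fs_hz))


def comodulogram(epoch: Epoch, grid: FrequencyBinGrid = FULL_GRID,
                 n_shuffles: int = 200, seed: int = 0,
                 width_cycles: float = 7.0,
                 notch_band_hz: tuple[float, float] = (48.5, 55.0)) -> Comodulogram:
    """Surrogate-normalized ESC over all ordered bin pairs of ``grid``.

    Rows index the envelope (faster) bin, columns the slow (modulating) bin;
    pairs with slow >= fast are NaN. The epoch must be long enough to hold
    three cycles of the lowest center frequency after edge trimming.
    """
    fs = epoch.fs_hz
    x = np.asarray(epoch.samples, dtype=float)
    lowest = grid.centers[0]
    trim_low = _edge_trim_samples(lowest, width_cycles, fs)
    usable = len(x) - 2 * trim_low
    if usable < 3.0 * fs / lowest:
        raise ValueError(
            f"epoch too short for the {lowest} Hz bin: {usable / fs:.2f} s usable after "
            "edge trimming, need 3 cycles"
        )
    bank = _filter_bank(x, fs, grid.centers, width_cycles)
    k = len(grid.centers)
    z = np.full((k, k), np.nan)
    raw = np.full((k, k), np.nan)
    notch_flags = np.zeros((k, k), dtype=bool)
    rng = np.random.default_rng(seed)
    for j, c_sig in enumerate(grid.centers):        # slow, modulating
        for i, c_env in enumerate(grid.centers):    # fast, amplitude-providing
            if c_sig >= c_env:
                continue
            trim = _edge_trim_samples(c_sig, width_cycles, fs)
            low = np.real(bank[c_sig])[trim:len(x) - trim]
            env = np.abs(bank[c_env])[trim:len(x) - trim]
            r = esc(low, env)
            raw[i, j] = r
            z[i, j] = surrogate_normalize(r, low, env, n_shuffles=n_shuffles, seed=rng)
            env_lo = c_env - grid.half_width_hz
            env_hi = c_env + grid.half_width_hz
            notch_flags[i, j] = env_lo < notch_band_hz[1] and env_hi > notch_band_hz[0]
    return Comodulogram(env_centers=grid.centers, sig_centers=grid.centers, z=z, raw=raw,
                        n_shuffles=n_shuffles, notch_flags=notch_flags,
                        window_label=epoch.window_label,
                        sub_window_index=epoch.sub_window_index)


def comodulogram_mean(epochs: list[Epoch], grid: FrequencyBinGrid = FULL_GRID,
                      n_shuffles: int = 200, seed: int = 0,
                      width_cycles: float = 7.0,
                      notch_band_hz: tuple[float, float] = (48.5, 55.0)) -> Comodulogram:
    """Comodulogram pooled over epochs (the per-window mean score).

    Raw scores are averaged; normalized scores are Stouffer-combined
    (sum of per-epoch z over sqrt(n_epochs)), which keeps unit variance under
    the null so the pooled matrix thresholds like a single z-map. With more
    than two epochs the pooled map also carries a per-cell across-epoch t
    statistic (mean z over its standard error, dof = n_epochs - 1): because
    its null spread is estimated from the epochs themselves, it stays exactly
    calibrated even where the shift-surrogate null is slightly overdispersed
    on short narrowband series, and is the statistic to use for
    multiplicity-corrected cell tests.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    seeds = np.random.SeedSequence(seed).generate_state(len(epochs))
    coms = [comodulogram(epo, grid=grid, n_shuffles=n_shuffles, seed=int(s),
                         width_cycles=width_cycles, notch_band_hz=notch_band_hz)
            for epo, s in zip(epochs, seeds)]
    stack = np.array([c.z for c in coms])
    k = len(coms)
    z = np.sum(stack, axis=0) / np.sqrt(k)
    raw = np.mean([c.raw for c in coms], axis=0)
    t = None
    if k > 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.mean(stack, axis=0) / (np.std(stack, axis=0, ddof=1) / np.sqrt(k))
    return Comodulogram(env_centers=grid.centers, sig_centers=grid.centers, z=z,
                        raw=raw, n_shuffles=n_shuffles, notch_flags=coms[0].notch_flags,
                        window_label=epochs[0].window_label, sub_window_index=-1,
                        t=t, n_epochs=k)


def _band_centers(grid: FrequencyBinGrid, f_low: float, f_high: float) -> tuple[float, ...]:
    """Grid centers lying inside [f_low, f_high]."""
    return tuple(c for c in grid.centers if f_low <= c <= f_high)


def theta_gamma_score(epoch: Epoch, theta_band: tuple[float, float] = (4.0, 10.0),
                      gamma_grid: FrequencyBinGrid = GAMMA_GRID,
                      slow_grid: FrequencyBinGrid = FULL_GRID,
                      n_shuffles: int = 200, seed: int = 0,
                      width_cycles: float = 7.0,
                      return_raw: bool = False) -> float | tuple[float, float]:
    """Pooled theta-gamma coupling: mean normalized ESC over all
    (theta-bin, gamma-bin) pairs.

    Theta bins are the slow-grid centers whose nominal bin overlaps
    ``theta_band``; gamma bins come from ``gamma_grid``.
    """
    fs = epoch.fs_hz
    x = np.asarray(epoch.samples, dtype=float)
    theta_centers = _band_centers(slow_grid, *theta_band)
    if not theta_centers:
        raise ValueError(f"no grid bins overlap the theta band {theta_band}")
    bank_theta = _filter_bank(x, fs, theta_centers, width_cycles)
    bank_gamma = _filter_bank(x, fs, gamma_grid.centers, width_cycles)
    rng = np.random.default_rng(seed)
    zs, raws = [], []
    for c_t in theta_centers:
        trim = _edge_trim_samples(c_t, width_cycles, fs)
        low = np.real(bank_theta[c_t])[trim:len(x) - trim]
        for c_g in gamma_grid.centers:
            if c_g <= c_t:
                continue
            env = np.abs(bank_gamma[c_g])[trim:len(x) - trim]
            r = esc(low, env)
            raws.append(r)
            zs.append(surrogate_normalize(r, low, env, n_shuffles=n_shuffles, seed=rng))
    pooled_z = float(np.mean(zs))
    if return_raw:
        return pooled_z, float(np.mean(raws))
    return pooled_z


@dataclass
class CouplingTimecourse:
    """Per-HFS-sub-window pooled theta-gamma coupling scores."""

    epoch_indices: list[int]
    scores_z: list[float]
    scores_raw: list[float]
    pooled_z: float
    baseline_mean_z: float
    scores_rel_baseline: list[float]
    missing_indices: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch_index": self.epoch_indices,
            "score_z": self.scores_z,
            "score_raw": self.scores_raw,
            "score_rel_baseline": self.scores_rel_baseline,
        })


def hfs_coupling_timecourse(during_epochs: list[Epoch], baseline_epochs: list[Epoch],
                            n_shuffles: int = 200, seed: int = 0,
                            width_cycles: float = 7.0,
                            theta_band: tuple[float, float] = (4.0, 10.0),
                            gamma_grid: FrequencyBinGrid = GAMMA_GRID) -> CouplingTimecourse:
    """Theta-gamma coupling per HFS sub-window epoch, relative to baseline.

    Missing sub-windows are logged, not fatal; scores are also expressed
    relative to the mean baseline score (ratio, guarded against a near-zero
    baseline by reporting NaN there).
    """
    if len(during_epochs) < 2:
        raise ValueError("need at least 2 during-HFS epochs")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(during_epochs) + len(baseline_epochs))
    idx, zs, raws = [], [], []
    for ep, s in zip(during_epochs, seeds[:len(during_epochs)]):
        z, r = theta_gamma_score(ep, theta_band=theta_band, gamma_grid=gamma_grid,
                                 n_shuffles=n_shuffles, seed=int(s),
                                 width_cycles=width_cycles, return_raw=True)
        idx.append(ep.sub_window_index)
        zs.append(z)
        raws.append(r)
    missing = sorted(set(range(10)) - set(idx))
    if missing:
        logger.info("HFS coupling timecourse: missing sub-windows %s", missing)
    base_scores = [
        theta_gamma_score(ep, theta_band=theta_band, gamma_grid=gamma_grid,
                          n_shuffles=n_shuffles, seed=int(s), width_cycles=width_cycles)
        for ep, s in zip(baseline_epochs, seeds[len(during_epochs):])
    ]
    base_mean = float(np.mean(base_scores)) if base_scores else float("nan")
    if base_scores and abs(base_mean) > 1e-12:
        rel = [z / base_mean for z in zs]
    else:
        rel = [float("nan")] * len(zs)
    return CouplingTimecourse(epoch_indices=idx, scores_z=zs, scores_raw=raws,
                              pooled_z=float(np.mean(zs)), baseline_mean_z=base_mean,
                              scores_rel_baseline=rel, missing_indices=missing)
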