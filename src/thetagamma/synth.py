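"""Synthetic LFP/EEG, stimulation-schedule and evoked-sweep generators.

Every downstream stage of the pipeline (epoching, band power, phase-amplitude
coupling, LTP quantification, statistics) is exercisable against recordings
with known ground truth produced here. The generative model is deliberately
phenomenological:

* a theta sinusoid plus a gamma sinusoid whose instantaneous amplitude is
  modulated by theta phase with a cosine kernel — the exact construct that
  envelope-to-signal correlation (ESC) estimates;
* spectrally shaped Gaussian background noise with a 1/f**alpha spectrum;
* a 50 Hz mains line component;
* biphasic rectangular stimulation artifacts superposed at event times;
* evoked field potentials whose potentiation decays exponentially
  (tau = inf encodes persistent LTP).

The gamma envelope is ``gamma_amp * (1 + depth * cos(theta_phase - lag))``,
so the modulation depth ``(max - min) / (max + min)`` of the envelope equals
``coupling_depth`` exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .core import (
    HFS_PULSE_RATE_HZ,
    HFS_PULSES_PER_TRAIN,
    HFS_TRAIN_DURATION_S,
    Recording,
    StimEvent,
)

__all__ = [
    "SynthConfig",
    "PlasticityModel",
    "EvokedSweep",
    "Experiment",
    "gen_coupled_eeg",
    "gen_stim_schedule",
    "inject_artifacts",
    "gen_evoked_sweep",
    "gen_experiment",
    "CONDITIONS",
    "potentiation_profile",
    "DEFAULT_EVOKED_SCHEDULE_MIN",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the coupled theta-gamma signal generator.

    Amplitudes are in microvolts; ``noise_amp_uv`` is the RMS of the 1/f**alpha
    background. ``coupling_depth`` in [0, 1] is the exact envelope modulation
    depth; ``coupling_phase_lag`` (radians) shifts the envelope maximum away
    from the theta peak.

    ``theta_phase_drift`` is a phase-diffusion coefficient (rad^2/s) giving the
    theta oscillator the cycle-to-cycle frequency variability of real
    hippocampal theta: its phase performs a random walk on top of the mean
    8 Hz advance (the default, 8 rad^2/s, diffuses about 1 rad per theta
    cycle), so phase coherence is lost over a few cycles. Without it the
    modulator would be a perfect clock, which no LFP is — and against which
    circular-shift surrogates are not a valid null, since shifting a strictly
    periodic modulator by whole cycles reproduces the original alignment.
    Set it to 0 for exactly sinusoidal components.
    """

    duration_s: float = 100.0
    fs_hz: float = 2000.0
    theta_freq_hz: float = 8.0
    theta_amp_uv: float = 150.0
    gamma_freq_hz: float = 78.0
    gamma_amp_uv: float = 30.0
    coupling_depth: float = 0.6
    coupling_phase_lag: float = 0.0
    theta_phase_drift: float = 8.0
    noise_exponent: float = 1.0
    noise_amp_uv: float = 50.0
    line_freq_hz: float = 50.0
    line_amp_uv: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError(f"coupling_depth must be in [0, 1], got {self.coupling_depth}")
        if self.fs_hz <= 2.0 * self.gamma_freq_hz:
            raise ValueError(
                f"fs_hz must exceed 2 * gamma_freq_hz "
                f"({self.fs_hz} <= {2 * self.gamma_freq_hz})"
            )
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.noise_exponent < 0:
            raise ValueError(f"noise_exponent must be >= 0, got {self.noise_exponent}")
        if self.theta_phase_drift < 0:
            raise ValueError(f"theta_phase_drift must be >= 0, got {self.theta_phase_drift}")


def _one_over_f_noise(n: int, alpha: float, rms_uv: float, fs_hz: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f**alpha."""
    if rms_uv == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if alpha == 0.0:
        shaped = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
        scale = np.zeros_like(freqs)
        nz = freqs > 0
        scale[nz] = freqs[nz] ** (-alpha / 2.0)
        shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    if sd == 0.0:
        return np.zeros(n)
    return shaped * (rms_uv / sd)


def _theta_phase(t: np.ndarray, theta_freq: float, drift: float, fs_hz: float,
                 rng: np.random.Generator) -> np.ndarray:
    phase = 2.0 * np.pi * theta_freq * t
    if drift > 0:
        phase = phase + np.cumsum(rng.standard_normal(len(t))) * np.sqrt(drift / fs_hz)
    return phase


def _coupled_signal(theta_phase: np.ndarray, t: np.ndarray, theta_amp: np.ndarray | float,
                    gamma_freq: float, gamma_amp: np.ndarray | float,
                    depth: np.ndarray | float, lag: float) -> np.ndarray:
    envelope = gamma_amp * (1.0 + depth * np.cos(theta_phase - lag))
    return theta_amp * np.cos(theta_phase) + envelope * np.cos(2.0 * np.pi * gamma_freq * t)


def gen_coupled_eeg(config: SynthConfig) -> Recording:
    """Generate a theta-gamma coupled LFP recording from ``config``.

    Identical configs (including seed) produce bit-identical samples.
    """
    config.validate()
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz
    rng = np.random.default_rng(config.seed)
    phase = _theta_phase(t, config.theta_freq_hz, config.theta_phase_drift,
                         config.fs_hz, rng)
    signal = _coupled_signal(
        phase, t, config.theta_amp_uv,
        config.gamma_freq_hz, config.gamma_amp_uv,
        config.coupling_depth, config.coupling_phase_lag,
    )
    signal = signal + _one_over_f_noise(n, config.noise_exponent, config.noise_amp_uv,
                                        config.fs_hz, rng)
    if config.line_amp_uv:
        signal = signal + config.line_amp_uv * np.sin(2.0 * np.pi * config.line_freq_hz * t)
    return Recording(samples=signal, fs_hz=config.fs_hz, events=[], condition="synthetic")


def gen_stim_schedule(n_hfs_trains: int, train_interval_s: float, tp_rate_hz: float,
                      duration_s: float, start_s: float = 0.0) -> list[StimEvent]:
    """Build a stimulation-event log: HFS trains plus ongoing test pulses.

    Trains are 15 pulses at 200 Hz (75 ms) at ``train_interval_s`` spacing from
    ``start_s``; test pulses are spaced ``1/tp_rate_hz`` apart over the whole
    duration. A schedule whose trains would overlap themselves is rejected.
    """
    if n_hfs_trains < 0:
        raise ValueError("n_hfs_trains must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_hfs_trains > 0:
        if train_interval_s <= 0:
            raise ValueError("train_interval_s must be positive")
        if n_hfs_trains > 1 and train_interval_s < HFS_TRAIN_DURATION_S:
            raise ValueError(
                f"train_interval_s={train_interval_s} overlaps the "
                f"{HFS_TRAIN_DURATION_S} s train duration"
            )
    events: list[StimEvent] = []
    for i in range(n_hfs_trains):
        t0 = start_s + i * train_interval_s
        if t0 + HFS_TRAIN_DURATION_S > duration_s + 1e-9:
            raise ValueError(f"HFS train at {t0} s exceeds the {duration_s} s schedule")
        events.append(StimEvent(time_s=t0, kind="hfs_train", duration_s=HFS_TRAIN_DURATION_S))
    if tp_rate_hz and tp_rate_hz > 0:
        spacing = 1.0 / tp_rate_hz
        t0 = spacing
        while t0 < duration_s:
            events.append(StimEvent(time_s=t0, kind="test_pulse", duration_s=0.0002))
            t0 += spacing
    events.sort(key=lambda ev: ev.time_s)
    return events


def inject_artifacts(recording: Recording, events: list[StimEvent],
                     artifact_amp_uv: float | None = None,
                     pulse_phase_s: float = 0.001) -> Recording:
    """Superpose biphasic rectangular stimulation transients at event times.

    ``artifact_amp_uv`` defaults to 10x the pre-injection signal RMS so that
    threshold detection downstream is unambiguous. HFS trains carry 15 biphasic
    pulses at 200 Hz; test pulses carry a single biphasic transient. Samples
    outside event windows are unchanged.
    """
    fs = recording.fs_hz
    n = recording.n_samples
    for ev in events:
        if ev.end_s > recording.duration_s + 1e-9:
            raise ValueError(f"event at {ev.time_s} s lies outside the recording")
    if artifact_amp_uv is None:
        rms = float(np.sqrt(np.mean(recording.samples ** 2)))
        artifact_amp_uv = 10.0 * rms if rms > 0 else 1000.0
    out = recording.samples.copy()
    half = max(1, int(round(pulse_phase_s * fs)))

    def _add_pulse(onset_s: float) -> None:
        i0 = int(round(onset_s * fs))
        out[max(0, i0):min(n, i0 + half)] += artifact_amp_uv
        out[max(0, i0 + half):min(n, i0 + 2 * half)] -= artifact_amp_uv

    for ev in events:
        if ev.kind == "hfs_train":
            for k in range(HFS_PULSES_PER_TRAIN):
                _add_pulse(ev.time_s + k / HFS_PULSE_RATE_HZ)
        else:
            _add_pulse(ev.time_s)
    return Recording(samples=out, fs_hz=fs,
                     events=sorted(recording.events + list(events), key=lambda e: e.time_s),
                     condition=recording.condition, subject_id=recording.subject_id)


# ---------------------------------------------------------------------------
# Evoked potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasticityModel:
    """Exponential-decay model of post-tetanic potentiation.

    Response magnitude relative to baseline is
    ``f(t) = 1 + (potentiation_factor - 1) * exp(-t / decay_tau_min)`` for
    post-HFS times t (minutes) and 1 before HFS. ``decay_tau_min = inf``
    encodes LTP that persists beyond 24 h.
    """

    baseline_slope_mv_ms: float = 5.0
    baseline_ps_mv: float = 5.0
    potentiation_factor: float = 1.5
    decay_tau_min: float = math.inf
    sweep_noise_frac: float = 0.0

    def validate(self) -> None:
        if self.potentiation_factor < 1.0:
            raise ValueError(f"potentiation_factor must be >= 1, got {self.potentiation_factor}")
        if not (self.decay_tau_min > 0):
            raise ValueError(f"decay_tau_min must be > 0 (or inf), got {self.decay_tau_min}")
        # PS trough must undercut both flanking peaks (tangent method needs a dip)
        if self.baseline_ps_mv <= self.baseline_slope_mv_ms / 2.0:
            raise ValueError(
                "baseline_ps_mv must exceed baseline_slope_mv_ms / 2 for the "
                "population spike to form a trough between the flanking peaks"
            )

    def factor(self, t_min: float) -> float:
        """Potentiation multiple of baseline at ``t_min`` minutes post-HFS."""
        if t_min < 0:
            return 1.0
        if math.isinf(self.decay_tau_min):
            return self.potentiation_factor
        return 1.0 + (self.potentiation_factor - 1.0) * math.exp(-t_min / self.decay_tau_min)


def potentiation_profile(model: PlasticityModel, t_min: np.ndarray) -> np.ndarray:
    """Vectorized ``model.factor`` over an array of times (minutes)."""
    return np.array([model.factor(float(t)) for t in np.asarray(t_min, dtype=float)])


@dataclass
class EvokedSweep:
    """Fixed-length waveform (mV) around one test pulse."""

    samples: np.ndarray
    fs_hz: float
    stim_time_s: float
    intensity_ua: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        dur = len(self.samples) / self.fs_hz
        if not 0 <= self.stim_time_s < dur:
            raise ValueError("stim_time_s must lie inside the sweep")
        if dur - self.stim_time_s < 0.020:
            raise ValueError("sweep must extend >= 20 ms beyond the stimulus")


# Canonical waveform node times in ms after the stimulus. The rising fEPSP
# segment runs RISE_T0..RISE_T1 with the model slope; the population spike
# trough sits between two positive peaks so the tangent measure is exact.
_RISE_T0, _RISE_T1 = 1.0, 4.0
_TROUGH_T, _PEAK2_T, _DECAY_END_T = 5.5, 7.0, 15.0


def _evoked_waveform(slope_mv_ms: float, ps_mv: float, fs_hz: float,
                     pre_s: float, post_s: float) -> tuple[np.ndarray, float]:
    """Noise-free canonical sweep; returns (samples, stim_time_s)."""
    h = slope_mv_ms * (_RISE_T1 - _RISE_T0)           # first peak height
    v2 = h - slope_mv_ms                               # second peak height
    v_trough = (h + v2) / 2.0 - ps_mv                  # tangent amplitude = ps_mv
    t_nodes = np.array([0.0, _RISE_T0, _RISE_T1, _TROUGH_T, _PEAK2_T, _DECAY_END_T])
    v_nodes = np.array([0.0, 0.0, h, v_trough, v2, 0.0])
    n_pre = int(round(pre_s * fs_hz))
    n_post = int(round(post_s * fs_hz))
    t_ms = (np.arange(n_post) / fs_hz) * 1000.0
    post = np.interp(t_ms, t_nodes, v_nodes, right=0.0)
    return np.concatenate([np.zeros(n_pre), post]), n_pre / fs_hz


def gen_evoked_sweep(model: PlasticityModel, t_min: float, seed: int | None = None,
                     fs_hz: float = 10000.0, pre_s: float = 0.005,
                     post_s: float = 0.025, intensity_ua: float = 0.0) -> EvokedSweep:
    """Generate one evoked sweep at ``t_min`` minutes relative to HFS.

    Negative ``t_min`` marks a pre-HFS (baseline) sweep. fEPSP slope and PS
    amplitude both scale with the potentiation factor f(t); multiplicative
    Gaussian noise of fraction ``model.sweep_noise_frac`` is applied.
    """
    model.validate()
    f = model.factor(t_min)
    samples, stim_time = _evoked_waveform(model.baseline_slope_mv_ms * f,
                                          model.baseline_ps_mv * f, fs_hz, pre_s, post_s)
    if model.sweep_noise_frac > 0:
        rng = np.random.default_rng(seed)
        samples = samples * (1.0 + model.sweep_noise_frac * rng.standard_normal(len(samples)))
    return EvokedSweep(samples=samples, fs_hz=fs_hz, stim_time_s=stim_time,
                       intensity_ua=intensity_ua)


#: Evoked-response schedule in minutes relative to HFS: six 5-min baseline
#: points, three 5-min points post-HFS, 15-min intervals to 4 h, then an
#: additional hour of recordings 24-25 h after HFS.
DEFAULT_EVOKED_SCHEDULE_MIN: tuple[float, ...] = tuple(
    [-30.0, -25.0, -20.0, -15.0, -10.0, -5.0]
    + [5.0, 10.0, 15.0]
    + [float(t) for t in range(30, 241, 15)]
    + [1440.0, 1455.0, 1470.0, 1485.0, 1500.0]
)


# ---------------------------------------------------------------------------
# Experiment presets
# ---------------------------------------------------------------------------

@dataclass
class ExperimentTruth:
    """Ground-truth generator parameters attached to a synthetic experiment."""

    condition: str
    base_config: SynthConfig
    theta_amp_factor: dict[str, float]
    coupling_depth_during: list[float]      # per 10 s HFS sub-window, len 10
    plasticity: PlasticityModel
    hfs_onset_s: float


@dataclass
class Experiment:
    """A complete synthetic experiment: recording + evoked sweeps + truth."""

    recording: Recording
    sweeps: list[tuple[float, list[EvokedSweep]]]   # (t_min, 5 sweeps)
    truth: ExperimentTruth


def _condition_presets(condition: str, base: SynthConfig,
                       sweep_noise_frac: float) -> ExperimentTruth:
    """Scenario presets encoding effect *directions* reported for this model.

    control: persistent (>24 h) LTP, transient theta dip during HFS followed
    by rebound, constant theta-gamma coupling.
    mk801_w1 / mk801_w4: LTP decaying within ~4 h, deeper theta suppression
    during HFS sustained into the post windows (longer for w4), gamma spared,
    coupling depth halved in HFS sub-windows 6-10.
    """
    if condition == "control":
        theta_factor = {"pre": 1.0, "during": 0.85, "post1": 1.1, "post2": 1.05, "post3": 1.0}
        depth = [base.coupling_depth] * 10
        plasticity = PlasticityModel(potentiation_factor=1.5, decay_tau_min=math.inf,
                                     sweep_noise_frac=sweep_noise_frac)
    elif condition == "mk801_w1":
        theta_factor = {"pre": 1.0, "during": 0.6, "post1": 0.7, "post2": 0.7, "post3": 1.0}
        depth = [base.coupling_depth] * 5 + [base.coupling_depth / 2.0] * 5
        plasticity = PlasticityModel(potentiation_factor=1.5, decay_tau_min=240.0,
                                     sweep_noise_frac=sweep_noise_frac)
    elif condition == "mk801_w4":
        theta_factor = {"pre": 1.0, "during": 0.6, "post1": 0.7, "post2": 0.7, "post3": 0.7}
        depth = [base.coupling_depth] * 5 + [base.coupling_depth / 2.0] * 5
        plasticity = PlasticityModel(potentiation_factor=1.5, decay_tau_min=240.0,
                                     sweep_noise_frac=sweep_noise_frac)
    else:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return ExperimentTruth(condition=condition, base_config=base,
                           theta_amp_factor=theta_factor,
                           coupling_depth_during=depth, plasticity=plasticity,
                           hfs_onset_s=100.0)


CONDITIONS = ("control", "mk801_w1", "mk801_w4")


def gen_experiment(condition: str, seed: int, base_config: SynthConfig | None = None,
                   sweep_noise_frac: float = 0.05, artifact_amp_uv: float | None = None,
                   n_sweeps_per_point: int = 5,
                   schedule_min: tuple[float, ...] = DEFAULT_EVOKED_SCHEDULE_MIN) -> Experiment:
    """Generate a full synthetic experiment for one condition preset.

    The recording spans the five analysis windows (pre at 0-100 s, HFS onset at
    100 s, posts through 500 s) with per-window theta-amplitude factors and
    per-sub-window coupling depths from the preset, HFS/test-pulse artifacts
    injected, and an evoked-sweep series following the plasticity model.
    """
    if base_config is None:
        base_config = SynthConfig()
    base_config.validate()
    truth = _condition_presets(condition, base_config, sweep_noise_frac)

    fs = base_config.fs_hz
    duration = 500.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    hfs_onset = truth.hfs_onset_s

    # Per-sample profiles for theta amplitude and coupling depth.
    theta_amp = np.full(n, base_config.theta_amp_uv)
    depth = np.full(n, base_config.coupling_depth)
    window_starts = {"pre": 0.0, "during": 100.0, "post1": 200.0, "post2": 300.0,
                     "post3": 400.0}
    for label, w0 in window_starts.items():
        i0, i1 = int(w0 * fs), int((w0 + 100.0) * fs)
        theta_amp[i0:i1] = base_config.theta_amp_uv * truth.theta_amp_factor[label]
    for k in range(10):
        i0 = int((hfs_onset + 10.0 * k) * fs)
        i1 = int((hfs_onset + 10.0 * (k + 1)) * fs)
        depth[i0:i1] = truth.coupling_depth_during[k]

    ss = np.random.SeedSequence([zlib.crc32(condition.encode()) % (2 ** 31), seed])
    sig_seed, sweep_seed = ss.spawn(2)
    rng = np.random.default_rng(sig_seed)
    phase = _theta_phase(t, base_config.theta_freq_hz, base_config.theta_phase_drift,
                         fs, rng)
    signal = _coupled_signal(phase, t, theta_amp,
                             base_config.gamma_freq_hz, base_config.gamma_amp_uv,
                             depth, base_config.coupling_phase_lag)
    signal += _one_over_f_noise(n, base_config.noise_exponent, base_config.noise_amp_uv,
                                fs, rng)
    if base_config.line_amp_uv:
        signal += base_config.line_amp_uv * np.sin(2.0 * np.pi * base_config.line_freq_hz * t)

    recording = Recording(samples=signal, fs_hz=fs, events=[], condition=condition)
    events = gen_stim_schedule(n_hfs_trains=10, train_interval_s=10.0, tp_rate_hz=0.025,
                               duration_s=duration, start_s=hfs_onset)
    recording = inject_artifacts(recording, events, artifact_amp_uv=artifact_amp_uv)

    sweep_rng = np.random.default_rng(sweep_seed)
    sweeps: list[tuple[float, list[EvokedSweep]]] = []
    for t_min in schedule_min:
        point = [gen_evoked_sweep(truth.plasticity, t_min,
                                  seed=int(sweep_rng.integers(2 ** 31)))
                 for _ in range(n_sweeps_per_point)]
        sweeps.append((t_min, point))
    return Experiment(recording=recording, sweeps=sweeps, truth=truth)
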