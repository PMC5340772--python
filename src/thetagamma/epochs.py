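"""Analysis-window placement, artifact detection and epoch extraction.

The five 100 s analysis windows bracket the tetanus: 100 s of baseline before
the first HFS train, 100 s spanning HFS itself, and three contiguous 100 s
post-HFS windows. Each window is cut into ten 10 s sub-windows, and from each
sub-window the earliest 4.1 s run of artifact-free samples is extracted.

"Artifact-free" means: outside every declared stimulation-event interval
(plus a guard margin) and below an amplitude threshold expressed in robust
standard deviations (median absolute deviation scaled to Gaussian SD).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .core import (
    AnalysisWindow,
    Epoch,
    Recording,
    StimEvent,
    WINDOW_LABELS,
    epoch_length_samples,
)

__all__ = [
    "locate_windows",
    "detect_artifacts",
    "extract_epochs",
    "extract_all_epochs",
    "downsample",
    "DEFAULT_GUARD_S",
    "DEFAULT_THRESHOLD_SD",
]

logger = logging.getLogger(__name__)

DEFAULT_GUARD_S = 0.05
DEFAULT_THRESHOLD_SD = 6.0
WINDOW_S = 100.0


def locate_windows(recording: Recording) -> list[AnalysisWindow]:
    """Place the five contiguous 100 s windows around the tetanus.

    ``pre`` is the 100 s immediately before the first HFS train; ``during``
    starts at first-train onset; the three post windows follow contiguously.
    """
    hfs = recording.hfs_events()
    if not hfs:
        raise ValueError("window scheme requires a tetanus: no hfs_train events in recording")
    onset = min(ev.time_s for ev in hfs)
    last_end = max(ev.end_s for ev in hfs)
    if last_end > onset + WINDOW_S:
        raise ValueError("HFS trains span more than the 100 s `during` window")
    if onset < WINDOW_S - 1e-9:
        raise ValueError(
            f"recording provides only {onset:.1f} s before HFS; 100 s of baseline required"
        )
    if onset + 4 * WINDOW_S > recording.duration_s + 1e-9:
        raise ValueError(
            f"recording ends at {recording.duration_s:.1f} s; "
            f"{onset + 4 * WINDOW_S:.1f} s required for the post-HFS windows"
        )
    starts = [onset - WINDOW_S, onset, onset + WINDOW_S, onset + 2 * WINDOW_S,
              onset + 3 * WINDOW_S]
    return [AnalysisWindow(label=lab, start_s=s, duration_s=WINDOW_S)
            for lab, s in zip(WINDOW_LABELS, starts)]


def detect_artifacts(samples: np.ndarray, fs_hz: float,
                     events: list[StimEvent] | None = None,
                     threshold_sd: float = DEFAULT_THRESHOLD_SD,
                     guard_s: float = DEFAULT_GUARD_S) -> np.ndarray:
    """Boolean mask of artifact samples (True = contaminated).

    A sample is flagged if |x| exceeds ``threshold_sd`` robust standard
    deviations (1.4826 * MAD) of the whole trace, or if it falls inside a
    declared event interval extended by ``guard_s`` on both sides.
    """
    if threshold_sd <= 0:
        raise ValueError(f"threshold_sd must be positive, got {threshold_sd}")
    x = np.asarray(samples, dtype=float)
    mask = np.zeros(len(x), dtype=bool)
    mad = np.median(np.abs(x - np.median(x)))
    robust_sd = 1.4826 * mad
    if robust_sd > 0:
        mask |= np.abs(x) > threshold_sd * robust_sd
    n = len(x)
    for ev in events or []:
        i0 = max(0, int(np.floor((ev.time_s - guard_s) * fs_hz)))
        i1 = min(n, int(np.ceil((ev.end_s + guard_s) * fs_hz)) + 1)
        mask[i0:i1] = True
    return mask


def _earliest_clean_start(mask_slice: np.ndarray, n_need: int) -> int | None:
    """Index of the earliest run of ``n_need`` consecutive False values."""
    n = len(mask_slice)
    if n_need > n:
        return None
    clean = (~mask_slice).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(clean)])
    window_sums = csum[n_need:] - csum[:-n_need]   # clean count in [i, i+n_need)
    hits = np.nonzero(window_sums == n_need)[0]
    if len(hits) == 0:
        return None
    return int(hits[0])


def extract_epochs(recording: Recording, window: AnalysisWindow, mask: np.ndarray,
                   epoch_s: float = 4.1, n_sub_windows: int = 10) -> list[Epoch]:
    """Extract one artifact-free epoch per 10 s sub-window of ``window``.

    Within each sub-window the earliest fully clean run of ``epoch_s`` seconds
    is taken; sub-windows with no qualifying run contribute nothing (logged).
    Raises if every sub-window fails.
    """
    fs = recording.fs_hz
    if window.start_s < -1e-9 or window.end_s > recording.duration_s + 1e-9:
        raise ValueError("analysis window extends outside the recording")
    if len(mask) != recording.n_samples:
        raise ValueError("mask length must equal the number of recording samples")
    n_need = epoch_length_samples(fs, epoch_s)
    sub_len = window.duration_s / n_sub_windows
    out: list[Epoch] = []
    for k in range(n_sub_windows):
        s0 = window.start_s + k * sub_len
        i0 = int(round(s0 * fs))
        i1 = int(round((s0 + sub_len) * fs))
        i1 = min(i1, recording.n_samples)
        start = _earliest_clean_start(mask[i0:i1], n_need)
        if start is None:
            logger.info("window %s sub-window %d: no clean %.1f s run",
                        window.label, k, epoch_s)
            continue
        j0 = i0 + start
        out.append(Epoch(samples=recording.samples[j0:j0 + n_need].copy(), fs_hz=fs,
                         window_label=window.label, sub_window_index=k,
                         start_s=j0 / fs))
    if not out:
        raise ValueError(f"no artifact-free {epoch_s} s epoch in any sub-window of "
                         f"window {window.label!r}")
    return out


def extract_all_epochs(recording: Recording, threshold_sd: float = DEFAULT_THRESHOLD_SD,
                       guard_s: float = DEFAULT_GUARD_S,
                       epoch_s: float = 4.1) -> dict[str, list[Epoch]]:
    """Windows + artifact mask + per-window epoch extraction in one call."""
    windows = locate_windows(recording)
    mask = detect_artifacts(recording.samples, recording.fs_hz, recording.events,
                            threshold_sd=threshold_sd, guard_s=guard_s)
    return {w.label: extract_epochs(recording, w, mask, epoch_s=epoch_s) for w in windows}


def downsample(recording: Recording, target_fs_hz: float,
               analysis_top_hz: float | None = None) -> Recording:
    """Anti-aliased downsampling of a recording; events pass through unchanged.

    ``analysis_top_hz`` (if given) is the highest frequency the downstream
    analysis needs; the target rate must leave a Nyquist margin above it.
    """
    fs = recording.fs_hz
    if target_fs_hz > fs:
        raise ValueError(f"target {target_fs_hz} Hz exceeds the recording rate {fs} Hz")
    if analysis_top_hz is not None and target_fs_hz <= 2.0 * analysis_top_hz:
        raise ValueError(
            f"target {target_fs_hz} Hz violates the Nyquist margin for analysis up to "
            f"{analysis_top_hz} Hz"
        )
    if target_fs_hz == fs:
        return Recording(samples=recording.samples.copy(), fs_hz=fs,
                         events=list(recording.events), condition=recording.condition,
                         subject_id=recording.subject_id)
    from fractions import Fraction
    frac = Fraction(target_fs_hz / fs).limit_denominator(1000)
    resampled = sps.resample_poly(recording.samples, frac.numerator, frac.denominator)
    return Recording(samples=resampled, fs_hz=fs * frac.numerator / frac.denominator,
                     events=list(recording.events), condition=recording.condition,
                     subject_id=recording.subject_id)
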