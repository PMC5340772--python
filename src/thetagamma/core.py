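"""Shared domain containers for recordings, stimulation events and epochs.

A :class:`Recording` is a single-channel local field potential / EEG trace in
microvolts with a stimulation-event log attached; an :class:`Epoch` is a short
artifact-free segment cut from one of the five 100 s analysis windows placed
around high-frequency stimulation (HFS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimEvent",
    "Recording",
    "AnalysisWindow",
    "Epoch",
    "WINDOW_LABELS",
    "HFS_PULSES_PER_TRAIN",
    "HFS_PULSE_RATE_HZ",
    "HFS_TRAIN_DURATION_S",
]

#: Labels of the five 100 s analysis windows, in temporal order.
WINDOW_LABELS = ("pre", "during", "post1", "post2", "post3")

#: Tetanus geometry: 15 pulses at 200 Hz per train.
HFS_PULSES_PER_TRAIN = 15
HFS_PULSE_RATE_HZ = 200.0
HFS_TRAIN_DURATION_S = HFS_PULSES_PER_TRAIN / HFS_PULSE_RATE_HZ  # 0.075 s

_EVENT_KINDS = ("test_pulse", "hfs_train")


@dataclass(frozen=True)
class StimEvent:
    """A stimulation event: a single test pulse or one HFS train.

    Parameters
    ----------
    time_s
        Onset in seconds from recording start.
    kind
        ``"test_pulse"`` or ``"hfs_train"``.
    duration_s
        Event duration in seconds (0.2 ms for a test pulse, 75 ms for a
        15-pulse 200 Hz train).
    """

    time_s: float
    kind: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"event time_s must be >= 0, got {self.time_s}")
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"event kind must be one of {_EVENT_KINDS}, got {self.kind!r}")
        if self.duration_s < 0:
            raise ValueError(f"event duration_s must be >= 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.time_s + self.duration_s


@dataclass
class Recording:
    """Continuous single-channel LFP/EEG recording in microvolts."""

    samples: np.ndarray
    fs_hz: float
    events: list[StimEvent] = field(default_factory=list)
    condition: str = "unlabeled"
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        span = max((ev.end_s for ev in self.events), default=0.0)
        if span > self.duration_s + 1e-9:
            raise ValueError(
                f"events extend to {span:.3f} s, beyond the {self.duration_s:.3f} s recording"
            )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def hfs_events(self) -> list[StimEvent]:
        return [ev for ev in self.events if ev.kind == "hfs_train"]

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass(frozen=True)
class AnalysisWindow:
    """One of the five contiguous 100 s windows around HFS."""

    label: str
    start_s: float
    duration_s: float = 100.0

    def __post_init__(self) -> None:
        if self.label not in WINDOW_LABELS:
            raise ValueError(f"window label must be one of {WINDOW_LABELS}, got {self.label!r}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class Epoch:
    """A 4.1 s artifact-free segment tied to one 10 s sub-window."""

    samples: np.ndarray
    fs_hz: float
    window_label: str
    sub_window_index: int
    start_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0 <= self.sub_window_index <= 9:
            raise ValueError(f"sub_window_index must be 0-9, got {self.sub_window_index}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


def epoch_length_samples(fs_hz: float, epoch_s: float = 4.1) -> int:
    """Number of samples in one artifact-free epoch (round(epoch_s * fs))."""
    return int(round(epoch_s * fs_hz))


def isclose_time(a: float, b: float, fs_hz: float) -> bool:
    """Times equal to within half a sample."""
    return math.isclose(a, b, abs_tol=0.5 / fs_hz)
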