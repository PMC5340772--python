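"""Plain-text readers/writers for recordings and evoked sweeps.

A recording is stored as a two-file pair: ``<base>.dat`` holds the raw signal
as one microvolt value per line, and ``<base>.yaml`` is a sidecar with the
sampling rate, condition/subject labels, the stimulation-event log and (for
synthetic data) the ground-truth parameters. Evoked sweeps go into a single
delimited text file with a ``#``-prefixed metadata header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .core import Recording, StimEvent
from .synth import EvokedSweep

__all__ = ["save_recording", "load_recording", "save_sweeps", "load_sweeps"]


def save_recording(recording: Recording, base: str | Path,
                   truth: dict[str, Any] | None = None) -> tuple[Path, Path]:
    base = Path(base)
    dat = base.with_suffix(".dat")
    meta = base.with_suffix(".yaml")
    np.savetxt(dat, recording.samples, fmt="%.6f")
    sidecar = {
        "fs_hz": float(recording.fs_hz),
        "n_samples": int(recording.n_samples),
        "units": "microvolts",
        "condition": recording.condition,
        "subject_id": recording.subject_id,
        "events": [
            {"time_s": float(ev.time_s), "kind": ev.kind, "duration_s": float(ev.duration_s)}
            for ev in recording.events
        ],
    }
    if truth is not None:
        sidecar["truth"] = truth
    meta.write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return dat, meta


def load_recording(base: str | Path) -> Recording:
    base = Path(base)
    samples = np.loadtxt(base.with_suffix(".dat"))
    sidecar = yaml.safe_load(base.with_suffix(".yaml").read_text())
    events = [StimEvent(time_s=e["time_s"], kind=e["kind"], duration_s=e["duration_s"])
              for e in sidecar.get("events", [])]
    return Recording(samples=samples, fs_hz=sidecar["fs_hz"], events=events,
                     condition=sidecar.get("condition", "unlabeled"),
                     subject_id=sidecar.get("subject_id", "unknown"))


def save_sweeps(sweeps: Sequence[tuple[float, Sequence[EvokedSweep]]],
                path: str | Path) -> Path:
    """All evoked sweeps in one TSV: header comments + one row per sweep."""
    path = Path(path)
    first = sweeps[0][1][0]
    lines = [
        f"# fs_hz={first.fs_hz}",
        f"# stim_time_s={first.stim_time_s}",
        "# units=mV; columns: t_min, intensity_ua, samples...",
    ]
    for t_min, point in sweeps:
        for sw in point:
            vals = "\t".join(f"{v:.6f}" for v in sw.samples)
            lines.append(f"{t_min}\t{sw.intensity_ua}\t{vals}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_sweeps(path: str | Path) -> list[tuple[float, list[EvokedSweep]]]:
    path = Path(path)
    fs = stim = None
    grouped: dict[float, list[EvokedSweep]] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if "fs_hz=" in line:
                fs = float(line.split("=", 1)[1])
            elif "stim_time_s=" in line:
                stim = float(line.split("=", 1)[1])
            continue
        parts = line.split("\t")
        t_min, intensity = float(parts[0]), float(parts[1])
        samples = np.array([float(v) for v in parts[2:]])
        grouped.setdefault(t_min, []).append(
            EvokedSweep(samples=samples, fs_hz=fs, stim_time_s=stim, intensity_ua=intensity))
    return sorted(grouped.items(), key=lambda kv: kv[0])
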