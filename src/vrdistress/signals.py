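"""Core in-memory containers for waveforms, beat events and heart-rate series.

All times are seconds as floats. Raw device exports carry epoch start
timestamps; once a recording is attached to a scene, times are interpreted
relative to the scene start (t = 0 at scene onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ECG_FS = 500.0  #: chest-ECG sampling rate, Hz
BVP_FS = 64.0  #: wrist-BVP sampling rate, Hz

SCENES = ("baseline", "NIS", "IS")
DEVICES = ("faros", "e4")


@dataclass
class UniformSignal:
    """A regularly sampled waveform (ECG or BVP).

    Sample ``i`` occurs at ``start_time_s + i / fs``.
    """

    samples: np.ndarray
    fs: float
    start_time_s: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.samples)) / self.fs

    def crop(self, t0: float, t1: float) -> "UniformSignal":
        """Return the samples falling in wall-clock span ``[t0, t1)``.

        The sampling rate and kept sample values are untouched; only the
        leading/trailing samples outside the span are dropped.
        """
        if t1 <= t0:
            raise ValueError("empty crop span")
        i0 = int(np.ceil(round((t0 - self.start_time_s) * self.fs, 9)))
        i1 = int(np.floor(round((t1 - self.start_time_s) * self.fs, 9)))
        i0 = max(i0, 0)
        # right endpoint exclusive unless it is exactly the last sample time
        if self.start_time_s + i1 / self.fs >= t1:
            i1 -= 1
        i1 = min(i1, len(self.samples) - 1)
        if i1 < i0:
            raise ValueError("crop span contains no samples")
        return replace(
            self,
            samples=self.samples[i0 : i1 + 1].copy(),
            start_time_s=self.start_time_s + i0 / self.fs,
        )

    def shifted(self, offset_s: float) -> "UniformSignal":
        """Same samples on a time axis shifted by ``offset_s``."""
        return replace(self, start_time_s=self.start_time_s + offset_s)


MIN_BEAT_GAP_S = 0.2  #: physiological refractory floor between beats


@dataclass
class BeatSeries:
    """Ordered beat event times (R-peaks or pulse onsets), scene-relative."""

    times_s: np.ndarray
    kind: str = "r_peak"  # or "pulse_onset"
    source_fs: float = ECG_FS

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("beat times must be one-dimensional")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.times_s)


@dataclass
class HRSeries:
    """Heart-rate values in bpm, beat-domain or uniform 4 Hz."""

    times_s: np.ndarray
    bpm: np.ndarray
    domain: str = "beat"  # or "uniform_4hz"
    device: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.times_s.shape != self.bpm.shape:
            raise ValueError("times and bpm must have equal length")
        if self.domain == "uniform_4hz" and len(self.times_s) > 1:
            dt = np.diff(self.times_s)
            if not np.allclose(dt, 0.25, atol=1e-9):
                raise ValueError("uniform_4hz series must have 0.25 s spacing")

    def __len__(self) -> int:
        return len(self.bpm)


@dataclass
class SessionManifest:
    """Per-subject index of scene recordings on disk.

    ``scenes`` maps scene label -> dict with keys ``ecg_path``, ``bvp_path``,
    ``start_time_s`` and ``event_times_s`` (empty except for IS).
    """

    subject_id: str
    scenes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.scenes:
            if label not in SCENES:
                raise ValueError(f"unknown scene label {label!r}")
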