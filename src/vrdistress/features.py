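"""Heart-rate features: beat times -> smoothed HR -> uniform 4 Hz series
-> 10 s windows -> mean HR / RMSSD -> personalized thresholds.

RMSSD here follows the ultra-short-term convention used throughout this
pipeline: the root mean square of successive differences of the 4 Hz HR
samples (bpm) inside each window — not the classical RMSSD over
NN intervals in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import BeatSeries, HRSeries

SMOOTH_WINDOW = 3  # boxcar length, samples (beat domain)
RESAMPLE_HZ = 4.0
WINDOW_S = 10.0
HR_MULTIPLIER = 1.3
RMSSD_MULTIPLIER = 0.5


def boxcar_duration_ms(n_samples: int, fs: float) -> float:
    """Duration of an ``n_samples`` boxcar at sampling rate ``fs``, in ms."""
    return 1000.0 * n_samples / fs


def beats_to_hr(beats: BeatSeries, smooth_window: int = SMOOTH_WINDOW,
                device: str = "") -> HRSeries:
    """Instantaneous HR (60/RR, bpm) at each beat time, boxcar-smoothed.

    HR_i = 60 / (t_i - t_{i-1}) is assigned at t_i; the boxcar moving
    average of length ``smooth_window`` uses reflective edge padding so
    the output length matches.
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to compute HR")
    rr = beats.rr_intervals()
    if np.any(rr <= 0):
        raise ValueError("non-positive inter-beat interval")
    hr = 60.0 / rr
    times = beats.times_s[1:]
    if smooth_window > 1:
        hr = _boxcar_reflect(hr, smooth_window)
    return HRSeries(times, hr, domain="beat", device=device)


def _boxcar_reflect(x: np.ndarray, w: int) -> np.ndarray:
    if w > len(x):
        w = len(x) if len(x) % 2 else len(x) - 1
        if w <= 1:
            return x.copy()
    half = (w - 1) // 2
    left = x[1 : half + 1][::-1] if half else np.empty(0)
    rhalf = w - 1 - half
    right = x[-rhalf - 1 : -1][::-1] if rhalf else np.empty(0)
    padded = np.concatenate([left, x, right])
    return np.convolve(padded, np.ones(w) / w, mode="valid")


def resample_4hz(hr: HRSeries, grid_start_s: float, grid_end_s: float,
                 rate_hz: float = RESAMPLE_HZ) -> HRSeries:
    """Linear interpolation of a beat-domain HR series onto a 4 Hz grid.

    Grid points are ``grid_start + k * 0.25 s`` for ``k`` with time
    strictly below ``grid_end``; values outside the beat span are held at
    the nearest beat's HR.  Both devices resampled onto the identical grid
    pair 1:1.
    """
    if len(hr) == 0:
        raise ValueError("cannot resample an empty HR series")
    if grid_end_s <= grid_start_s:
        raise ValueError("empty resampling grid")
    n = int(np.floor(round((grid_end_s - grid_start_s) * rate_hz, 9)))
    grid = grid_start_s + np.arange(n) / rate_hz
    vals = np.interp(grid, hr.times_s, hr.bpm)  # np.interp holds at edges
    return HRSeries(grid, vals, domain="uniform_4hz", device=hr.device)


@dataclass
class SegmentFeature:
    """Mean HR and RMSSD over one 10 s window."""

    window_index: int
    start_s: float
    end_s: float
    mean_hr_bpm: float
    rmssd_bpm: float
    n_samples: int


def mean_hr(values) -> float:
    """Arithmetic mean of the window's HR samples, bpm."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty window")
    return float(values.mean())


def rmssd(values) -> float:
    """Root mean square of successive differences of the window's samples."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("RMSSD needs at least 2 values")
    d = np.diff(values)
    return float(np.sqrt(np.mean(d * d)))


def segment_windows(hr: HRSeries, window_s: float = WINDOW_S):
    """Split a uniform 4 Hz HR series into consecutive 10 s windows.

    Windows are ``[k*10, (k+1)*10)`` from the series start; a trailing
    incomplete window is discarded.  Returns a list of
    :class:`SegmentFeature` with mean HR and RMSSD filled in.
    """
    if hr.domain != "uniform_4hz":
        raise ValueError("segmentation expects a uniform_4hz series")
    per = int(round(window_s * RESAMPLE_HZ))
    n_windows = len(hr) // per
    if n_windows == 0:
        raise ValueError("series shorter than one window")
    t0 = hr.times_s[0]
    out = []
    for k in range(n_windows):
        chunk = hr.bpm[k * per : (k + 1) * per]
        out.append(
            SegmentFeature(
                window_index=k,
                start_s=t0 + k * window_s,
                end_s=t0 + (k + 1) * window_s,
                mean_hr_bpm=mean_hr(chunk),
                rmssd_bpm=rmssd(chunk),
                n_samples=per,
            )
        )
    return out


@dataclass
class ThresholdPair:
    """Subject-specific distress thresholds derived from the baseline scene."""

    hr_baseline_min_bpm: float
    rmssd_baseline_median_bpm: float
    hr_multiplier: float = HR_MULTIPLIER
    rmssd_multiplier: float = RMSSD_MULTIPLIER


def compute_thresholds(baseline_hr: HRSeries,
                       window_s: float = WINDOW_S) -> ThresholdPair:
    """Personalized thresholds from a subject's baseline 4 Hz HR series.

    The HR reference is the minimum over all baseline samples (taken as
    the resting HR); the RMSSD reference is the median of the per-window
    RMSSD values over the entire baseline (even counts average the two
    central values).
    """
    if len(baseline_hr) < 2 * int(window_s * RESAMPLE_HZ):
        raise ValueError("baseline must span at least two complete windows")
    feats = segment_windows(baseline_hr, window_s)
    return ThresholdPair(
        hr_baseline_min_bpm=float(baseline_hr.bpm.min()),
        rmssd_baseline_median_bpm=float(
            np.median([f.rmssd_bpm for f in feats])
        ),
    )
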