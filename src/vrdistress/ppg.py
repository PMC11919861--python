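"""Wrist-BVP processing: zero-phase Butterworth bandpass and Elgendi
onset detection.

Elgendi's scheme finds systolic peaks by comparing two moving averages of
the clipped-squared signal: a short one tracking individual peaks
(W1 = 111 ms) against a longer one tracking whole beats (W2 = 667 ms)
plus a small offset proportional to the overall signal power.  Each
above-threshold block at least W1 wide yields one beat; the reported beat
anchor is the pulse onset (the local minimum preceding the systolic
maximum), with the systolic peak available behind a switch.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signals import BeatSeries, UniformSignal

BUTTER_ORDER = 4
BUTTER_BAND_HZ = (1.0, 8.0)

W1_S = 0.111  # systolic-peak moving-average window
W2_S = 0.667  # beat moving-average window
BETA = 0.02
PPG_REFRACTORY_S = 0.2
MIN_PEAK_FRACTION = 1 / 3  # reject blocks far below the median systolic height


def butter_bandpass_bvp(
    sig: UniformSignal,
    band_hz: tuple = BUTTER_BAND_HZ,
    order: int = BUTTER_ORDER,
) -> UniformSignal:
    """Zero-phase 4th-order Butterworth bandpass, 1-8 Hz.

    Forward-backward application doubles the effective order (8 poles of
    attenuation) while cancelling phase; length is preserved.
    """
    if sig.fs < 32:
        raise ValueError("BVP bandpass expects fs >= 32 Hz")
    sos = sps.butter(order, band_hz, btype="bandpass", fs=sig.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(sig) <= 3 * padlen:
        raise ValueError(f"signal too short for filtering: {len(sig)} samples")
    filtered = sps.sosfiltfilt(sos, sig.samples, padtype="even")
    return UniformSignal(filtered, fs=sig.fs, start_time_s=sig.start_time_s,
                         channel=sig.channel)


def detect_onsets_elgendi(
    sig: UniformSignal, return_peaks: bool = False
) -> BeatSeries:
    """Detect pulse beats in a bandpassed BVP signal.

    Returns onsets by default (``kind="pulse_onset"``); with
    ``return_peaks=True`` returns systolic maxima instead.  A flat signal
    yields an empty series.
    """
    fs = sig.fs
    x = sig.samples
    if len(x) == 0:
        return BeatSeries(np.empty(0), kind="pulse_onset", source_fs=fs)

    clipped = np.clip(x, 0.0, None)
    sq = clipped * clipped
    if sq.max() <= 1e-24:
        return BeatSeries(np.empty(0), kind="pulse_onset", source_fs=fs)

    w1 = max(int(round(W1_S * fs)), 1)
    w2 = max(int(round(W2_S * fs)), 2)
    ma_peak = np.convolve(sq, np.ones(w1) / w1, mode="same")
    ma_beat = np.convolve(sq, np.ones(w2) / w2, mode="same")
    thr = ma_beat + BETA * sq.mean()

    above = ma_peak > thr
    # contiguous above-threshold blocks
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive

    peak_idx: list[int] = []
    for s, e in zip(starts, ends):
        if (e - s) < w1:
            continue
        peak_idx.append(s + int(np.argmax(x[s:e])))

    # refractory: merge peaks closer than 200 ms, keep the taller
    min_gap = int(round(PPG_REFRACTORY_S * fs))
    kept: list[int] = []
    for p in peak_idx:
        if kept and p - kept[-1] < min_gap:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)

    # prune low-amplitude blocks (filter rebound between slow beats): a
    # rebound can rival true beats in number, so reference the upper
    # quartile of block heights rather than the median
    if len(kept) >= 3:
        ref = float(np.percentile(x[np.asarray(kept)], 75))
        if ref > 0:
            kept = [p for p in kept if x[p] >= MIN_PEAK_FRACTION * ref]

    if return_peaks:
        times = sig.start_time_s + np.asarray(kept, float) / fs
        return BeatSeries(times, kind="systolic_peak", source_fs=fs)

    # onset = minimum of the pre-systolic trough: global argmin over the
    # window between the previous peak and this one (capped at 350 ms),
    # which is robust to noise micro-minima on the upstroke
    onset_idx: list[int] = []
    max_back = int(round(0.35 * fs))
    for k, p in enumerate(kept):
        lo = max(p - max_back, 0, (kept[k - 1] + 1) if k else 0)
        if lo >= p:
            lo = max(p - 1, 0)
        onset_idx.append(lo + int(np.argmin(x[lo : p + 1])))

    # dedupe/refractory on onsets as well
    final: list[int] = []
    for o in onset_idx:
        if final and o - final[-1] < min_gap:
            continue
        final.append(o)
    times = sig.start_time_s + np.asarray(final, float) / fs
    return BeatSeries(times, kind="pulse_onset", source_fs=fs)


def bvp_to_beats(sig: UniformSignal, return_peaks: bool = False) -> BeatSeries:
    """Full BVP chain: bandpass -> Elgendi beat detection."""
    return detect_onsets_elgendi(butter_bandpass_bvp(sig), return_peaks)
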