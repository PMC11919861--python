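"""Chest-ECG processing: zero-phase FIR bandpass, Hamilton QRS detection,
template-matching R-peak correction.

The detector follows Hamilton's open-source QRS scheme: differentiate,
rectify, 80 ms moving-average envelope, then adaptive classification of
envelope peaks against running QRS/noise averages with a 200 ms refractory
period and a search-back pass at 1.5x the running mean RR.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .signals import BeatSeries, UniformSignal

# Hamilton detector constants ("EP-limited" defaults)
ENVELOPE_WINDOW_S = 0.080
THRESHOLD_COEFF = 0.3125
REFRACTORY_S = 0.200
SEARCHBACK_FACTOR = 1.5
SNAP_WINDOW_S = 0.040
_RUNNING_LEN = 8

FIR_BAND_HZ = (3.0, 45.0)
FIR_ORDER_FACTOR = 0.3


def fir_bandpass_ecg(
    sig: UniformSignal,
    band_hz: tuple = FIR_BAND_HZ,
    order_factor: float = FIR_ORDER_FACTOR,
) -> UniformSignal:
    """Zero-phase FIR bandpass, passband 3-45 Hz, order ``0.3 * fs``.

    The Hamming-window FIR order is rounded to the nearest even value so
    the filter is linear-phase type I; applied forward-backward
    (``filtfilt``) so the net phase is zero.  Output length equals input
    length.
    """
    if sig.fs < 100:
        raise ValueError("ECG bandpass expects fs >= 100 Hz")
    order = int(round(order_factor * sig.fs))
    if order % 2:
        order += 1
    ntaps = order + 1
    if len(sig) < 3 * ntaps:
        raise ValueError(
            f"signal too short for filtering: {len(sig)} < 3 x {ntaps} taps"
        )
    taps = sps.firwin(
        ntaps, band_hz, fs=sig.fs, pass_zero=False, window="hamming"
    )
    # at this order the Hamming transition band is wide enough that DC
    # leaks through; mean-correcting the taps forces an exact null at 0 Hz
    # while perturbing the rest of the response by < 1%
    taps = taps - taps.mean()
    filtered = sps.filtfilt(taps, [1.0], sig.samples, padtype="even",
                            padlen=3 * ntaps)
    return UniformSignal(filtered, fs=sig.fs, start_time_s=sig.start_time_s,
                         channel=sig.channel)


def _envelope(x: np.ndarray, fs: float) -> np.ndarray:
    d = np.abs(np.diff(x, prepend=x[0]))
    w = max(int(round(ENVELOPE_WINDOW_S * fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(d, kernel, mode="same")


def detect_qrs_hamilton(sig: UniformSignal) -> BeatSeries:
    """Detect R-peaks in a bandpassed ECG with Hamilton's adaptive rules.

    Returns peak times snapped to the local signal maximum within +/-40 ms
    of each envelope detection.  A flat or near-flat signal yields an
    empty series.
    """
    fs = sig.fs
    x = sig.samples
    if len(x) < int(fs):
        return BeatSeries(np.empty(0), kind="r_peak", source_fs=fs)
    env = _envelope(x, fs)
    if env.max() <= 1e-12 or env.max() < 1e-6 * max(np.abs(x).max(), 1e-30):
        return BeatSeries(np.empty(0), kind="r_peak", source_fs=fs)

    # candidate envelope peaks, minimum separation = refractory period
    min_dist = max(int(REFRACTORY_S * fs), 1)
    peaks, _ = sps.find_peaks(env, distance=min_dist,
                              height=0.01 * env.max())
    if len(peaks) == 0:
        return BeatSeries(np.empty(0), kind="r_peak", source_fs=fs)

    # initialize running averages from the first two seconds
    lead = peaks[peaks < 2 * fs]
    init_qrs = env[lead].max() if len(lead) else env[peaks].max()
    init_noise = 0.1 * init_qrs
    qrs_peaks = [init_qrs] * _RUNNING_LEN
    noise_peaks = [init_noise] * _RUNNING_LEN
    rr_hist: list[float] = []

    def threshold() -> float:
        qa = np.mean(qrs_peaks[-_RUNNING_LEN:])
        na = np.mean(noise_peaks[-_RUNNING_LEN:])
        return na + THRESHOLD_COEFF * (qa - na)

    detections: list[int] = []
    rejected: list[tuple[int, float]] = []  # (index, height) below threshold

    for p in peaks:
        h = env[p]
        since_last = (p - detections[-1]) / fs if detections else np.inf
        mean_rr = np.mean(rr_hist[-_RUNNING_LEN:]) if rr_hist else None

        # search-back: expected beat overdue -> revisit rejected peaks
        if (
            detections
            and mean_rr is not None
            and since_last > SEARCHBACK_FACTOR * mean_rr
        ):
            window = [
                (i, hh)
                for i, hh in rejected
                if detections[-1] + min_dist <= i <= p - min_dist
            ]
            if window:
                bi, bh = max(window, key=lambda ih: ih[1])
                if bh > 0.5 * threshold():
                    rr_hist.append((bi - detections[-1]) / fs)
                    detections.append(bi)
                    qrs_peaks.append(bh)
                    rejected = [(i, hh) for i, hh in rejected if i > bi]
                    since_last = (p - bi) / fs

        if h > threshold() and since_last >= REFRACTORY_S:
            if detections:
                rr_hist.append(since_last)
            detections.append(p)
            qrs_peaks.append(h)
        else:
            noise_peaks.append(h)
            rejected.append((p, h))

    # final search-back for a trailing overdue beat
    if detections and rr_hist:
        mean_rr = np.mean(rr_hist[-_RUNNING_LEN:])
        tail = (len(x) - 1 - detections[-1]) / fs
        if tail > SEARCHBACK_FACTOR * mean_rr:
            window = [(i, hh) for i, hh in rejected
                      if i >= detections[-1] + min_dist]
            if window:
                bi, bh = max(window, key=lambda ih: ih[1])
                if bh > 0.5 * threshold():
                    detections.append(bi)

    # snap each detection to the local signal maximum
    snap = int(round(SNAP_WINDOW_S * fs))
    r_idx = []
    for p in detections:
        i0, i1 = max(p - snap, 0), min(p + snap + 1, len(x))
        r_idx.append(i0 + int(np.argmax(x[i0:i1])))
    r_idx = np.unique(r_idx)

    # enforce refractory after snapping (keep the larger peak)
    kept: list[int] = []
    for i in r_idx:
        if kept and (i - kept[-1]) < min_dist:
            if x[i] > x[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    times = sig.start_time_s + np.asarray(kept, dtype=float) / fs
    return BeatSeries(times, kind="r_peak", source_fs=fs)


TEMPLATE_HALF_S = 0.100
SHIFT_WINDOW_S = 0.050


def correct_rpeaks_template(
    sig: UniformSignal, beats: BeatSeries
) -> BeatSeries:
    """Refine R-peak times by cross-correlation against the mean beat.

    The mean template is built from -100..+100 ms windows around each
    beat; each beat is then shifted to the lag within +/-50 ms that
    maximizes the normalized cross-correlation with the template.  With
    fewer than 3 beats the input is returned unchanged (with a warning).
    """
    if len(beats) < 3:
        warnings.warn("fewer than 3 beats; template correction skipped")
        return beats
    fs = sig.fs
    x = sig.samples
    half = int(round(TEMPLATE_HALF_S * fs))
    shift_max = int(round(SHIFT_WINDOW_S * fs))
    idx = np.round((beats.times_s - sig.start_time_s) * fs).astype(int)

    windows = []
    for i in idx:
        if i - half >= 0 and i + half + 1 <= len(x):
            windows.append(x[i - half : i + half + 1])
    if len(windows) < 3:
        warnings.warn("too few full beat windows; template correction skipped")
        return beats
    template = np.mean(windows, axis=0)
    template = template - template.mean()
    tnorm = np.linalg.norm(template)
    if tnorm == 0:
        return beats

    corrected: list[tuple[int, float]] = []  # (index, best correlation)
    for i in idx:
        best_lag, best_c = 0, -np.inf
        if i - half < 0 or i + half + 1 > len(x):
            # centered window runs off the recording: leave the beat alone
            corrected.append((i, best_c))
            continue
        for lag in range(-shift_max, shift_max + 1):
            j = i + lag
            if j - half < 0 or j + half + 1 > len(x):
                continue
            w = x[j - half : j + half + 1]
            w = w - w.mean()
            denom = np.linalg.norm(w) * tnorm
            if denom == 0:
                continue
            c = float(np.dot(w, template) / denom)
            if c > best_c:
                best_c, best_lag = c, lag
        corrected.append((i + best_lag, best_c))

    # restore ordering/refractory: on conflict keep the better-correlated beat
    min_gap = int(round(REFRACTORY_S * fs))
    kept: list[tuple[int, float]] = []
    for j, c in sorted(corrected):
        if kept and j - kept[-1][0] < min_gap:
            if c > kept[-1][1]:
                kept[-1] = (j, c)
        else:
            kept.append((j, c))
    times = sig.start_time_s + np.asarray([j for j, _ in kept], float) / fs
    return BeatSeries(times, kind="r_peak", source_fs=fs)


def ecg_to_beats(sig: UniformSignal) -> BeatSeries:
    """Full ECG chain: bandpass -> Hamilton detection -> template correction."""
    filtered = fir_bandpass_ecg(sig)
    beats = detect_qrs_hamilton(filtered)
    if len(beats) >= 3:
        beats = correct_rpeaks_template(filtered, beats)
    return beats
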