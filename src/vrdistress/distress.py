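"""Rule-based distress detection and the interactive-scene event analysis.

Per 10 s window, two flags are raised against the subject's personalized
baseline thresholds: mean HR strictly above 1.3x the baseline HR minimum,
and RMSSD strictly below 0.5x the baseline RMSSD median.  The window's
distress level is the flag sum: 0 low/absent, 1 medium, 2 high.

For the interactive scene, each startle event is inspected through three
windows — immediately before onset, [t, t+10) and [t+10, t+20) — and a
subject's event-coincidence percentage is reported under a lenient (>= 1
of 3 windows detecting) and a strict (>= 2 of 3) criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import SegmentFeature, ThresholdPair


@dataclass
class DistressVector:
    """Per-window component flags and combined level in {0, 1, 2}."""

    hr_flags: np.ndarray
    rmssd_flags: np.ndarray
    levels: np.ndarray
    window_starts_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.levels)


def flag_segments(features: list[SegmentFeature], thr: ThresholdPair):
    """Compare each window's features against the personalized thresholds.

    Returns ``(hr_flags, rmssd_flags)`` as 0/1 arrays.  Inequalities are
    strict: a window exactly at a threshold is not flagged.  A degenerate
    RMSSD threshold of 0 (constant baseline) can never be undercut, so
    those flags are all 0 and a warning is emitted.
    """
    hr_thr = thr.hr_multiplier * thr.hr_baseline_min_bpm
    rmssd_thr = thr.rmssd_multiplier * thr.rmssd_baseline_median_bpm
    if rmssd_thr <= 0:
        warnings.warn(
            "RMSSD baseline threshold is 0; RMSSD flags will always be 0"
        )
    hr_flags = np.array(
        [1 if f.mean_hr_bpm > hr_thr else 0 for f in features], dtype=int
    )
    rmssd_flags = np.array(
        [1 if f.rmssd_bpm < rmssd_thr else 0 for f in features], dtype=int
    )
    return hr_flags, rmssd_flags


def combine_flags(hr_flags, rmssd_flags,
                  window_starts_s=None) -> DistressVector:
    """Elementwise flag sum: 0 = low/absent, 1 = medium, 2 = high distress."""
    hr_flags = np.asarray(hr_flags, dtype=int)
    rmssd_flags = np.asarray(rmssd_flags, dtype=int)
    if hr_flags.shape != rmssd_flags.shape:
        raise ValueError("flag vectors must have equal length")
    if window_starts_s is None:
        window_starts_s = 10.0 * np.arange(len(hr_flags))
    return DistressVector(
        hr_flags=hr_flags,
        rmssd_flags=rmssd_flags,
        levels=hr_flags + rmssd_flags,
        window_starts_s=np.asarray(window_starts_s, dtype=float),
    )


def count_levels(dv: DistressVector) -> dict:
    """Tally of windows at each distress level; values sum to the count."""
    return {lvl: int(np.sum(dv.levels == lvl)) for lvl in (0, 1, 2)}


ABSENT = None  # marker for event windows beyond the recorded span


def extract_event_segments(dv: DistressVector, event_times_s,
                           window_s: float = 10.0):
    """Distress levels of the three windows around each event.

    For an event at ``t`` the nominal windows cover ``[t-10, t)``,
    ``[t, t+10)`` and ``[t+10, t+20)``; windows outside the recorded span
    are marked absent (``None``).
    """
    n = len(dv)
    out = []
    for e in np.asarray(event_times_s, dtype=float):
        triplet = []
        for k, start in enumerate((e - window_s, e, e + window_s)):
            idx = int(np.floor(round(start / window_s, 9)))
            if 0 <= idx < n:
                triplet.append(int(dv.levels[idx]))
            else:
                triplet.append(ABSENT)
        out.append((float(e), tuple(triplet)))
    return out


@dataclass
class EventReport:
    """Per-event detection outcomes and subject-level percentages."""

    events: list  # (time_s, (levels...), criterion_1_3, criterion_2_3)
    pct_1_3: float
    pct_2_3: float


def event_coincidence(triplets) -> EventReport:
    """Event-coincidence percentages under the 1/3 and 2/3 criteria.

    A window "detects distress" iff its level is >= 1 (medium or high).
    Absent windows count as non-detecting but stay in the denominator of
    three, so an event truncated by the recording end can still only
    satisfy a criterion through its recorded windows.
    """
    if len(triplets) == 0:
        raise ValueError("no events to analyze")
    events = []
    n13 = n23 = 0
    for t, levels in triplets:
        if all(l is ABSENT for l in levels):
            raise ValueError(f"event at {t} s has no recorded window")
        detecting = sum(1 for l in levels if l is not ABSENT and l >= 1)
        c13 = detecting >= 1
        c23 = detecting >= 2
        n13 += c13
        n23 += c23
        events.append((t, levels, c13, c23))
    n = len(triplets)
    return EventReport(
        events=events,
        pct_1_3=100.0 * n13 / n,
        pct_2_3=100.0 * n23 / n,
    )
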