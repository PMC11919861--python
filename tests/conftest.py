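import numpy as np
import pytest

from vrdistress import synthetic as syn


@pytest.fixture(scope="session")
def calm_profile():
    return syn.SubjectProfile(
        resting_hr_bpm=70.0, hrv_sd_ms=30.0, distress_hr_gain=0.0
    )


@pytest.fixture(scope="session")
def clean_session_is():
    """One clean interactive-scene recording with the default effect sizes."""
    profile = syn.SubjectProfile(resting_hr_bpm=70.0, seed=11)
    return syn.generate_session(profile, "IS", seed=11, clean=True)


@pytest.fixture(scope="session")
def clean_subject_sessions():
    """A full clean subject: baseline, NIS and IS recordings."""
    profile = syn.SubjectProfile(resting_hr_bpm=70.0, seed=11)
    return {
        scene: syn.generate_session(profile, scene, seed=11, clean=True)
        for scene in ("baseline", "NIS", "IS")
    }


@pytest.fixture(scope="session")
def clean_cohort8():
    """Eight clean subjects for parameter-recovery checks."""
    return syn.generate_cohort(8, seed=0, clean=True)


@pytest.fixture(scope="session")
def noisy_cohort16_reports():
    """Sixteen subjects under the default sensor-noise model, analyzed."""
    from vrdistress import pipeline as pl

    cohort = syn.generate_cohort(16, seed=0)
    return [
        pl.analyze_recordings(f"S{i + 1:02d}", sessions)
        for i, (_, sessions) in enumerate(cohort)
    ]


def match_beats(detected: np.ndarray, truth: np.ndarray, tol_s: float):
    """Greedy one-to-one matching; returns (n_matched, n_false, n_missed)."""
    used = np.zeros(len(detected), dtype=bool)
    matched = 0
    for t in truth:
        if len(detected) == 0:
            break
        free = np.flatnonzero(~used)
        if len(free) == 0:
            break
        j = free[np.argmin(np.abs(detected[free] - t))]
        if abs(detected[j] - t) <= tol_s:
            used[j] = True
            matched += 1
    return matched, int((~used).sum()), len(truth) - matched
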