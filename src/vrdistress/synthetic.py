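"""Synthetic paired ECG/BVP session generator.

Emulates the study protocol: per subject, three 4-minute recordings
(baseline, a calm non-interactive VR scene "NIS", and an interactive VR
scene "IS" with startle events at 120/180/240 s), captured simultaneously
by a chest ECG at 500 Hz and a wrist blood-volume-pulse sensor at 64 Hz.

Both waveforms are driven by one shared ground-truth RR process, so every
downstream stage (beat detection, HR features, distress flags, device
agreement) can be validated against known truth.

Model sketch
------------
* RR process: stationary AR(1) on log-RR around 60/resting_hr, with
  relative jitter scale set by ``hrv_sd_ms``.
* Distress response (IS only): each event contributes a phasic trapezoid
  (2 s ramps, 20 s hold) plus a tonic sensitization term that decays over
  minutes — repeated scares leave the subject aroused, which is what makes
  the final event (coinciding with scene end) detectable in the window
  that precedes it. During response, mean HR is scaled by
  ``1 + distress_hr_gain * g(t)`` and RR jitter by
  ``1 - distress_rmssd_drop * g(t)`` with envelope ``g`` clipped to [0, 1].
* ECG: fixed sum-of-Gaussians PQRST template at each beat, plus baseline
  wander, powerline tone and white noise.
* BVP: pulse template delayed by the pulse transit time, plus motion
  spikes (Poisson) and contact-loss stretches (low-amplitude noise floor),
  both logged as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signals import BVP_FS, ECG_FS, SCENES, UniformSignal

IS_EVENT_TIMES_S = (120.0, 180.0, 240.0)
DEFAULT_DURATION_S = 240.0


# ---------------------------------------------------------------------------
# profiles and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    """Per-subject physiology and sensor-quality parameters."""

    resting_hr_bpm: float = 70.0
    hrv_sd_ms: float = 40.0
    distress_hr_gain: float = 0.4
    distress_rmssd_drop: float = 0.7
    artifact_rate_per_min: float = 1.0
    contact_loss_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.resting_hr_bpm <= 180.0:
            raise ValueError(
                f"resting HR {self.resting_hr_bpm} bpm outside [40, 180]"
            )
        if self.hrv_sd_ms < 0:
            raise ValueError("hrv_sd_ms must be >= 0")
        if self.distress_hr_gain < 0:
            raise ValueError("distress_hr_gain must be >= 0")
        if not 0.0 <= self.distress_rmssd_drop < 1.0:
            raise ValueError("distress_rmssd_drop must be in [0, 1)")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")
        if not 0.0 <= self.contact_loss_prob <= 1.0:
            raise ValueError("contact_loss_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Shared cardiac truth behind one session's paired recordings."""

    rr_intervals_s: np.ndarray
    beat_times_s: np.ndarray
    scene: str
    event_times_s: np.ndarray
    true_hr_trace: np.ndarray  # bpm at each beat time

    def __post_init__(self) -> None:
        self.rr_intervals_s = np.asarray(self.rr_intervals_s, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.true_hr_trace = np.asarray(self.true_hr_trace, dtype=float)


@dataclass
class SessionRecording:
    """One scene's paired ECG + BVP recording (synthetic or real)."""

    subject_id: str
    scene: str
    ecg: UniformSignal
    bvp: UniformSignal
    ground_truth: GroundTruth | None = None
    duration_s: float = DEFAULT_DURATION_S
    bvp_artifacts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# distress-response envelope
# ---------------------------------------------------------------------------

def response_envelope(
    t: np.ndarray,
    event_times_s,
    response_window_s: float = 20.0,
    ramp_s: float = 2.0,
    tonic_fraction: float = 0.6,
    tonic_tau_s: float = 180.0,
) -> np.ndarray:
    """Distress gain envelope ``g(t)`` in [0, 1] for the given events.

    Each event adds a phasic trapezoid (linear ``ramp_s`` rise, hold until
    ``response_window_s`` after onset, linear fall) and a slowly decaying
    tonic term of height ``tonic_fraction`` capturing sensitization.
    """
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    for e in np.asarray(event_times_s, dtype=float):
        dt = t - e
        rise = np.clip(dt / ramp_s, 0.0, 1.0)
        fall = np.clip(1.0 - (dt - response_window_s) / ramp_s, 0.0, 1.0)
        phasic = np.minimum(rise, fall)
        tonic = np.where(
            dt >= ramp_s,
            tonic_fraction * np.exp(-(dt - ramp_s) / tonic_tau_s),
            0.0,
        )
        g += np.maximum(phasic, tonic)
    return np.clip(g, 0.0, 1.0)


# ---------------------------------------------------------------------------
# RR process
# ---------------------------------------------------------------------------

def generate_rr_process(
    profile: SubjectProfile,
    scene: str,
    duration_s: float,
    seed: int,
    event_times_s=None,
    response_window_s: float = 20.0,
    ramp_s: float = 2.0,
    tonic_fraction: float = 0.6,
    tonic_tau_s: float = 180.0,
    ar_coeff: float = 0.9,
) -> GroundTruth:
    """Simulate the ground-truth beat sequence for one scene.

    The log-RR series is a unit-variance AR(1) (coefficient ``ar_coeff``)
    scaled to a relative jitter of ``hrv_sd_ms / resting RR``; during the
    distress envelope the local mean HR is multiplied by
    ``1 + distress_hr_gain * g`` and the jitter by
    ``1 - distress_rmssd_drop * g``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if scene not in SCENES:
        raise ValueError(f"unknown scene label {scene!r}")

    if event_times_s is None:
        event_times_s = IS_EVENT_TIMES_S if scene == "IS" else ()
    events = np.asarray(event_times_s, dtype=float)
    if scene != "IS" and len(events):
        raise ValueError("event times are only meaningful for the IS scene")

    rng = np.random.default_rng(seed)
    rr_rest = 60.0 / profile.resting_hr_bpm
    sigma = (profile.hrv_sd_ms / 1000.0) / rr_rest  # relative log-RR sd
    phi = ar_coeff

    rr_list: list[float] = []
    beat_list: list[float] = []
    t = 0.0
    z = rng.standard_normal() if sigma > 0 else 0.0
    while True:
        g = float(
            response_envelope(
                np.array([t]), events, response_window_s, ramp_s,
                tonic_fraction, tonic_tau_s,
            )[0]
        ) if len(events) else 0.0
        hr_mean = profile.resting_hr_bpm * (1.0 + profile.distress_hr_gain * g)
        jitter_scale = sigma * (1.0 - profile.distress_rmssd_drop * g)
        rr = (60.0 / hr_mean) * math.exp(jitter_scale * z)
        if t + rr > duration_s:
            break
        t += rr
        rr_list.append(rr)
        beat_list.append(t)
        z = phi * z + math.sqrt(1.0 - phi * phi) * rng.standard_normal()

    rr_arr = np.asarray(rr_list)
    beats = np.asarray(beat_list)
    return GroundTruth(
        rr_intervals_s=rr_arr,
        beat_times_s=beats,
        scene=scene,
        event_times_s=events,
        true_hr_trace=60.0 / rr_arr if len(rr_arr) else np.empty(0),
    )


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

# PQRST wave parameters: (amplitude, center offset from R [s], width [s])
_ECG_WAVES = (
    (0.12, -0.180, 0.025),   # P
    (-0.10, -0.035, 0.010),  # Q
    (1.00, 0.000, 0.012),    # R
    (-0.15, 0.035, 0.012),   # S
    (0.30, 0.250, 0.050),    # T
)
_ECG_TEMPLATE_HALFSPAN_S = 0.45
MIN_TEMPLATE_RR_S = 0.3  # below this, PQRST templates overlap nonphysically


@dataclass
class EcgNoiseSpec:
    """Additive ECG disturbances, in fractions of the R amplitude."""

    baseline_wander_amp: float = 0.05
    baseline_wander_freq_hz: float = 0.3
    powerline_amp: float = 0.01
    powerline_freq_hz: float = 50.0
    white_noise_sd: float = 0.02
    seed: int = 0

    @classmethod
    def clean(cls) -> "EcgNoiseSpec":
        return cls(0.0, 0.3, 0.0, 50.0, 0.0, 0)


def _pqrst(t_rel: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t_rel)
    for amp, mu, width in _ECG_WAVES:
        out += amp * np.exp(-0.5 * ((t_rel - mu) / width) ** 2)
    return out


def synthesize_ecg(
    gt: GroundTruth,
    fs: float = ECG_FS,
    noise: EcgNoiseSpec | None = None,
    duration_s: float | None = None,
) -> UniformSignal:
    """Render an ECG waveform from ground-truth beat times.

    A fixed PQRST template (sum of Gaussians, R apex exactly at the beat
    time) is placed at every beat; wander, powerline and white noise are
    then added per ``noise``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    noise = noise or EcgNoiseSpec()
    if duration_s is None:
        duration_s = (
            float(np.ceil(gt.beat_times_s[-1] + 0.5))
            if len(gt.beat_times_s)
            else 1.0
        )
    if len(gt.beat_times_s):
        if gt.beat_times_s[0] < 0 or gt.beat_times_s[-1] > duration_s:
            raise ValueError("beat times outside [0, duration]")
        if len(gt.rr_intervals_s) and gt.rr_intervals_s.min() < MIN_TEMPLATE_RR_S:
            raise ValueError(
                f"RR below {MIN_TEMPLATE_RR_S} s: PQRST templates would overlap"
            )

    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    half = int(round(_ECG_TEMPLATE_HALFSPAN_S * fs))
    for bt in gt.beat_times_s:
        c = int(round(bt * fs))
        i0, i1 = max(c - half, 0), min(c + half + 1, n)
        t_rel = np.arange(i0, i1) / fs - bt
        sig[i0:i1] += _pqrst(t_rel)

    rng = np.random.default_rng(noise.seed)
    t = np.arange(n) / fs
    if noise.baseline_wander_amp:
        phase = rng.uniform(0, 2 * np.pi)
        sig += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq_hz * t + phase
        )
    if noise.powerline_amp:
        phase = rng.uniform(0, 2 * np.pi)
        sig += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq_hz * t + phase
        )
    if noise.white_noise_sd:
        sig += noise.white_noise_sd * rng.standard_normal(n)
    return UniformSignal(sig, fs=fs, start_time_s=0.0, channel="ecg")


# ---------------------------------------------------------------------------
# BVP synthesis
# ---------------------------------------------------------------------------

@dataclass
class BvpNoiseSpec:
    """Additive BVP disturbances, in fractions of the pulse amplitude.

    ``inband_noise_sd`` is band-limited (1-8 Hz) noise inside the cardiac
    band — residual motion coupling the bandpass cannot remove, the main
    steady contributor to wrist-HR noise.
    """

    baseline_wander_amp: float = 0.1
    baseline_wander_freq_hz: float = 0.25
    white_noise_sd: float = 0.05
    inband_noise_sd: float = 0.12
    seed: int = 0

    @classmethod
    def clean(cls) -> "BvpNoiseSpec":
        return cls(0.0, 0.25, 0.0, 0.0, 0)


@dataclass
class BvpArtifactSpec:
    """Wrist-sensor artifact model: motion spikes and contact loss."""

    rate_per_min: float = 1.0
    spike_amp: float = 4.0
    spike_width_s: float = 0.25
    contact_loss_prob: float = 0.1  # per-minute chance of a loss episode
    loss_duration_range_s: tuple = (3.0, 8.0)
    loss_noise_sd: float = 0.02
    contact_loss_intervals_s: tuple | None = None  # explicit override
    seed: int = 0

    @classmethod
    def clean(cls) -> "BvpArtifactSpec":
        return cls(rate_per_min=0.0, contact_loss_prob=0.0)


# Gamma-shaped systolic wave (foot at 0, peak at alpha*tau = 0.18 s) with a
# small dicrotic bump.  The 1-8 Hz bandpass every consumer applies advances
# the waveform's apparent foot (the pre-upstroke local minimum) by ~18 ms,
# so templates are placed that much late and the *filtered* onset lands at
# the nominal transit delay.
_BVP_PULSE_ALPHA = 2.0
_BVP_PULSE_TAU = 0.09
_BVP_DICROTIC = (0.12, 0.38, 0.07)  # amp, center, width
_BVP_TEMPLATE_SPAN_S = 0.75
_FILTER_FOOT_ADVANCE_S = 0.018
DEFAULT_TRANSIT_DELAY_S = 0.25


def _pulse(t_rel: np.ndarray) -> np.ndarray:
    tc = np.clip(t_rel, 0.0, None)
    a, tau = _BVP_PULSE_ALPHA, _BVP_PULSE_TAU
    out = np.where(
        t_rel >= 0, (tc / (a * tau)) ** a * np.exp(a - tc / tau), 0.0
    )
    amp, mu, width = _BVP_DICROTIC
    out += amp * np.exp(-0.5 * ((t_rel - mu) / width) ** 2) * (t_rel > 0)
    return out


def synthesize_bvp(
    gt: GroundTruth,
    fs: float = BVP_FS,
    noise: BvpNoiseSpec | None = None,
    artifacts: BvpArtifactSpec | None = None,
    transit_delay_s: float = DEFAULT_TRANSIT_DELAY_S,
    duration_s: float | None = None,
):
    """Render a BVP waveform; returns ``(signal, artifact_metadata)``.

    The pulse foot is placed ``transit_delay_s`` after each ground-truth
    beat.  ``artifact_metadata`` maps ``"motion_spikes_s"`` to injected
    spike centers and ``"contact_loss_s"`` to (start, end) intervals where
    the waveform was replaced by a low-amplitude noise floor.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    noise = noise or BvpNoiseSpec()
    artifacts = artifacts or BvpArtifactSpec()
    if duration_s is None:
        duration_s = (
            float(np.ceil(gt.beat_times_s[-1] + 1.0))
            if len(gt.beat_times_s)
            else 1.0
        )
    if len(gt.beat_times_s) and (
        gt.beat_times_s[0] < 0 or gt.beat_times_s[-1] > duration_s
    ):
        raise ValueError("beat times outside [0, duration]")

    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    span = int(round(_BVP_TEMPLATE_SPAN_S * fs))
    for bt in gt.beat_times_s:
        foot = bt + transit_delay_s + _FILTER_FOOT_ADVANCE_S
        c = int(round(foot * fs))
        i0, i1 = max(c, 0), min(c + span + 1, n)
        if i0 >= n:
            continue
        t_rel = np.arange(i0, i1) / fs - foot
        sig[i0:i1] += _pulse(t_rel)

    rng = np.random.default_rng(noise.seed)
    t = np.arange(n) / fs
    if noise.baseline_wander_amp:
        phase = rng.uniform(0, 2 * np.pi)
        sig += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq_hz * t + phase
        )
    if noise.white_noise_sd:
        sig += noise.white_noise_sd * rng.standard_normal(n)
    if noise.inband_noise_sd:
        from scipy import signal as sps

        sos = sps.butter(2, (1.0, 8.0), btype="bandpass", fs=fs, output="sos")
        nz = sps.sosfilt(sos, rng.standard_normal(n))
        sd = nz.std()
        if sd > 0:
            sig += noise.inband_noise_sd * nz / sd

    # --- artifact injection -------------------------------------------------
    art_rng = np.random.default_rng(artifacts.seed)
    spike_times: list[float] = []
    if artifacts.rate_per_min > 0:
        n_spikes = art_rng.poisson(artifacts.rate_per_min * duration_s / 60.0)
        for ts in np.sort(art_rng.uniform(0, duration_s, n_spikes)):
            w = artifacts.spike_width_s
            c = int(round(ts * fs))
            half = int(round(2 * w * fs))
            i0, i1 = max(c - half, 0), min(c + half + 1, n)
            t_rel = np.arange(i0, i1) / fs - ts
            # biphasic bump (Gaussian derivative), random polarity
            amp = artifacts.spike_amp * art_rng.uniform(0.5, 1.5)
            pol = art_rng.choice((-1.0, 1.0))
            sig[i0:i1] += pol * amp * (-t_rel / w) * np.exp(
                -0.5 * (t_rel / w) ** 2
            )
            spike_times.append(float(ts))

    loss_intervals: list[tuple[float, float]] = []
    if artifacts.contact_loss_intervals_s is not None:
        loss_intervals = [
            (float(a), float(b)) for a, b in artifacts.contact_loss_intervals_s
        ]
    elif artifacts.contact_loss_prob > 0:
        lo, hi = artifacts.loss_duration_range_s
        for minute in range(int(np.ceil(duration_s / 60.0))):
            if art_rng.uniform() < artifacts.contact_loss_prob:
                dur = art_rng.uniform(lo, hi)
                start = art_rng.uniform(minute * 60.0, (minute + 1) * 60.0 - dur)
                loss_intervals.append((start, min(start + dur, duration_s)))
    for a, b in loss_intervals:
        i0 = max(int(round(a * fs)), 0)
        i1 = min(int(round(b * fs)), n)
        if i1 > i0:
            sig[i0:i1] = artifacts.loss_noise_sd * art_rng.standard_normal(
                i1 - i0
            )

    meta = {"motion_spikes_s": spike_times, "contact_loss_s": loss_intervals}
    return UniformSignal(sig, fs=fs, start_time_s=0.0, channel="bvp"), meta


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

def generate_session(
    profile: SubjectProfile,
    scene: str,
    seed: int | None = None,
    duration_s: float = DEFAULT_DURATION_S,
    clean: bool = False,
    subject_id: str = "synthetic",
) -> SessionRecording:
    """Generate one scene's paired 240 s recording with ground truth.

    ``clean=True`` disables all sensor noise and wrist artifacts (the
    waveforms are then pure template renderings of the shared RR truth).
    """
    if scene not in SCENES:
        raise ValueError(f"unknown scene label {scene!r}")
    if seed is None:
        seed = profile.seed
    ss = np.random.SeedSequence([int(seed) % (2**31), SCENES.index(scene)])
    rr_seed, ecg_seed, bvp_seed, art_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]

    gt = generate_rr_process(profile, scene, duration_s, rr_seed)
    if clean:
        ecg_noise = EcgNoiseSpec.clean()
        bvp_noise = BvpNoiseSpec.clean()
        art = BvpArtifactSpec.clean()
    else:
        ecg_noise = EcgNoiseSpec(seed=ecg_seed)
        bvp_noise = BvpNoiseSpec(seed=bvp_seed)
        art = BvpArtifactSpec(
            rate_per_min=profile.artifact_rate_per_min,
            contact_loss_prob=profile.contact_loss_prob,
            seed=art_seed,
        )
    ecg = synthesize_ecg(gt, fs=ECG_FS, noise=ecg_noise, duration_s=duration_s)
    bvp, meta = synthesize_bvp(
        gt, fs=BVP_FS, noise=bvp_noise, artifacts=art, duration_s=duration_s
    )
    return SessionRecording(
        subject_id=subject_id,
        scene=scene,
        ecg=ecg,
        bvp=bvp,
        ground_truth=gt,
        duration_s=duration_s,
        bvp_artifacts=meta,
    )


def sample_profile(rng: np.random.Generator, seed: int) -> SubjectProfile:
    """Draw one subject's physiology from the cohort distribution.

    Resting HR ~ N(70, 8) bpm clipped to [55, 90] (healthy adults in their
    early twenties); short-term RR variability ~ N(40, 8) ms clipped to
    [20, 60]; distress effect sizes fixed at the rule system's design
    points (HR gain 0.4, RMSSD drop 0.7).
    """
    return SubjectProfile(
        resting_hr_bpm=float(np.clip(rng.normal(70.0, 8.0), 55.0, 90.0)),
        hrv_sd_ms=float(np.clip(rng.normal(40.0, 8.0), 20.0, 60.0)),
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    seed: int = 0,
    clean: bool = False,
    duration_s: float = DEFAULT_DURATION_S,
    scenes=SCENES,
):
    """Generate ``n_subjects`` subjects x scenes of paired recordings.

    Returns a list of ``(SubjectProfile, {scene: SessionRecording})``.
    """
    ss = np.random.SeedSequence(int(seed) % (2**31))
    cohort = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        profile = sample_profile(np.random.default_rng(sub_seed), sub_seed)
        sessions = {
            scene: generate_session(
                profile,
                scene,
                seed=sub_seed,
                duration_s=duration_s,
                clean=clean,
                subject_id=f"S{i + 1:02d}",
            )
            for scene in scenes
        }
        cohort.append((profile, sessions))
    return cohort
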