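"""End-to-end orchestration: raw paired recordings -> per-subject distress
and agreement reports -> cohort tables and tests.

``run_subject`` executes the full chain for one subject: device pipelines
(ECG: FIR bandpass + Hamilton + template correction; BVP: Butterworth +
Elgendi onsets), beat-domain HR with boxcar-3 smoothing, resampling onto
a shared 4 Hz grid, 10 s window features, baseline-personalized
thresholds, distress vectors for the VR scenes, event coincidence for the
interactive scene, and device agreement for every scene.

``run_cohort`` aggregates subjects: per-level Wilcoxon signed-rank tests
(wrist vs chest interactive-scene counts, paired by subject), Cliff's
delta effect sizes, and mean +/- sd summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import agreement as agr
from . import distress as dst
from . import features as feat
from .ecg import ecg_to_beats
from .io import load_scene, read_manifest
from .ppg import bvp_to_beats
from .signals import DEVICES, UniformSignal
from .synthetic import IS_EVENT_TIMES_S, SessionRecording

log = logging.getLogger("vrdistress")


@dataclass
class RunConfig:
    """All pipeline tunables; the defaults are the analysis as designed."""

    smooth_window: int = feat.SMOOTH_WINDOW        # boxcar, beat-domain samples
    resample_hz: float = feat.RESAMPLE_HZ
    window_s: float = feat.WINDOW_S
    hr_multiplier: float = feat.HR_MULTIPLIER      # mean-HR flag at 1.3x
    rmssd_multiplier: float = feat.RMSSD_MULTIPLIER  # RMSSD flag at 0.5x
    event_times_s: tuple = IS_EVENT_TIMES_S
    ba_multiplier: float = agr.BA_MULTIPLIER
    ppg_use_peaks: bool = False                    # systolic peaks vs onsets
    seed: int = 0


@dataclass
class SubjectReport:
    """Everything computed for one subject."""

    subject_id: str
    features: pd.DataFrame            # device x scene x window features
    thresholds: dict                  # device -> ThresholdPair
    distress: dict = field(default_factory=dict)   # scene -> device -> vector
    level_counts: dict = field(default_factory=dict)
    event_reports: dict = field(default_factory=dict)  # device -> EventReport
    agreement: dict = field(default_factory=dict)  # scene -> AgreementReport
    skipped: dict = field(default_factory=dict)    # scene -> reason


def _device_hr(ecg: UniformSignal, bvp: UniformSignal, config: RunConfig,
               grid_end_s: float):
    """Per-device 4 Hz HR series on the shared scene grid."""
    out = {}
    beats = {
        "faros": ecg_to_beats(ecg),
        "e4": bvp_to_beats(bvp, return_peaks=config.ppg_use_peaks),
    }
    for device in DEVICES:
        hr = feat.beats_to_hr(
            beats[device], smooth_window=config.smooth_window, device=device
        )
        out[device] = feat.resample_4hz(hr, 0.0, grid_end_s)
    return out, beats


def analyze_sessions(subject_id: str, scenes: dict,
                     config: RunConfig | None = None) -> SubjectReport:
    """Run the full analysis for one subject.

    ``scenes`` maps scene label -> ``(ecg, bvp, event_times_s)`` with
    scene-relative signals.  A baseline scene is required (thresholds are
    undefined without it); any other scene whose streams fail to process
    is skipped with a logged reason.
    """
    config = config or RunConfig()
    if "baseline" not in scenes:
        raise ValueError(
            f"{subject_id}: no baseline scene; cannot personalize thresholds"
        )

    hr_by_scene: dict = {}
    skipped: dict = {}
    for scene, (ecg, bvp, events) in scenes.items():
        grid_end = float(np.floor(min(ecg.duration_s, bvp.duration_s)))
        try:
            hr_by_scene[scene], _ = _device_hr(ecg, bvp, config, grid_end)
        except Exception as exc:  # corrupted stream -> skip, keep going
            if scene == "baseline":
                raise
            log.warning("%s/%s skipped: %s", subject_id, scene, exc)
            skipped[scene] = str(exc)

    rows = []
    feats_by = {}
    for scene, by_device in hr_by_scene.items():
        for device, hr4 in by_device.items():
            feats = feat.segment_windows(hr4, config.window_s)
            feats_by[(scene, device)] = feats
            rows += [
                {
                    "subject": subject_id,
                    "device": device,
                    "scene": scene,
                    "window_index": f.window_index,
                    "start_s": f.start_s,
                    "mean_hr": f.mean_hr_bpm,
                    "rmssd": f.rmssd_bpm,
                }
                for f in feats
            ]

    thresholds = {
        device: feat.compute_thresholds(
            hr_by_scene["baseline"][device], config.window_s
        )
        for device in DEVICES
    }
    for device, thr in thresholds.items():
        thr.hr_multiplier = config.hr_multiplier
        thr.rmssd_multiplier = config.rmssd_multiplier

    report = SubjectReport(
        subject_id=subject_id,
        features=pd.DataFrame(rows),
        thresholds=thresholds,
        skipped=skipped,
    )

    for scene in hr_by_scene:
        if scene == "baseline":
            continue
        report.distress[scene] = {}
        report.level_counts[scene] = {}
        for device in DEVICES:
            flags = dst.flag_segments(
                feats_by[(scene, device)], thresholds[device]
            )
            dv = dst.combine_flags(
                *flags,
                window_starts_s=[
                    f.start_s for f in feats_by[(scene, device)]
                ],
            )
            report.distress[scene][device] = dv
            report.level_counts[scene][device] = dst.count_levels(dv)

        events = scenes[scene][2]
        if scene == "IS" and events:
            report.event_reports = report.event_reports or {}
            for device in DEVICES:
                triplets = dst.extract_event_segments(
                    report.distress[scene][device], events, config.window_s
                )
                report.event_reports[device] = dst.event_coincidence(triplets)

    for scene, by_device in hr_by_scene.items():
        report.agreement[scene] = agr.agreement_report(
            by_device["faros"].bpm, by_device["e4"].bpm
        )
    return report


def run_subject(manifest_path, config: RunConfig | None = None
                ) -> SubjectReport:
    """Load a subject's manifest from disk and run the full analysis."""
    manifest = read_manifest(manifest_path)
    scenes = {
        scene: load_scene(record)
        for scene, record in manifest.scenes.items()
    }
    return analyze_sessions(manifest.subject_id, scenes, config)


def analyze_recordings(subject_id: str, sessions: dict,
                       config: RunConfig | None = None) -> SubjectReport:
    """Analyze in-memory :class:`SessionRecording` objects directly."""
    scenes = {}
    for scene, rec in sessions.items():
        events = (
            list(map(float, rec.ground_truth.event_times_s))
            if isinstance(rec, SessionRecording) and rec.ground_truth is not None
            else []
        )
        scenes[scene] = (rec.ecg, rec.bvp, events)
    return analyze_sessions(subject_id, scenes, config)


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

LEVEL_NAMES = {0: "low", 1: "medium", 2: "high"}


@dataclass
class CohortReport:
    """Cohort-level tables and statistics."""

    agreement: pd.DataFrame       # per subject x scene quality metrics
    level_counts: pd.DataFrame    # per subject x scene x device counts
    event_pcts: pd.DataFrame      # per subject x device pct_1_3 / pct_2_3
    level_tests: pd.DataFrame     # Wilcoxon + Cliff's delta per level (IS)

    def summary(self) -> dict:
        """Mean +/- sd summaries in the shape of the study's tables."""

        def agg(df, by, cols, ndigits):
            g = df.groupby(by)[cols].agg(["mean", "std"]).round(ndigits)
            g.columns = [f"{c}_{stat}" for c, stat in g.columns]
            g.index = [
                "/".join(map(str, i)) if isinstance(i, tuple) else str(i)
                for i in g.index
            ]
            return g.to_dict(orient="index")

        return {
            "snr_db": agg(self.agreement, "scene",
                          ["snr_faros", "snr_e4"], 2),
            "agreement": agg(
                self.agreement, "scene",
                ["pearson_r", "spearman_rho", "mae", "rmse"], 3,
            ),
            "level_counts": agg(
                self.level_counts, ["scene", "device"],
                ["low", "medium", "high"], 2,
            ),
            "event_pcts": agg(self.event_pcts, "device",
                              ["pct_1_3", "pct_2_3"], 2),
        }


def run_cohort(reports: list[SubjectReport]) -> CohortReport:
    """Aggregate per-subject reports into cohort tables and tests."""
    if len(reports) < 2:
        raise ValueError("cohort statistics need at least 2 subjects")

    agree_rows = []
    count_rows = []
    pct_rows = []
    for rep in reports:
        for scene, ag in rep.agreement.items():
            agree_rows.append({
                "subject": rep.subject_id,
                "scene": scene,
                "snr_faros": ag.snr_ref_db,
                "snr_e4": ag.snr_test_db,
                "pearson_r": ag.pearson_r,
                "spearman_rho": ag.spearman_rho,
                "mae": ag.mae_bpm,
                "rmse": ag.rmse_bpm,
                "ba_bias": ag.ba_bias_bpm,
                "ba_loa_low": ag.ba_loa_low_bpm,
                "ba_loa_high": ag.ba_loa_high_bpm,
            })
        for scene, by_device in rep.level_counts.items():
            for device, counts in by_device.items():
                count_rows.append({
                    "subject": rep.subject_id,
                    "scene": scene,
                    "device": device,
                    "low": counts[0],
                    "medium": counts[1],
                    "high": counts[2],
                })
        for device, er in rep.event_reports.items():
            pct_rows.append({
                "subject": rep.subject_id,
                "device": device,
                "pct_1_3": er.pct_1_3,
                "pct_2_3": er.pct_2_3,
            })

    counts_df = pd.DataFrame(count_rows)
    test_rows = []
    is_counts = (
        counts_df[counts_df.scene == "IS"]
        if len(counts_df)
        else pd.DataFrame()
    )
    if len(is_counts):
        wide = is_counts.pivot(
            index="subject", columns="device",
            values=["low", "medium", "high"],
        )
        for level in ("low", "medium", "high"):
            e4 = wide[(level, "e4")].to_numpy(float)
            faros = wide[(level, "faros")].to_numpy(float)
            delta, mag = agr.cliffs_delta(e4, faros)
            row = {
                "level": level,
                "cliffs_delta": delta,
                "magnitude": mag,
            }
            try:
                w, p = agr.wilcoxon_signed_rank(e4, faros)
                row |= {"wilcoxon_stat": w, "p_value": p, "degenerate": False}
            except ValueError:
                row |= {
                    "wilcoxon_stat": np.nan, "p_value": np.nan,
                    "degenerate": True,
                }
            test_rows.append(row)

    return CohortReport(
        agreement=pd.DataFrame(agree_rows),
        level_counts=counts_df,
        event_pcts=pd.DataFrame(pct_rows),
        level_tests=pd.DataFrame(test_rows),
    )


def report_to_dict(rep: SubjectReport) -> dict:
    """JSON-serializable view of a subject report."""
    out = {
        "subject_id": rep.subject_id,
        "thresholds": {d: asdict(t) for d, t in rep.thresholds.items()},
        "level_counts": rep.level_counts,
        "skipped": rep.skipped,
        "agreement": {s: asdict(a) for s, a in rep.agreement.items()},
        "event_reports": {
            d: {
                "pct_1_3": er.pct_1_3,
                "pct_2_3": er.pct_2_3,
                "events": [
                    {
                        "time_s": t,
                        "levels": list(levels),
                        "criterion_1_3": bool(c13),
                        "criterion_2_3": bool(c23),
                    }
                    for t, levels, c13, c23 in er.events
                ],
            }
            for d, er in rep.event_reports.items()
        },
        "distress": {
            scene: {
                d: dv.levels.tolist() for d, dv in by_device.items()
            }
            for scene, by_device in rep.distress.items()
        },
    }
    return out
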