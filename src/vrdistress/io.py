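"""Read/write device exports and session manifests; align paired streams.

Formats:

* Wrist-device BVP export: CSV with a two-line header — line 1 a UNIX
  start timestamp, line 2 the sampling rate — then one sample per line
  (the Empatica E4 export dialect).
* Chest-device ECG: the same two-line-header CSV at 500 Hz, or EDF with a
  single ECG channel.
* Session manifest: JSON mapping scene labels to file paths, scene start
  times and (for the interactive scene) event times.

On loading a session, recordings are shifted to scene-relative time
(t = 0 at the scene start).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from . import edf as _edf
from .signals import BVP_FS, ECG_FS, SessionManifest, UniformSignal
from .synthetic import SessionRecording


class FormatError(ValueError):
    """A device export did not match its expected dialect."""


class AlignmentError(ValueError):
    """Two streams share no common time span."""


# ---------------------------------------------------------------------------
# two-line-header CSV dialect
# ---------------------------------------------------------------------------

def _read_header_csv(path, expected_fs: float, channel: str) -> UniformSignal:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: expected a 2-line header")
    try:
        start = float(lines[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a UNIX timestamp") from exc
    try:
        fs = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2 is not a sampling rate") from exc
    if fs <= 0:
        raise FormatError(f"{path}: line 2: non-positive sampling rate")
    if fs != expected_fs:
        warnings.warn(
            f"{path}: sampling rate {fs} Hz differs from the usual "
            f"{expected_fs} Hz"
        )
    try:
        samples = np.array([float(v) for v in lines[2:] if v.strip()])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed sample value") from exc
    return UniformSignal(samples, fs=fs, start_time_s=start, channel=channel)


def _write_header_csv(sig: UniformSignal, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{sig.start_time_s:.6f}\n{sig.fs:.6f}\n")
        fh.writelines(f"{v:.6f}\n" for v in sig.samples)


def read_e4_bvp(path) -> UniformSignal:
    """Read a wrist BVP export (E4 CSV dialect, nominally 64 Hz)."""
    return _read_header_csv(path, BVP_FS, channel="bvp")


def write_e4_bvp(sig: UniformSignal, path) -> None:
    _write_header_csv(sig, path)


def read_ecg(path, edf_channel: str | None = None) -> UniformSignal:
    """Read a chest ECG export: header CSV (500 Hz) or EDF.

    A multi-channel EDF requires ``edf_channel`` to name the channel,
    otherwise the choice is ambiguous.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        channels, start = _edf.read_edf(path)
        if len(channels) > 1:
            if edf_channel is None:
                raise FormatError(
                    f"{path}: {len(channels)} channels; pass edf_channel "
                    f"to select one of {[c.label for c in channels]}"
                )
            matches = [c for c in channels if c.label == edf_channel]
            if not matches:
                raise FormatError(f"{path}: no channel {edf_channel!r}")
            ch = matches[0]
        else:
            ch = channels[0]
        return UniformSignal(ch.samples, fs=ch.fs, start_time_s=start,
                             channel="ecg")
    return _read_header_csv(path, ECG_FS, channel="ecg")


def write_ecg_csv(sig: UniformSignal, path) -> None:
    _write_header_csv(sig, path)


def write_ecg_edf(sig: UniformSignal, path) -> None:
    _edf.write_edf(
        path,
        [_edf.EdfChannel(label="ECG", samples=sig.samples, fs=sig.fs)],
        start_time_s=sig.start_time_s,
    )


# ---------------------------------------------------------------------------
# stream alignment
# ---------------------------------------------------------------------------

def align_streams(ecg: UniformSignal, bvp: UniformSignal):
    """Crop both signals to the intersection of their wall-clock spans.

    Returns ``(ecg, bvp, (start, end))``.  Sampling rates and the kept
    sample values are unchanged.
    """
    start = max(ecg.start_time_s, bvp.start_time_s)
    end = min(ecg.end_time_s, bvp.end_time_s)
    if end <= start:
        raise AlignmentError(
            f"no overlap: ECG spans [{ecg.start_time_s}, {ecg.end_time_s}), "
            f"BVP spans [{bvp.start_time_s}, {bvp.end_time_s})"
        )
    return ecg.crop(start, end), bvp.crop(start, end), (start, end)


# ---------------------------------------------------------------------------
# manifests and session round-trips
# ---------------------------------------------------------------------------

def write_manifest(manifest: SessionManifest, path) -> None:
    payload = {"subject_id": manifest.subject_id, "scenes": manifest.scenes}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_manifest(path) -> SessionManifest:
    with open(path) as fh:
        payload = json.load(fh)
    return SessionManifest(
        subject_id=payload["subject_id"], scenes=payload["scenes"]
    )


def write_session(session: SessionRecording, out_dir,
                  scene_start_time_s: float = 0.0,
                  ecg_format: str = "csv") -> dict:
    """Write one scene's paired recording; returns its manifest record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{session.subject_id}_{session.scene}"
    ecg = session.ecg.shifted(
        scene_start_time_s - session.ecg.start_time_s
    )
    bvp = session.bvp.shifted(
        scene_start_time_s - session.bvp.start_time_s
    )
    if ecg_format == "edf":
        ecg_path = out_dir / f"{stem}_ecg.edf"
        write_ecg_edf(ecg, ecg_path)
    else:
        ecg_path = out_dir / f"{stem}_ecg.csv"
        write_ecg_csv(ecg, ecg_path)
    bvp_path = out_dir / f"{stem}_bvp.csv"
    write_e4_bvp(bvp, bvp_path)
    events = (
        list(map(float, session.ground_truth.event_times_s))
        if session.ground_truth is not None
        else []
    )
    return {
        "ecg_path": str(ecg_path),
        "bvp_path": str(bvp_path),
        "start_time_s": float(scene_start_time_s),
        "event_times_s": events,
    }


def write_subject(sessions: dict, out_dir, subject_id: str,
                  ecg_format: str = "csv") -> Path:
    """Write all of a subject's scenes plus the manifest; returns its path."""
    out_dir = Path(out_dir)
    records = {
        scene: write_session(sess, out_dir, ecg_format=ecg_format)
        for scene, sess in sessions.items()
    }
    manifest = SessionManifest(subject_id=subject_id, scenes=records)
    path = out_dir / f"{subject_id}_manifest.json"
    write_manifest(manifest, path)
    return path


def load_scene(record: dict):
    """Load one manifest scene record as scene-relative aligned signals."""
    ecg = read_ecg(record["ecg_path"])
    bvp = read_e4_bvp(record["bvp_path"])
    ecg, bvp, _ = align_streams(ecg, bvp)
    t0 = record.get("start_time_s", ecg.start_time_s)
    return (
        ecg.shifted(-t0),
        bvp.shifted(-t0),
        [float(e) for e in record.get("event_times_s", [])],
    )
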