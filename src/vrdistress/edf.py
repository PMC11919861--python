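"""Minimal EDF (European Data Format) reader/writer.

Supports plain EDF with a fixed per-record layout: ASCII headers, 16-bit
little-endian samples, 1 s data records.  Amplitude resolution is bounded
by the 16-bit digital range mapped over each channel's physical range;
recordings are padded to whole records by repeating the final sample, and
start times are stored at whole-second resolution (both documented
quantizations of the format).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np


@dataclass
class EdfChannel:
    label: str
    samples: np.ndarray
    fs: float
    physical_dim: str = "mV"


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, channels: list[EdfChannel], start_time_s: float = 0.0,
              record_duration_s: float = 1.0) -> None:
    """Write channels to an EDF file; all channels must share a duration."""
    if not channels:
        raise ValueError("no channels to write")
    durations = {
        round(len(c.samples) / c.fs, 6) for c in channels if len(c.samples)
    }
    if len(durations) > 1:
        raise ValueError("channels must cover the same duration")
    duration = durations.pop() if durations else 0.0
    n_records = max(int(math.ceil(duration / record_duration_s)), 1)

    start = _dt.datetime.fromtimestamp(int(start_time_s), tz=_dt.timezone.utc)
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii(start.strftime("%d.%m.%y"), 8),
        _ascii(start.strftime("%H.%M.%S"), 8),
        _ascii(256 * (1 + len(channels)), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(record_duration_s, 8),
        _ascii(len(channels), 4),
    ])

    spr = []  # samples per record per channel
    scaled = []
    phys_ranges = []
    for ch in channels:
        n_per = int(round(ch.fs * record_duration_s))
        spr.append(n_per)
        x = np.asarray(ch.samples, dtype=float)
        pmin = float(x.min()) if len(x) else -1.0
        pmax = float(x.max()) if len(x) else 1.0
        if pmax <= pmin:
            pmax = pmin + 1.0
        phys_ranges.append((pmin, pmax))
        total = n_per * n_records
        if len(x) < total:
            pad_val = x[-1] if len(x) else 0.0
            x = np.concatenate([x, np.full(total - len(x), pad_val)])
        gain = (pmax - pmin) / 65535.0
        dig = np.round((x - pmin) / gain - 32768.0).astype("<i2")
        scaled.append(dig)

    for field, width in [
        ([c.label for c in channels], 16),
        (["" for _ in channels], 80),
        ([c.physical_dim for c in channels], 8),
        ([f"{p[0]:.6g}" for p in phys_ranges], 8),
        ([f"{p[1]:.6g}" for p in phys_ranges], 8),
        (["-32768" for _ in channels], 8),
        (["32767" for _ in channels], 8),
        (["" for _ in channels], 80),
        (spr, 8),
        (["" for _ in channels], 32),
    ]:
        header += b"".join(_ascii(v, width) for v in field)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch_i, n_per in enumerate(spr):
                chunk = scaled[ch_i][rec * n_per : (rec + 1) * n_per]
                fh.write(chunk.tobytes())


def read_edf(path):
    """Read an EDF file; returns ``(channels, start_time_s)``."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        date_s = head[168:176].decode("ascii").strip()
        time_s = head[176:184].decode("ascii").strip()
        n_records = int(head[236:244])
        record_duration = float(head[244:252])
        ns = int(head[252:256])

        def fields(width):
            raw = fh.read(width * ns)
            return [
                raw[i * width : (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(16)
        fields(80)  # transducer
        dims = fields(8)
        pmins = [float(v) for v in fields(8)]
        pmaxs = [float(v) for v in fields(8)]
        dmins = [float(v) for v in fields(8)]
        dmaxs = [float(v) for v in fields(8)]
        fields(80)  # prefiltering
        sprs = [int(v) for v in fields(8)]
        fields(32)  # reserved

        raw = fh.read()

    try:
        day, month, year = (int(v) for v in date_s.split("."))
        hh, mm, ss = (int(v) for v in time_s.split("."))
        year += 2000 if year < 85 else 1900
        start_time_s = _dt.datetime(
            year, month, day, hh, mm, ss, tzinfo=_dt.timezone.utc
        ).timestamp()
    except ValueError:
        start_time_s = 0.0

    rec_len = sum(sprs)
    data = np.frombuffer(raw, dtype="<i2", count=rec_len * n_records)
    data = data.reshape(n_records, rec_len)
    channels = []
    offset = 0
    for i in range(ns):
        dig = data[:, offset : offset + sprs[i]].reshape(-1).astype(float)
        offset += sprs[i]
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (dig - dmins[i]) * gain + pmins[i]
        channels.append(
            EdfChannel(
                label=labels[i],
                samples=phys,
                fs=sprs[i] / record_duration,
                physical_dim=dims[i],
            )
        )
    return channels, start_time_s
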