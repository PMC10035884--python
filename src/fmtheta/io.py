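"""File interchange: EDF export/import of records, TSV event tables,
CSV frame streams and long tables, JSON subject parameters.

The EDF writer emits a minimal single-channel EDF (16-bit, physical
units uV, 1-s data records); files round-trip through any standard EDF
reader. Event tables travel separately as TSV (onset_s, duration_s,
code).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EEGRecord, Epoch, FeedbackFrame, SignalSegment, SubjectParams

__all__ = [
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
    "frames_to_csv",
    "frames_from_csv",
    "subject_params_to_json",
    "subject_params_from_json",
    "write_epochs",
    "read_epochs",
]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long for EDF header: {text!r}")
    return b.ljust(width)


def write_edf(record: EEGRecord, path: str | Path) -> Path:
    """Write a single-channel record as 16-bit EDF (1-s data records;
    the signal is zero-padded to a whole number of records)."""
    path = Path(path)
    fs = record.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    x = record.segment.samples
    n_rec = int(np.ceil(x.size / spr))
    padded = np.zeros(n_rec * spr)
    padded[: x.size] = x

    limit = max(float(np.abs(padded).max()), 1.0) * 1.001
    phys_max_str = f"{limit:.6g}"
    if len(phys_max_str) > 7:  # keep room for the minus sign in phys_min
        phys_max_str = f"{limit:.3g}"
    phys_max = float(phys_max_str)  # digitize with the printed value
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * gain + dig_min).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 + 256), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad("1", 4),
            # signal header
            _pad(f"EEG {record.channel_label}", 16),
            _pad("", 80),
            _pad("uV", 8),
            _pad(f"-{phys_max_str}"[:8], 8),
            _pad(phys_max_str, 8),
            _pad(str(dig_min), 8),
            _pad(str(dig_max), 8),
            _pad("", 80),
            _pad(str(spr), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecord:
    """Read a single-channel 16-bit EDF written by :func:`write_edf`."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        if ns != 1:
            raise ValueError("reader supports single-channel EDF only")
        sig = fh.read(256)
        label = sig[0:16].decode().strip()
        phys_min = float(sig[104:112].decode().strip())
        phys_max = float(sig[112:120].decode().strip())
        dig_min = float(sig[120:128].decode().strip())
        dig_max = float(sig[128:136].decode().strip())
        spr = int(sig[216:224].decode().strip())
        data = np.frombuffer(fh.read(n_rec * spr * 2), dtype="<i2").astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    x = (data - dig_min) * gain + phys_min
    fs = spr / rec_dur
    channel = label.removeprefix("EEG ").strip() or label
    return EEGRecord(segment=SignalSegment(x, fs), events=[], channel_label=channel)


def write_events_tsv(record: EEGRecord, path: str | Path) -> Path:
    path = Path(path)
    fs = record.fs
    df = pd.DataFrame(
        [
            {"onset_s": onset / fs, "duration_s": dur / fs, "code": code}
            for onset, dur, code in record.events
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path, fs: float) -> list[tuple[int, int, str]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (int(round(r.onset_s * fs)), int(round(r.duration_s * fs)), str(r.code))
        for r in df.itertuples()
    ]


def frames_to_csv(frames: list[FeedbackFrame], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"t_s": f.t_s, "theta_power": f.theta_power, "db": f.db,
             "gated": f.gated, "achieved": f.achieved}
            for f in frames
        ]
    ).to_csv(path, index=False)
    return path


def frames_from_csv(path: str | Path) -> list[FeedbackFrame]:
    df = pd.read_csv(path)
    return [
        FeedbackFrame(t_s=r.t_s, theta_power=r.theta_power, db=r.db,
                      gated=bool(r.gated), achieved=bool(r.achieved))
        for r in df.itertuples()
    ]


def write_epochs(epochs: list[Epoch], path: str | Path) -> Path:
    """Epoch batch as an .npy matrix (epochs x samples) with a JSON
    sidecar carrying fs, t0 offsets and labels."""
    path = Path(path)
    data = np.stack([ep.samples for ep in epochs])
    np.save(path, data)
    sidecar = {
        "fs": epochs[0].fs,
        "t0_s": [ep.t0_s for ep in epochs],
        "labels": [ep.label for ep in epochs],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path.with_suffix(".npy")


def read_epochs(path: str | Path) -> list[Epoch]:
    path = Path(path).with_suffix(".npy")
    data = np.load(path)
    side = json.loads(path.with_suffix(".json").read_text())
    return [
        Epoch(samples=row, fs=side["fs"], t0_s=t0, label=lab)
        for row, t0, lab in zip(data, side["t0_s"], side["labels"])
    ]


def subject_params_to_json(params: SubjectParams, path: str | Path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(params)
    d["group"] = params.group.value
    path.write_text(json.dumps(d, indent=2))
    return path


def subject_params_from_json(path: str | Path) -> SubjectParams:
    d = json.loads(Path(path).read_text())
    return SubjectParams(**d)
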