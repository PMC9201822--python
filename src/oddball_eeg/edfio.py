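"""Minimal European Data Format (EDF) I/O plus a tab-delimited event table.

Implements just enough of the EDF specification (Kemp et al. 1992) for
lossless-within-quantization round trips of continuous multichannel
recordings: 16-bit samples, one-second data records, per-channel physical
scaling chosen symmetrically around zero.  Event markers travel in a
sidecar TSV with columns ``onset_sample``, ``onset_s``, ``condition``
(EDF+ annotation channels are out of scope).

The true sample count is stamped into the 44-byte reserved header field
(``NSAMP=<n>``) because EDF pads the last record; this reader trims the
padding, foreign readers simply see trailing zeros.
"""

from __future__ import annotations

import datetime as _dt
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CONDITIONS, ContinuousRecording

__all__ = ["write_edf", "read_edf", "write_events", "read_events",
           "write_session", "read_session"]

_DIG_MAX = 32767


def _phys_str(value: float) -> str:
    """Shortest decimal for ``value`` that fits 7 chars (8 with a minus)."""
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 7:
            return s
    raise ValueError(f"cannot encode physical bound {value}")


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: ContinuousRecording, path: str | Path) -> None:
    """Write a recording as plain EDF (data only; events go in the TSV)."""
    rec.validate()
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(rec.channel_names)
    n_samples = rec.n_samples
    n_records = max(1, math.ceil(n_samples / fs))

    # 0.1% headroom so decimal rounding of the bound can never clip data
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6) * 1.001
    phys_strs = [_phys_str(pm) for pm in phys_max]
    stored_max = np.array([float(s) for s in phys_strs])
    # symmetric bounds written with identical digits => exact reader scale
    scale = stored_max / _DIG_MAX

    header = bytearray()
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field("Startdate X synthetic oddball session", 80)
    now = _dt.datetime(2000, 1, 1)
    header += _field(now.strftime("%d.%m.%y"), 8)
    header += _field(now.strftime("%H.%M.%S"), 8)
    header += _field(256 * (1 + n_ch), 8)
    header += _field(f"NSAMP={n_samples}", 44)
    header += _field(n_records, 8)
    header += _field(1, 8)  # record duration, seconds
    header += _field(n_ch, 4)
    for name in rec.channel_names:
        header += _field(f"EEG {name}", 16)
    for _ in range(n_ch):
        header += _field("AgAgCl electrode", 80)
    for _ in range(n_ch):
        header += _field("au", 8)
    for s in phys_strs:
        header += _field("-" + s, 8)
    for s in phys_strs:
        header += _field(s, 8)
    for _ in range(n_ch):
        header += _field(-_DIG_MAX, 8)
    for _ in range(n_ch):
        header += _field(_DIG_MAX, 8)
    for _ in range(n_ch):
        header += _field("", 80)
    for _ in range(n_ch):
        header += _field(fs, 8)
    for _ in range(n_ch):
        header += _field("", 32)

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samples] = rec.data
    digital = np.clip(np.round(padded / scale[:, None]), -_DIG_MAX, _DIG_MAX
                      ).astype("<i2")

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())  # C order: channel-by-channel


def read_edf(path: str | Path) -> ContinuousRecording:
    """Read an EDF file written by :func:`write_edf` (no events)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (truncated header)")
    n_records = int(raw[236:244].decode("ascii"))
    n_ch = int(raw[252:256].decode("ascii"))
    reserved = raw[192:236].decode("ascii").strip()
    n_samples_true = int(reserved.split("=", 1)[1]) if reserved.startswith("NSAMP=") else None

    off = 256
    def block(width):
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)]
        off += n_ch * width
        return vals

    labels = block(16)
    block(80)  # transducer
    block(8)   # physical dimension
    phys_min = [float(v) for v in block(8)]
    phys_max = [float(v) for v in block(8)]
    dig_min = [int(v) for v in block(8)]
    dig_max = [int(v) for v in block(8)]
    block(80)  # prefiltering
    spr = [int(v) for v in block(8)]  # samples per record
    block(32)

    fs = float(spr[0])
    data_bytes = raw[256 * (1 + n_ch):]
    per_record = sum(spr)
    digital = np.frombuffer(data_bytes, dtype="<i2", count=n_records * per_record)
    digital = digital.reshape(n_records, n_ch, spr[0]).astype(np.int64)
    chans_data = np.concatenate([digital[:, i, :].ravel()[None, :] for i in range(n_ch)])
    out = np.empty_like(chans_data, dtype=float)
    for i in range(n_ch):
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        out[i] = (chans_data[i] - dig_min[i]) * scale + phys_min[i]
    if n_samples_true is not None:
        out = out[:, :n_samples_true]
    names = [lb[4:] if lb.startswith("EEG ") else lb for lb in labels]
    return ContinuousRecording(channel_names=names, sampling_rate=fs,
                               data=out, events=[])


_EVENT_COLUMNS = ["onset_sample", "onset_s", "condition"]


def write_events(rec: ContinuousRecording, path: str | Path) -> None:
    rows = [{"onset_sample": s, "onset_s": s / rec.sampling_rate, "condition": c}
            for s, c in rec.events]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[tuple[int, str]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event table missing column(s) {missing}")
    events = []
    for i, row in df.iterrows():
        cond = str(row["condition"])
        if cond not in CONDITIONS:
            raise ValueError(
                f"{path}: row {i}: unknown condition label {cond!r} "
                f"(expected one of {CONDITIONS})")
        events.append((int(row["onset_sample"]), cond))
    return events


def write_session(rec: ContinuousRecording, edf_path: str | Path,
                  events_path: str | Path | None = None) -> None:
    """Persist a recording as EDF + events TSV (``<stem>_events.tsv``)."""
    edf_path = Path(edf_path)
    if events_path is None:
        events_path = edf_path.with_name(edf_path.stem + "_events.tsv")
    write_edf(rec, edf_path)
    write_events(rec, events_path)


def read_session(edf_path: str | Path,
                 events_path: str | Path | None = None) -> ContinuousRecording:
    edf_path = Path(edf_path)
    if events_path is None:
        events_path = edf_path.with_name(edf_path.stem + "_events.tsv")
    rec = read_edf(edf_path)
    rec.events = read_events(events_path)
    rec.validate()
    return rec
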