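"""Reading and writing EEG recordings (EDF and long-format CSV).

EDF files are read through MNE.  Writing uses a minimal European Data
Format encoder (16-bit samples, physical units µV, one-second data
records) implemented here; files it produces round-trip through both
this module's reader and MNE within one quantization step.

The CSV layout is long format with columns ``time_s, channel,
value_uV``; channels must have identical, complete time grids.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from vims_eeg.recording import EEGRecording

__all__ = ["read_recording", "write_recording", "read_edf", "write_edf",
           "read_csv", "write_csv"]

_EDF_DIGITAL_MAX = 32767


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF with µV physical units.

    The sampling rate must be a positive integer (EDF stores an integer
    number of samples per one-second record).  A trailing partial second
    is zero-padded.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs < 1:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, :rec.n_samples] = rec.data

    phys_min = np.minimum(data.min(axis=1), -1e-6)
    phys_max = np.maximum(data.max(axis=1), 1e-6)
    # symmetric range keeps 0 µV at digital 0
    bound = np.maximum(np.abs(phys_min), np.abs(phys_max))
    phys_min, phys_max = -bound, bound
    scale = _EDF_DIGITAL_MAX / bound
    digital = np.round(data * scale[:, None]).astype("<i2")

    hdr = bytearray()
    hdr += _pad_field("0", 8)                        # version
    hdr += _pad_field("X X X X", 80)                 # patient id
    hdr += _pad_field("Startdate 01-JAN-2000", 80)   # recording id
    hdr += _pad_field("01.01.00", 8)
    hdr += _pad_field("00.00.00", 8)
    hdr += _pad_field(256 * (1 + n_ch), 8)           # header length
    hdr += _pad_field("", 44)
    hdr += _pad_field(n_records, 8)
    hdr += _pad_field("1", 8)                        # record duration, s
    hdr += _pad_field(n_ch, 4)

    def field_block(values, width):
        return b"".join(_pad_field(v, width) for v in values)

    hdr += field_block([f"EEG {n}" for n in rec.channel_names], 16)
    hdr += field_block(["" for _ in range(n_ch)], 80)          # transducer
    hdr += field_block(["uV" for _ in range(n_ch)], 8)
    hdr += field_block([f"{v:.6g}" for v in phys_min], 8)
    hdr += field_block([f"{v:.6g}" for v in phys_max], 8)
    hdr += field_block([-_EDF_DIGITAL_MAX for _ in range(n_ch)], 8)
    hdr += field_block([_EDF_DIGITAL_MAX for _ in range(n_ch)], 8)
    hdr += field_block(["" for _ in range(n_ch)], 80)          # prefiltering
    hdr += field_block([fs for _ in range(n_ch)], 8)
    hdr += field_block(["" for _ in range(n_ch)], 32)

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file (via MNE) into an :class:`EEGRecording` in µV."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns Volts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return EEGRecording(data_uv, float(raw.info["sfreq"]), names)


def write_csv(rec: EEGRecording, path) -> None:
    """Write long-format CSV: ``time_s, channel, value_uV``."""
    t = rec.times()
    frames = [pd.DataFrame({"time_s": t, "channel": name, "value_uV": rec.data[i]})
              for i, name in enumerate(rec.channel_names)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_csv(path, fs: float | None = None) -> EEGRecording:
    """Read a long-format CSV recording.

    The sampling rate is inferred from the time grid unless given.
    Raises if channels disagree in length or the grid is irregular.
    """
    df = pd.read_csv(path)
    needed = {"time_s", "channel", "value_uV"}
    if not needed.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(needed)}")
    wide = df.pivot(index="time_s", columns="channel", values="value_uV")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"channels with missing samples: {bad}")
    t = wide.index.to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples to infer the time grid")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("irregular time grid in CSV recording")
    if fs is None:
        fs = 1.0 / dt[0]
    names = [str(c) for c in df["channel"].drop_duplicates()]
    data = np.stack([wide[c].to_numpy(dtype=float) for c in names])
    return EEGRecording(data, float(fs), names, start_time_s=float(t[0]))


def write_recording(rec: EEGRecording, path, fmt: str | None = None) -> None:
    fmt = fmt or _infer_format(path)
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "csv":
        write_csv(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")


def read_recording(path, fmt: str | None = None) -> EEGRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edf":
        return read_edf(path)
    if fmt == "csv":
        return read_csv(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"edf": "edf", "csv": "csv"}.get(suffix, suffix)
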