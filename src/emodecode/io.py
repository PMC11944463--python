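"""Persistence: TSV tables, HDF5 epoch containers, YAML configs, EDF/BDF.

The EDF/BDF reader is deliberately minimal — fixed-layout ASCII header,
little-endian int16 (EDF) or int24 (BDF) data records, digital-to-physical
scaling — enough to ingest BioSemi exports for the optional real-data path.
Annotation channels are returned like any other channel; event onsets come
from a TSV sidecar, not from annotations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import EpochedEEG


# ---------------------------------------------------------------- TSV tables

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ HDF5 container

def save_epochs(eeg: EpochedEEG, path: str | Path) -> None:
    """Persist an :class:`EpochedEEG` to HDF5 (arrays as datasets, metadata
    as attributes, trial metadata as JSON records)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data, compression="gzip")
        f.create_dataset("times", data=eeg.times)
        f.attrs["sampling_rate"] = eeg.sampling_rate
        f.attrs["subject_id"] = eeg.subject_id
        f.attrs["group"] = eeg.group
        f.attrs["channel_labels"] = json.dumps(list(eeg.channel_labels))
        f.attrs["trial_meta"] = eeg.trial_meta.to_json(orient="table")


def load_epochs(path: str | Path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        meta = pd.read_json(
            pd.io.common.StringIO(f.attrs["trial_meta"]), orient="table")
        return EpochedEEG(
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            times=f["times"][()],
            channel_labels=json.loads(f.attrs["channel_labels"]),
            trial_meta=meta.reset_index(drop=True),
            subject_id=str(f.attrs["subject_id"]),
            group=str(f.attrs["group"]),
        )


# ------------------------------------------------------------- YAML configs

def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_as_plain(config), f, sort_keys=True)


def load_config_dict(path: str | Path) -> dict:
    with open(path) as f:
        out = yaml.safe_load(f)
    if out is None:
        return {}
    if not isinstance(out, dict):
        raise ValueError(f"config root must be a mapping, got {type(out).__name__}")
    return out


def config_hash(config) -> str:
    """Stable short hash of a (nested dataclass) configuration."""
    blob = json.dumps(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------- EDF/BDF reader

def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start:start + length].decode("ascii", errors="replace").strip()


def read_raw_edf(path: str | Path):
    """Read an EDF or BDF file into (data, sampling_rate, channel_labels).

    ``data`` is channels x samples in physical units.  All channels must
    share one sampling rate (true for BioSemi exports).  BDF is detected
    from the version byte (0xFF) and read as little-endian int24.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: too short to be EDF/BDF")
    is_bdf = raw[0] == 0xFF
    n_records = int(_field(raw, 236, 8))
    record_dur = float(_field(raw, 244, 8))
    n_ch = int(_field(raw, 252, 4))
    header_len = int(_field(raw, 184, 8))

    off = 256
    labels = [_field(raw, off + 16 * i, 16) for i in range(n_ch)]
    off += 16 * n_ch
    off += 80 * n_ch  # transducer
    off += 8 * n_ch   # physical dimension
    phys_min = np.array(
        [float(_field(raw, off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    phys_max = np.array(
        [float(_field(raw, off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dig_min = np.array(
        [float(_field(raw, off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dig_max = np.array(
        [float(_field(raw, off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    off += 80 * n_ch  # prefiltering
    ns = np.array([int(_field(raw, off + 8 * i, 8)) for i in range(n_ch)])

    if len(set(ns.tolist())) != 1:
        raise ValueError(f"{path}: channels with mixed sampling rates")
    spr = int(ns[0])
    sampling_rate = spr / record_dur

    bps = 3 if is_bdf else 2
    body = raw[header_len:]
    expected = n_records * n_ch * spr * bps
    if len(body) < expected:
        raise ValueError(f"{path}: truncated data section")
    body = body[:expected]

    if is_bdf:
        b = np.frombuffer(body, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
        dig = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
        dig = np.where(dig >= 2**23, dig - 2**24, dig)
    else:
        dig = np.frombuffer(body, dtype="<i2").astype(np.int32)

    dig = dig.reshape(n_records, n_ch, spr)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    data = dig * gain[None, :, None] + offset[None, :, None]
    data = np.transpose(data, (1, 0, 2)).reshape(n_ch, -1)
    return data, sampling_rate, labels
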