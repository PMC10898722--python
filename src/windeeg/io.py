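"""On-disk artifact formats.

Recordings are stored as a directory: ``recording.npz`` (float32 microvolt
array), ``events.tsv`` (tab-separated marker table) and ``meta.json``
(sampling rate, channel names, seed, generator profile). Epochs use the
same pattern; feature tables are plain CSV; protocol results are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synth import Recording


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_recording(recording: Recording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "recording.npz", data=recording.data.astype(np.float32))
    recording.events.to_csv(out / "events.tsv", sep="\t", index=False)
    meta = {
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        **_jsonable(recording.meta),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_recording(in_dir: str | Path) -> Recording:
    src = Path(in_dir)
    data = np.load(src / "recording.npz")["data"]
    events = pd.read_csv(src / "events.tsv", sep="\t")
    meta = json.loads((src / "meta.json").read_text())
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=tuple(meta["channel_names"]),
        events=events,
        meta={k: v for k, v in meta.items() if k not in ("fs", "channel_names")},
    )


def write_epochs(epochs: EpochSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "epochs.npz", data=epochs.data.astype(np.float32))
    epochs.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    meta = {
        "fs": epochs.fs,
        "tmin": epochs.tmin,
        "channel_names": list(epochs.channel_names),
        "bad_channels": list(epochs.bad_channels),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if epochs.channel_positions is not None:
        np.savez(out / "positions.npz", positions=epochs.channel_positions)
    return out


def read_epochs(in_dir: str | Path) -> EpochSet:
    src = Path(in_dir)
    data = np.load(src / "epochs.npz")["data"]
    metadata = pd.read_csv(src / "metadata.tsv", sep="\t")
    meta = json.loads((src / "meta.json").read_text())
    positions = None
    if (src / "positions.npz").exists():
        positions = np.load(src / "positions.npz")["positions"]
    return EpochSet(
        data=data,
        fs=float(meta["fs"]),
        channel_names=tuple(meta["channel_names"]),
        metadata=metadata,
        tmin=float(meta["tmin"]),
        bad_channels=tuple(meta["bad_channels"]),
        channel_positions=positions,
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=1, default=str))
    return path
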