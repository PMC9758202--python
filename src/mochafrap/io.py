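"""File formats: trace CSVs with JSON sidecars, result JSON, TIFF stacks.

A half-FRAP experiment on disk is a CSV with columns
``frame,time_s,I_B,I_NB,I_BG,I_REF`` plus a sidecar ``<name>.json`` holding
``N_B, N_NB, radius_um, pre_bleach_frames, bleach_frame, experiment_id``.
Results are schema-versioned JSON documents embedding the configuration and
a hash of it, so any result can be regenerated from its own provenance
block.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .processing import RawTrace

__all__ = [
    "SCHEMA_VERSION",
    "TRACE_COLUMNS",
    "read_trace",
    "read_traces",
    "write_trace",
    "write_results",
    "read_results",
    "config_hash",
    "read_stack",
]

SCHEMA_VERSION = 1
TRACE_COLUMNS = ["frame", "time_s", "I_B", "I_NB", "I_BG", "I_REF"]
_SIDECAR_FIELDS = [
    "N_B",
    "N_NB",
    "radius_um",
    "pre_bleach_frames",
    "bleach_frame",
    "experiment_id",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def read_trace(path) -> RawTrace:
    """One trace from ``<path>.csv`` plus its ``<path>.json`` sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {', '.join(missing)}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar metadata {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_FIELDS[:-1] if k not in meta]
    if missing:
        raise ValueError(f"{sidecar.name}: missing field(s) {', '.join(missing)}")
    return RawTrace(
        frames=df["frame"].to_numpy(),
        times=df["time_s"].to_numpy(),
        I_B=df["I_B"].to_numpy(),
        I_NB=df["I_NB"].to_numpy(),
        I_BG=df["I_BG"].to_numpy(),
        I_REF=df["I_REF"].to_numpy(),
        N_B=int(meta["N_B"]),
        N_NB=int(meta["N_NB"]),
        radius_um=float(meta["radius_um"]),
        pre_bleach_frames=int(meta["pre_bleach_frames"]),
        bleach_frame=int(meta["bleach_frame"]),
        experiment_id=str(meta.get("experiment_id", path.stem)),
    )


def read_traces(path) -> list[RawTrace]:
    """All traces under a directory (``*.csv`` + sidecars) or a single file."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no trace CSVs found in {path}")
        return [read_trace(f) for f in files]
    return [read_trace(path)]


def write_trace(trace: RawTrace, path) -> Path:
    """Write one trace as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame": trace.frames.astype(int),
            "time_s": trace.times,
            "I_B": trace.I_B,
            "I_NB": trace.I_NB,
            "I_BG": trace.I_BG,
            "I_REF": trace.I_REF,
        }
    ).to_csv(path, index=False)
    meta = {
        "N_B": trace.N_B,
        "N_NB": trace.N_NB,
        "radius_um": trace.radius_um,
        "pre_bleach_frames": trace.pre_bleach_frames,
        "bleach_frame": trace.bleach_frame,
        "experiment_id": trace.experiment_id,
        "schema_version": SCHEMA_VERSION,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def config_hash(config: dict) -> str:
    """Deterministic sha256 of a JSON-serialisable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_results(results: dict, path, config: dict | None = None) -> Path:
    """Schema-versioned result JSON with an embedded provenance block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "results": results,
    }
    if config is not None:
        doc["provenance"] = {"config": config, "config_hash": config_hash(config)}
    path.write_text(json.dumps(doc, indent=1, cls=_NumpyEncoder))
    return path


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def read_stack(path) -> np.ndarray:
    """Single-channel TIFF stack as a (frames, y, x) array."""
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"expected a single-channel stack, got shape {arr.shape}"
        )
    return arr
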