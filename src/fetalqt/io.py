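"""CSV/YAML plumbing: records, annotations, beat tables, configs.

Records travel as two-column CSV (time_s, amplitude); annotation, beat and
result tables are CSVs with documented columns.  Every table written by the
package carries ``# key=value`` comment headers (tool version, config hash,
seed, column provenance) that the readers skip transparently.  Floats are
written with repr-level precision so a write/read round trip is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .signal_processing import BeatAnnotations, EcgRecord

__all__ = [
    "read_ecg_csv",
    "write_ecg_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_beats_csv",
    "read_table",
    "write_table",
    "load_config",
    "config_hash",
]

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _meta_lines(meta: dict | None) -> list[str]:
    from . import __version__

    lines = [f"# fetalqt_version={__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with ``# key=value`` provenance headers."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (frame, meta)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, float_precision="round_trip")
    return df, meta


def write_ecg_csv(record: EcgRecord, path, meta: dict | None = None) -> None:
    """Write a record as (time_s, amplitude) CSV."""
    t = (record.t0_ms / 1000.0) + np.arange(record.n_samples) / record.fs_hz
    df = pd.DataFrame({"time_s": t, "amplitude": record.samples})
    all_meta = {"fs_hz": FLOAT_FMT % record.fs_hz, "label": record.label}
    all_meta.update(meta or {})
    write_table(df, path, all_meta)


def read_ecg_csv(path) -> EcgRecord:
    """Read a (time_s, amplitude) CSV into a record.

    The sampling rate comes from the ``fs_hz`` header when present, else
    from the median time step; non-finite samples are rejected.
    """
    df, meta = read_table(path)
    required = {"time_s", "amplitude"}
    if not required <= set(df.columns):
        raise InvalidArgumentError(f"ECG CSV must have columns {sorted(required)}")
    if df.empty:
        raise InvalidArgumentError("ECG CSV is empty")
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    else:
        dt = np.median(np.diff(df["time_s"].to_numpy())) if len(df) > 1 else 1.0
        if dt <= 0:
            raise InvalidArgumentError("time_s must be increasing")
        fs = 1.0 / dt
    return EcgRecord(
        fs_hz=fs,
        samples=df["amplitude"].to_numpy(),
        label=meta.get("label", "fecg"),
        t0_ms=float(df["time_s"].iloc[0]) * 1000.0,
    )


def write_annotations_csv(ann: BeatAnnotations, path, meta: dict | None = None) -> None:
    """Write beat annotations (sample indices; -1 where absent)."""
    n = ann.n_beats
    df = pd.DataFrame(
        {
            "beat_index": np.arange(n),
            "r_sample": ann.r_idx,
            "q_sample": ann.q_idx if ann.q_idx is not None else np.full(n, -1),
            "t_end_sample": ann.t_end_idx if ann.t_end_idx is not None else np.full(n, -1),
            "source": ann.source,
        }
    )
    write_table(df, path, meta)


def read_annotations_csv(path) -> BeatAnnotations:
    df, _ = read_table(path)
    required = {"r_sample"}
    if not required <= set(df.columns):
        raise InvalidArgumentError("annotation CSV must have an r_sample column")
    source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "external"

    def optional(col):
        if col not in df.columns:
            return None
        arr = df[col].to_numpy(dtype=np.int64)
        return None if np.all(arr < 0) else arr

    return BeatAnnotations(
        r_idx=df["r_sample"].to_numpy(dtype=np.int64),
        q_idx=optional("q_sample"),
        t_end_idx=optional("t_end_sample"),
        source=source,
    )


def read_beats_csv(path) -> pd.DataFrame:
    """Read a per-beat table (beat_index, r_sample, q_sample, rr_ms) and
    derive the columns the estimator consumes (r_time_ms, q_offset_ms),
    assuming 1 kHz unless an ``fs_hz`` header says otherwise."""
    df, meta = read_table(path)
    required = {"beat_index", "r_sample", "q_sample", "rr_ms"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"beats CSV missing columns: {sorted(missing)}")
    fs = float(meta.get("fs_hz", 1000.0))
    out = pd.DataFrame(
        {
            "beat_index": df["beat_index"],
            "r_time_ms": df["r_sample"] / fs * 1000.0,
            "rr_ms": df["rr_ms"].astype(float),
            "q_offset_ms": (df["r_sample"] - df["q_sample"]) / fs * 1000.0,
        }
    )
    if (out["q_offset_ms"] < 0).any():
        raise InvalidArgumentError("q_sample must precede r_sample")
    return out


def load_config(path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InvalidArgumentError("config file must hold a key-value mapping")
    return data


def config_hash(config) -> str:
    """Short stable hash of a resolved configuration, for output headers."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
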