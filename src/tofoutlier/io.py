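"""Reading and writing recordings, feature tables and model files.

Recordings travel as JSON-lines (one measurement per line) or long-format
CSV; feature tables as CSV in the documented column order.  Floats are
serialized with shortest round-trip decimal representation, so read/write
round-trips are bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .features import TABLE_COLUMNS
from .synth import RawRecording

_JSONL_KEYS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def write_recordings(recordings: Sequence[RawRecording], path, format: str = "jsonl"):
    """Write recordings as JSON-lines or long-format CSV."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w") as fh:
            for r in recordings:
                row = {
                    "measurement_id": r.measurement_id,
                    "patient_id": r.patient_id,
                    "label": r.label,
                    "anomaly_type": r.anomaly_type,
                    "t": r.t.tolist(),
                    "ax": r.accel[:, 0].tolist(),
                    "ay": r.accel[:, 1].tolist(),
                    "az": r.accel[:, 2].tolist(),
                    "gx": r.gyro[:, 0].tolist(),
                    "gy": r.gyro[:, 1].tolist(),
                    "gz": r.gyro[:, 2].tolist(),
                }
                fh.write(json.dumps(row) + "\n")
    elif format == "csv":
        frames = []
        for r in recordings:
            frames.append(
                pd.DataFrame(
                    {
                        "measurement_id": r.measurement_id,
                        "patient_id": r.patient_id,
                        "t": r.t,
                        "ax": r.accel[:, 0],
                        "ay": r.accel[:, 1],
                        "az": r.accel[:, 2],
                        "gx": r.gyro[:, 0],
                        "gy": r.gyro[:, 1],
                        "gz": r.gyro[:, 2],
                        "label": r.label,
                        "anomaly_type": r.anomaly_type or "",
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format='%.17g')
    else:
        raise SchemaError(f"unknown recording format {format!r}")


def _recording_from_dict(d: dict, where: str) -> RawRecording:
    try:
        arrays = {k: np.asarray(d[k], dtype=float) for k in _JSONL_KEYS}
        rec = RawRecording(
            measurement_id=str(d["measurement_id"]),
            patient_id=str(d["patient_id"]),
            t=arrays["t"],
            accel=np.column_stack([arrays["ax"], arrays["ay"], arrays["az"]]),
            gyro=np.column_stack([arrays["gx"], arrays["gy"], arrays["gz"]]),
            label=str(d["label"]),
            anomaly_type=d.get("anomaly_type") or None,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"malformed record at {where}: {exc}") from exc
    return rec


def read_recordings(path, format: str = "jsonl") -> List[RawRecording]:
    """Read recordings, validating channel lengths, time order and labels."""
    path = Path(path)
    if format == "jsonl":
        out = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    d = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(
                        f"malformed record at {path}:{lineno}: {exc}"
                    ) from exc
                out.append(_recording_from_dict(d, f"{path}:{lineno}"))
        return out
    if format == "csv":
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        required = {"measurement_id", "patient_id", "t", "label"} | set(
            _JSONL_KEYS[1:]
        )
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"CSV lacks columns {sorted(missing)}")
        out = []
        for mid, grp in df.groupby("measurement_id", sort=False):
            d = {
                "measurement_id": mid,
                "patient_id": grp["patient_id"].iloc[0],
                "label": grp["label"].iloc[0],
                "anomaly_type": (
                    grp["anomaly_type"].iloc[0] if "anomaly_type" in grp else None
                )
                or None,
            }
            for k in _JSONL_KEYS:
                d[k] = grp[k].to_numpy(dtype=float)
            out.append(_recording_from_dict(d, f"{path}[{mid}]"))
        return out
    raise SchemaError(f"unknown recording format {format!r}")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV in the documented column order."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    extra = [c for c in table.columns if c not in TABLE_COLUMNS]
    table[TABLE_COLUMNS + extra].to_csv(Path(path), index=False, float_format='%.17g')


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV, checking the required columns."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    extra = [c for c in df.columns if c not in TABLE_COLUMNS]
    if extra:
        import warnings

        warnings.warn(f"feature table has extra columns {extra}; preserved")
    return df
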