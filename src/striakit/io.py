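"""Delimited-table readers and writers shared by the pipelines and the CLI.

All formats are plain text: comma-separated tables with "." decimals, TSV
spot tables, and JSON sidecars/summaries. Readers validate the declared
schema and report missing columns and non-numeric cells with row numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from striakit.colocalization import SpotField
from striakit.exceptions import DataError
from striakit.photometry import PhotometryRecording

__all__ = [
    "read_table",
    "write_table",
    "read_trace",
    "write_trace",
    "read_spots",
    "write_spots",
    "write_json",
]


def read_table(
    path, required: tuple[str, ...], numeric: tuple[str, ...] = (),
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited table, enforcing required columns and numeric cells."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty (expected a header)") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # 1-based + header
            raise DataError(f"{path}: non-numeric values in column {col!r} "
                            f"at file line(s) {rows}")
        df[col] = converted
    return df


def write_table(path, df: pd.DataFrame, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# photometry traces


def write_trace(path, rec: PhotometryRecording, meta: dict | None = None) -> None:
    """Write a trace as CSV (time_s, f465, f405) plus a JSON metadata sidecar
    at ``<path>.meta.json`` (sampling rate, autofluorescence, extras)."""
    df = pd.DataFrame({"time_s": rec.time_s, "f465": rec.f_signal,
                       "f405": rec.f_control})
    write_table(path, df)
    payload = {
        "rate_hz": rec.rate_hz,
        "autofluorescence_signal": rec.autofluorescence_signal,
        "autofluorescence_control": rec.autofluorescence_control,
    }
    payload.update(meta or {})
    write_json(str(path) + ".meta.json", payload)


def read_trace(
    path,
    time_col: str = "time_s",
    signal_col: str = "f465",
    control_col: str = "f405",
) -> PhotometryRecording:
    """Read a trace CSV and its ``<path>.meta.json`` sidecar."""
    df = read_table(path, required=(time_col, signal_col, control_col),
                    numeric=(time_col, signal_col, control_col))
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise DataError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    return PhotometryRecording(
        time_s=df[time_col].to_numpy(),
        f_signal=df[signal_col].to_numpy(),
        f_control=df[control_col].to_numpy(),
        rate_hz=float(meta["rate_hz"]),
        autofluorescence_signal=float(meta.get("autofluorescence_signal", 0.0)),
        autofluorescence_control=float(meta.get("autofluorescence_control", 0.0)),
    )


# ---------------------------------------------------------------------------
# spot fields


def write_spots(path, field: SpotField) -> None:
    """Write a spot field as TSV (channel, x_nm, y_nm, truth_pair_id)."""
    frames = []
    for channel, df in (("A", field.spots_a), ("B", field.spots_b)):
        sub = df.copy()
        sub.insert(0, "channel", channel)
        if "truth_pair_id" not in sub.columns:
            sub["truth_pair_id"] = -1
        frames.append(sub[["channel", "x_nm", "y_nm", "truth_pair_id"]])
    write_table(path, pd.concat(frames, ignore_index=True), sep="\t")


def read_spots(path) -> SpotField:
    """Read a TSV spot table into a two-channel :class:`SpotField`."""
    df = read_table(path, required=("channel", "x_nm", "y_nm"),
                    numeric=("x_nm", "y_nm"), sep="\t")
    channels = set(df["channel"].unique())
    unknown = channels - {"A", "B"}
    if unknown:
        raise DataError(f"{path}: unknown channel labels {sorted(unknown)}")
    return SpotField(
        spots_a=df[df["channel"] == "A"].reset_index(drop=True),
        spots_b=df[df["channel"] == "B"].reset_index(drop=True),
    )
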