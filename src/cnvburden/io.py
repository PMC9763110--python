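"""Readers and writers for the pipeline's plain-text interchange formats.

CNV call tables use the PennCNV-style dialect on disk (tab-separated, 1-based
inclusive coordinates); everything in memory is 0-based half-open. The
conversion happens exactly once, at the read/write boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical in-memory call-table columns
CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "cnv_type",
    "n_probes",
    "caller",
    "confidence",
]

CNV_TYPES = ("DEL", "DUP")


def empty_calls() -> pd.DataFrame:
    """An empty call table with the canonical schema."""
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "cnv_type": pd.Series(dtype=str),
            "n_probes": pd.Series(dtype=np.int64),
            "caller": pd.Series(dtype=str),
            "confidence": pd.Series(dtype=float),
        }
    )


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical call-table invariants; returns the input."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    if len(calls):
        if not (calls["start"] < calls["end"]).all():
            bad = calls.loc[calls["start"] >= calls["end"]].head()
            raise ValueError(f"call table has start >= end rows:\n{bad}")
        if not calls["cnv_type"].isin(CNV_TYPES).all():
            raise ValueError("cnv_type must be DEL or DUP")
        if (calls["n_probes"] < 0).any():
            raise ValueError("n_probes must be >= 0")
    return calls


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a PennCNV-like tab-separated call table.

    On-disk columns: chrom, start (1-based inclusive), end (inclusive),
    cnv_type/state, n_probes, confidence, sample_id, caller. Coordinates are
    converted to 0-based half-open (start-1, end unchanged).
    """
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    if "caller" not in df.columns:
        df["caller"] = "unknown"
    if "confidence" not in df.columns:
        df["confidence"] = np.nan
    return validate_calls(df[CALL_COLUMNS].copy())


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls as a PennCNV-like table (1-based inclusive coordinates)."""
    out = calls[CALL_COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64) + 1
    out = out[["chrom", "start", "end", "cnv_type", "n_probes", "confidence", "sample_id", "caller"]]
    out.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED-like file (0-based half-open; no conversion needed)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    extra = names or [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = base + list(extra[: df.shape[1] - 3])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
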