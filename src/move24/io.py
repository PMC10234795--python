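"""File formats: epoch CSV files, participant tables, run outputs.

Epoch files are UTF-8 CSV with columns ``timestamp`` (ISO 8601,
timezone-naive local clock), ``enmo_mg`` and ``z_angle_deg``; one file
per participant.  Every output table carries a comment header stamping
the configuration hash and seed of the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .epochs import EpochSeries

EPOCH_COLUMNS = ["timestamp", "enmo_mg", "z_angle_deg"]


def read_epochs(path, participant_id: str | None = None) -> EpochSeries:
    """Read and validate one epoch CSV file.

    Fails with the offending row number on duplicated / non-monotone
    timestamps or non-uniform spacing.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    if df[["enmo_mg", "z_angle_deg"]].isna().any().any():
        row = int(df[["enmo_mg", "z_angle_deg"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path.name}: malformed row {row}")
    pid = participant_id or path.stem
    try:
        return EpochSeries.from_frame(df, pid)
    except ValueError as e:
        raise ValueError(f"{path.name}: {e}") from None


def write_epochs(series: EpochSeries, path, stamp: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        series.to_frame().to_csv(fh, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    return path


def write_table(df: pd.DataFrame, path, stamp: str | None = None,
                index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=index)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        try:
            import numpy as np
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
        except ImportError:
            pass
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
    return path
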