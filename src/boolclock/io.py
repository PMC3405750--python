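"""Tabular time-series input/output.

One canonical dialect: a header row, a ``time`` column in hours, one
column per species, comma-separated (tab-separated files are detected
automatically).  The grid must be uniform; the sampling interval is
inferred from the time column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .discretize import ContinuousSeries
from .simulate import BitTrajectory

__all__ = ["read_timeseries", "write_timeseries", "write_trajectory"]


def read_timeseries(path: str | Path, regime: str = "") -> ContinuousSeries:
    """Read a CSV/TSV time-series file into a :class:`ContinuousSeries`."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0].lower() != "time":
        raise ValueError(f"{path}: first column must be 'time' (hours)")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cells: {exc}") from exc
    t = values.iloc[:, 0].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise ValueError(f"{path}: time column is not a uniform grid")
    return ContinuousSeries(
        t_s=float(dt[0]),
        data=values.iloc[:, 1:].reset_index(drop=True),
        regime=regime,
        t0=float(t[0]),
    )


def write_timeseries(series: ContinuousSeries, path: str | Path) -> None:
    df = series.data.copy()
    df.insert(0, "time", series.times)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_trajectory(trajectory: BitTrajectory, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trajectory.to_frame().to_csv(path, index=False)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
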