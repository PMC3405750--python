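"""Discretization of continuous expression time courses.

Continuous series are min–max normalized to [0, 1] per species (and per
light regime, mirroring the per-dataset fitting convention) and
thresholded into bitstrings: a sample is ON iff its value is strictly
above the species' threshold, so ties at the threshold discretize to
OFF.  Because thresholding a finite series can only produce finitely
many distinct bitstrings, each threshold lattice collapses to a small
set of informative representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import BitTrajectory

__all__ = [
    "ContinuousSeries",
    "ThresholdLattice",
    "normalize",
    "binarize",
    "distinct_thresholds",
]


@dataclass
class ContinuousSeries:
    """Uniformly sampled real-valued expression series for several species."""

    t_s: float
    data: pd.DataFrame  # one column per species; row k is time t0 + k*t_s
    regime: str = ""  # LD / DD / LL
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("series contains non-finite values")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_steps(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.t_s * np.arange(self.n_steps)

    def values(self, species: str) -> np.ndarray:
        return self.data[species].to_numpy(dtype=float)

    def rename(self, mapping: Mapping[str, str]) -> "ContinuousSeries":
        return replace(self, data=self.data.rename(columns=dict(mapping)))


@dataclass(frozen=True)
class ThresholdLattice:
    """Regular grid of candidate thresholds ``T_MIN, T_MIN+T_R, ..., T_MAX``."""

    t_min: float = 0.2
    t_max: float = 0.8
    t_r: float = 0.025

    def __post_init__(self) -> None:
        if not (0.0 < self.t_min <= self.t_max < 1.0):
            raise ValueError("need 0 < T_MIN <= T_MAX < 1")
        if self.t_r <= 0:
            raise ValueError("threshold resolution must be positive")

    def values(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_r))
        grid = self.t_min + self.t_r * np.arange(n + 1)
        return grid[grid <= self.t_max + 1e-9]


def normalize(series: ContinuousSeries) -> ContinuousSeries:
    """Min–max scale every species of one regime onto [0, 1].

    Constant species cannot be normalized (no dynamic range) and are
    rejected.
    """
    df = series.data.astype(float)
    lo, hi = df.min(axis=0), df.max(axis=0)
    flat = hi - lo <= 0
    if flat.any():
        bad = list(df.columns[flat])
        raise ValueError(f"constant series cannot be normalized: {bad}")
    return replace(series, data=(df - lo) / (hi - lo))


def binarize(
    series: ContinuousSeries, thresholds: Mapping[str, float] | float
) -> BitTrajectory:
    """Threshold a (normalized) series into a Boolean trajectory.

    A sample is ON iff its value is strictly greater than the species'
    threshold.
    """
    if isinstance(thresholds, Mapping):
        missing = set(series.species) - set(thresholds)
        if missing:
            raise ValueError(f"no threshold for species {sorted(missing)}")
        th = np.array([thresholds[s] for s in series.species], dtype=float)
    else:
        th = np.full(len(series.species), float(thresholds))
    bits = (series.data.to_numpy(dtype=float) > th).astype(np.int8)
    return BitTrajectory(
        t_s=series.t_s, genes=series.species, states=bits, t0=series.t0
    )


def distinct_thresholds(
    values: np.ndarray | Sequence[float] | ContinuousSeries,
    lattice: ThresholdLattice = ThresholdLattice(),
    species: str | None = None,
) -> list[float]:
    """Informative thresholds: one lattice representative per distinct bitstring.

    Two thresholds that binarize the series identically are redundant;
    for each equivalence class the smallest lattice threshold is kept,
    in ascending order.
    """
    if isinstance(values, ContinuousSeries):
        if species is None:
            raise ValueError("species required when passing a ContinuousSeries")
        values = values.values(species)
    v = np.asarray(values, dtype=float)
    reps: list[float] = []
    seen: set[bytes] = set()
    for t in lattice.values():
        bits = (v > t).astype(np.int8).tobytes()
        if bits not in seen:
            seen.add(bits)
            reps.append(float(t))
    return reps
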