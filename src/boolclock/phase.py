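"""Phase markers and phase–photoperiod analysis.

The natural phase marker of a Boolean species is the time, within the
24 h light–dark cycle, of its ON-to-OFF transition; a continuous series
is assigned the analogous marker, the time at which it falls below its
discretization threshold.  Scanning a range of photoperiods P (daylight
hours in an LD P:24−P cycle) and tracking how each species' markers
move relative to dawn and dusk classifies components as dawn-locked,
dusk-locked or mixed — the system-level signature of how a clock
integrates seasonal daylength changes.  A species may carry more than
one marker per cycle (e.g. a gene with an acute light-driven peak plus
a circadian peak); all markers are reported in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LogicConfiguration
from .discretize import ContinuousSeries
from .light import DAY_HOURS
from .models import ModelSpec
from .simulate import BitTrajectory, detect_limit_cycle, seed_bank

__all__ = [
    "PhaseTable",
    "boolean_phase",
    "continuous_phase",
    "phase_photoperiod_curve",
    "max_symmetric_interval",
    "classify_locking",
]


@dataclass
class PhaseTable:
    """Phase markers of every species at one photoperiod."""

    photoperiod: float
    dawn: float
    dusk: float
    entrained: bool
    phases: dict[str, list[float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp, marks in self.phases.items():
            if not marks:
                rows.append((self.photoperiod, sp, -1, np.nan, self.dawn, self.dusk))
            for i, ph in enumerate(marks):
                rows.append((self.photoperiod, sp, i, ph, self.dawn, self.dusk))
        return pd.DataFrame(
            rows,
            columns=["photoperiod", "species", "marker", "phase", "dawn", "dusk"],
        )


def boolean_phase(cycle: BitTrajectory, species: str) -> list[float]:
    """ON-to-OFF transition times of one species over one entrained cycle.

    ``cycle`` must cover exactly one 24 h period; the cycle is treated
    as circular, and each time t with ``X(t - t_S) = 1, X(t) = 0`` is
    reported modulo 24 h.  A species that is never ON or never OFF has
    no marker and yields an empty list.
    """
    x = cycle.series(species)
    n = x.shape[0]
    out = []
    for k in range(n):
        if x[k - 1] == 1 and x[k] == 0:
            out.append(float((cycle.t0 + k * cycle.t_s) % DAY_HOURS))
    return sorted(out)


def continuous_phase(
    series: ContinuousSeries, threshold: float, species: str
) -> list[float]:
    """Threshold down-crossing times of one species over one cycle.

    A crossing is a sample strictly above the threshold followed by one
    at or below it; the crossing time is linearly interpolated between
    the two samples (so discretizing the series and taking the Boolean
    marker recovers these times rounded up to the grid).
    """
    v = series.values(species)
    n = v.shape[0]
    out = []
    for k in range(n):
        prev, cur = v[k - 1], v[k]
        if prev > threshold >= cur:
            frac = (prev - threshold) / (prev - cur) if prev != cur else 1.0
            t_prev = series.t0 + ((k - 1) % n) * series.t_s if k > 0 else series.t0 - series.t_s
            out.append(float((t_prev + frac * series.t_s) % DAY_HOURS))
    return sorted(out)


def _entrained_cycle(
    spec: ModelSpec,
    config: LogicConfiguration,
    delays: Sequence[float],
    photoperiod: float,
    t_s: float,
) -> BitTrajectory | None:
    """One dawn-aligned 24 h cycle of the entrained solution, or None."""
    free = None
    for hist in seed_bank(spec.topology).values():
        rep = detect_limit_cycle(
            spec, config, delays, spec.free_run_program(), hist, t_s=t_s
        )
        if rep.found and rep.period > 0:
            free = rep
            break
    if free is None:
        return None
    window = max(1, int(round(max(delays, default=t_s) / t_s)))
    reps = int(np.ceil(window / free.cycle.shape[0])) + 1
    hist = np.tile(free.cycle, (reps, 1))[-window:]
    ld = detect_limit_cycle(
        spec, config, delays, spec.light_program(photoperiod), hist, t_s=t_s
    )
    if not ld.found or ld.period != DAY_HOURS:
        return None
    if (ld.cycle == ld.cycle[0]).all():
        return None
    shift = int(round((ld.t_start % DAY_HOURS) / t_s))
    states = np.roll(ld.cycle, shift, axis=0)  # index 0 at dawn (ZT0)
    return BitTrajectory(t_s=t_s, genes=ld.genes, states=states, t0=0.0)


def phase_photoperiod_curve(
    spec: ModelSpec,
    config: LogicConfiguration | None = None,
    delays: Sequence[float] | None = None,
    photoperiods: Sequence[float] | None = None,
    t_s: float = 0.5,
) -> list[PhaseTable]:
    """Phase markers across a photoperiod range (default 4–20 h in t_S steps).

    For each requested P the circuit is entrained in LD P:24−P from its
    free-running cycle; photoperiods at which no 24 h entrained cycle is
    reached are flagged rather than raised.
    """
    config = config if config is not None else spec.default_lc
    delays = delays if delays is not None else spec.default_delays
    if photoperiods is None:
        photoperiods = np.arange(4.0, 20.0 + t_s / 2, t_s)
    tables = []
    for p in photoperiods:
        cyc = _entrained_cycle(spec, config, delays, float(p), t_s)
        table = PhaseTable(
            photoperiod=float(p), dawn=0.0, dusk=float(p), entrained=cyc is not None
        )
        if cyc is not None:
            table.phases = {sp: boolean_phase(cyc, sp) for sp in cyc.genes}
        tables.append(table)
    return tables


def max_symmetric_interval(
    spec: ModelSpec,
    config: LogicConfiguration | None = None,
    delays: Sequence[float] | None = None,
    t_s: float = 0.5,
) -> float:
    """Half-width P_MAX of the largest symmetric entrainment window around 12:12.

    The model is entrained at every photoperiod on the t_S grid in
    (0, 24); P_MAX is the largest value such that every scanned P in
    (12 − P_MAX, 12 + P_MAX) entrains.  Failure at 12:12 itself gives 0.
    """
    config = config if config is not None else spec.default_lc
    delays = delays if delays is not None else spec.default_delays
    scan = np.arange(t_s, DAY_HOURS, t_s)
    if _entrained_cycle(spec, config, delays, 12.0, t_s) is None:
        return 0.0
    fail_dist = [
        abs(float(p) - 12.0)
        for p in scan
        if _entrained_cycle(spec, config, delays, float(p), t_s) is None
    ]
    return min(fail_dist) if fail_dist else 12.0


def _circular_range(values: Sequence[float]) -> float:
    """Spread of phase values on the 24 h circle (24 minus the largest gap)."""
    v = np.sort(np.mod(values, DAY_HOURS))
    if v.size <= 1:
        return 0.0
    gaps = np.diff(np.concatenate([v, [v[0] + DAY_HOURS]]))
    return float(DAY_HOURS - gaps.max())


def classify_locking(
    tables: Sequence[PhaseTable], t_s: float = 0.5
) -> dict[str, str]:
    """Label each species dawn-locked, dusk-locked or mixed.

    A marker profile is dusk-locked if its offset from dusk varies by at
    most one sampling step across photoperiods (dawn analogously, with
    dawn at ZT0).  Species with several markers per cycle are labelled
    by consensus over marker profiles; disagreement (or a marker count
    that changes with photoperiod) is 'mixed'.
    """
    good = [t for t in tables if t.entrained]
    if len(good) < 3:
        raise ValueError("need at least three entrained photoperiods")
    species = sorted({sp for t in good for sp in t.phases})
    tol = t_s + 1e-9
    labels = {}
    for sp in species:
        lists = [t.phases.get(sp, []) for t in good]
        counts = {len(l) for l in lists}
        if 0 in counts:
            continue  # no marker at some photoperiod: excluded
        if len(counts) != 1:
            labels[sp] = "mixed"
            continue
        verdicts = []
        for j in range(counts.pop()):
            dawn_off = [t.phases[sp][j] - t.dawn for t in good]
            dusk_off = [t.phases[sp][j] - t.dusk for t in good]
            if _circular_range(dusk_off) <= tol:
                verdicts.append("dusk-locked")
            elif _circular_range(dawn_off) <= tol:
                verdicts.append("dawn-locked")
            else:
                verdicts.append("mixed")
        labels[sp] = verdicts[0] if len(set(verdicts)) == 1 else "mixed"
    return labels
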