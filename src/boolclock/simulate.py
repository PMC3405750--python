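"""Forward simulation of delayed Boolean clock circuits.

The state of gene i at time ``t = k t_S`` is computed from the states of
its regulators, each lagged by the signalling delay of the corresponding
edge, and from the (lagged) light inputs.  All delays must be multiples
of the sampling interval ``t_S``.  Edges with zero delay create
within-step dependencies; these are resolved by evaluating genes in
topological order of the zero-delay subgraph, and a cycle of all-zero
delays (instantaneous feedback) is rejected.

Because the delayed state — the window of the last ``W/t_S`` steps plus
the phase of the 24 h light cycle — lives in a finite set, every
deterministic trajectory eventually revisits a state.  Limit-cycle
detection exploits this: the first recurrence of the full delayed state
yields the transient length and the exact period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LogicConfiguration, Topology, build_vertex_rules, gate1, gate2
from .light import DAY_HOURS, LightProgram
from .models import ModelSpec

__all__ = [
    "BitTrajectory",
    "CycleReport",
    "ViabilityReport",
    "ZeroDelayLoopError",
    "simulate",
    "detect_limit_cycle",
    "check_viability",
    "seed_bank",
]


class ZeroDelayLoopError(ValueError):
    """A feedback loop whose delays are all zero has no synchronous update."""


@dataclass
class BitTrajectory:
    """Discrete-time Boolean states on a uniform grid.

    ``states[k, i]`` is the state of ``genes[i]`` at time ``t0 + k*t_s``.
    """

    t_s: float
    genes: tuple[str, ...]
    states: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.genes):
            raise ValueError("states must be (steps, n_genes)")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("trajectory states must be binary")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.t_s * np.arange(self.n_steps)

    def series(self, gene: str) -> np.ndarray:
        return self.states[:, self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.genes))
        df.insert(0, "time", self.times)
        return df


@dataclass
class CycleReport:
    """Attractor found by state-recurrence search.

    ``period`` is 0 for a fixed point; ``cycle`` then holds the single
    repeating state.  ``t_start`` is the absolute time (hours) of
    ``cycle[0]``, which fixes the attractor's phase relative to dawn
    when a light–dark program is applied.
    """

    found: bool
    transient: float = np.nan  # hours until the attractor is entered
    period: float = np.nan  # hours; 0 for a fixed point
    cycle: np.ndarray | None = None
    t_start: float = np.nan
    t_s: float = 0.5
    genes: tuple[str, ...] = ()

    @property
    def is_fixed_point(self) -> bool:
        return self.found and self.period == 0.0

    def cycle_trajectory(self) -> BitTrajectory:
        if not self.found:
            raise ValueError("no attractor found")
        return BitTrajectory(
            t_s=self.t_s, genes=self.genes, states=self.cycle, t0=self.t_start
        )


@dataclass
class ViabilityReport:
    """Free-run period test plus light–dark entrainment test."""

    free_run_period: float
    rel_deviation: float
    free_run_viable: bool
    entrained: bool | None
    viable: bool
    seed: str = ""

    def __post_init__(self) -> None:
        if self.viable:
            assert self.free_run_viable and self.entrained in (True, None)


class _Stepper:
    """Compiled update rule for one (topology, LC, delays, program) tuple."""

    def __init__(
        self,
        topology: Topology,
        config: LogicConfiguration,
        delays: Sequence[float],
        program: LightProgram,
        t_s: float,
    ) -> None:
        if len(delays) != topology.n_delay_slots:
            raise ValueError(
                f"expected {topology.n_delay_slots} delays, got {len(delays)}"
            )
        steps = []
        for tau in delays:
            d = tau / t_s
            if abs(d - round(d)) > 1e-9:
                raise ValueError(f"delay {tau} h is not a multiple of t_s={t_s} h")
            if tau < 0:
                raise ValueError("delays must be non-negative")
            steps.append(int(round(d)))
        if program.n_lights != topology.m_lights:
            raise ValueError("light program size does not match topology")
        self.topology = topology
        self.t_s = t_s
        self.program = program
        self.delay_steps = steps
        rules = build_vertex_rules(topology, config)
        gidx = {g: i for i, g in enumerate(topology.genes)}
        self.compiled = []
        for rule in rules:
            gene_in = [
                (gidx[src], steps[slot - 1], g) for src, slot, g in rule.gene_inputs
            ]
            light_in = [(k, delays[slot - 1]) for k, slot in rule.light_inputs]
            self.compiled.append((gene_in, rule.combiner, light_in, rule.h))
        self.order = self._zero_delay_order()
        gene_delay_steps = [
            steps[topology.edge_delay_slot(j) - 1]
            for j in range(len(topology.gene_edges))
        ]
        # window of past steps the update depends on (>=1 to carry state)
        self.window = max(1, max(gene_delay_steps, default=1))

    def _zero_delay_order(self) -> list[int]:
        """Gene evaluation order respecting zero-delay (within-step) edges."""
        topo = self.topology
        gidx = {g: i for i, g in enumerate(topo.genes)}
        succ: dict[int, list[int]] = {i: [] for i in range(topo.n_genes)}
        indeg = [0] * topo.n_genes
        for j, (src, dst) in enumerate(topo.gene_edges):
            if self.delay_steps[topo.edge_delay_slot(j) - 1] == 0:
                succ[gidx[src]].append(gidx[dst])
                indeg[gidx[dst]] += 1
        order, queue = [], sorted(i for i in range(topo.n_genes) if indeg[i] == 0)
        while queue:
            i = queue.pop(0)
            order.append(i)
            for j in succ[i]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    queue.append(j)
            queue.sort()
        if len(order) != topo.n_genes:
            raise ZeroDelayLoopError(
                "zero-total-delay feedback loop: a cycle of zero-delay edges "
                "has no well-defined synchronous update"
            )
        return order

    def step(self, states: np.ndarray, k: int, t0: float) -> np.ndarray:
        """Compute the state row at step ``k`` given rows ``0..k-1`` in ``states``."""
        t = t0 + k * self.t_s
        row = states[k]
        for i in self.order:
            gene_in, combiner, light_in, h = self.compiled[i]
            vals = []
            for src, d, g in gene_in:
                b = int(states[k - d, src]) if d > 0 else int(row[src])
                vals.append(b if g == 0 else 1 - b)
            out = vals[0] if len(vals) == 1 else gate2(vals[0], vals[1], combiner)
            if light_in:
                light = 0
                for lk, tau in light_in:
                    light |= self.program.signal(lk, t - tau)
                out = gate2(out, light, h)
            row[i] = out
        return row


def _coerce_history(
    topology: Topology, history: np.ndarray | BitTrajectory | Sequence, window: int
) -> np.ndarray:
    if isinstance(history, BitTrajectory):
        hist = history.states
    else:
        hist = np.asarray(history, dtype=np.int8)
    if hist.ndim == 1:
        hist = np.tile(hist, (window, 1))
    if hist.shape[1] != topology.n_genes:
        raise ValueError("history has wrong number of genes")
    if hist.shape[0] < window:
        raise ValueError(
            f"history of {hist.shape[0]} steps is shorter than the delay "
            f"window of {window} steps"
        )
    if not np.isin(hist, (0, 1)).all():
        raise ValueError("history must be binary")
    return hist.astype(np.int8)


def simulate(
    spec: ModelSpec | Topology,
    config: LogicConfiguration,
    delays: Sequence[float],
    program: LightProgram,
    history: np.ndarray | BitTrajectory | Sequence,
    horizon: float,
    t_s: float = 0.5,
    t0: float = 0.0,
) -> BitTrajectory:
    """Evolve the circuit for ``horizon`` hours beyond the supplied history.

    ``history`` supplies the initial window of states (a constant row is
    tiled to the required window length); the returned trajectory
    includes it.  ``t0`` is the absolute time of the first history row,
    which sets the phase relative to dawn.
    """
    topology = spec.topology if isinstance(spec, ModelSpec) else spec
    stepper = _Stepper(topology, config, delays, program, t_s)
    hist = _coerce_history(topology, history, stepper.window)
    extra = int(round(horizon / t_s))
    states = np.empty((hist.shape[0] + extra, topology.n_genes), dtype=np.int8)
    states[: hist.shape[0]] = hist
    for k in range(hist.shape[0], states.shape[0]):
        states[k] = 0
        stepper.step(states, k, t0)
    return BitTrajectory(t_s=t_s, genes=topology.genes, states=states, t0=t0)


def detect_limit_cycle(
    spec: ModelSpec | Topology,
    config: LogicConfiguration,
    delays: Sequence[float],
    program: LightProgram,
    history: np.ndarray | BitTrajectory | Sequence,
    t_s: float = 0.5,
    max_horizon: float = 100 * DAY_HOURS,
    t0: float = 0.0,
) -> CycleReport:
    """Run the circuit until the full delayed state recurs.

    The dynamical state at step k is the window of the last ``W/t_S``
    state rows together with, under a non-constant light program, the
    time of day; its first recurrence delimits the transient and one
    full cycle.  A cycle whose states are all identical is reported as a
    fixed point with period 0.
    """
    topology = spec.topology if isinstance(spec, ModelSpec) else spec
    stepper = _Stepper(topology, config, delays, program, t_s)
    hist = _coerce_history(topology, history, stepper.window)
    # keep only the window the dynamics depend on
    hist = hist[-stepper.window :]
    max_steps = int(round(max_horizon / t_s))
    states = np.empty((hist.shape[0] + max_steps, topology.n_genes), dtype=np.int8)
    states[: hist.shape[0]] = hist
    phase_steps = int(round(DAY_HOURS / t_s)) if not program.is_constant else 0
    seen: dict = {}
    w = stepper.window

    def key(k: int):
        window = states[k - w + 1 : k + 1].tobytes()
        if phase_steps:
            return window, (int(round(t0 / t_s)) + k) % phase_steps
        return window

    start = hist.shape[0] - 1
    seen[key(start)] = start
    for k in range(start + 1, states.shape[0]):
        states[k] = 0
        stepper.step(states, k, t0)
        ck = key(k)
        if ck in seen:
            prev = seen[ck]
            cycle = states[prev:k].copy()
            if (cycle == cycle[0]).all():
                cycle = cycle[:1]
                period = 0.0
            else:
                period = (k - prev) * t_s
            return CycleReport(
                found=True,
                transient=(prev - start) * t_s,
                period=period,
                cycle=cycle,
                t_start=t0 + prev * t_s,
                t_s=t_s,
                genes=topology.genes,
            )
        seen[ck] = k
    return CycleReport(found=False, t_s=t_s, genes=topology.genes)


def seed_bank(topology: Topology) -> dict[str, np.ndarray]:
    """Standard initial conditions: all-OFF, all-ON, each single gene ON.

    Delayed Boolean circuits are multistable, so viability screening
    tries a small bank of constant histories when no data are supplied.
    """
    n = topology.n_genes
    seeds = {"all_off": np.zeros(n, dtype=np.int8), "all_on": np.ones(n, dtype=np.int8)}
    for i, g in enumerate(topology.genes):
        row = np.zeros(n, dtype=np.int8)
        row[i] = 1
        seeds[f"on_{g}"] = row
    return seeds


def check_viability(
    spec: ModelSpec,
    config: LogicConfiguration | None = None,
    delays: Sequence[float] | None = None,
    init_data: BitTrajectory | np.ndarray | None = None,
    t_s: float = 0.5,
    photoperiod: float = 12.0,
    require_entrainment: bool = True,
    period_tolerance: float = 0.2,
    max_horizon: float = 100 * DAY_HOURS,
) -> ViabilityReport:
    """Classify a parametrized configuration as a viable clock or not.

    A viable clock must (i) reach a free-running limit cycle whose
    period deviates from the target ``tau_fr`` by at most 20% and,
    unless ``require_entrainment`` is off (the convention used when
    fitting free-run-only data), (ii) entrain 1:1 to a 24 h light–dark
    cycle, i.e. settle on a non-constant cycle of exactly 24 h.

    When ``init_data`` (e.g. discretized observations) is given, its
    last window seeds the free-run simulation; otherwise the standard
    seed bank is tried and the first qualifying seed is reported.
    """
    config = config if config is not None else spec.default_lc
    delays = delays if delays is not None else spec.default_delays
    free_program = spec.free_run_program()
    try:
        _Stepper(spec.topology, config, delays, free_program, t_s)
    except ZeroDelayLoopError:
        # an instantaneous feedback loop cannot function as a clock
        return ViabilityReport(
            free_run_period=np.nan,
            rel_deviation=np.nan,
            free_run_viable=False,
            entrained=None,
            viable=False,
            seed="",
        )

    if init_data is not None:
        seeds = {"data": init_data}
    else:
        seeds = seed_bank(spec.topology)

    best: tuple[str, CycleReport] | None = None
    qualifying: tuple[str, CycleReport] | None = None
    for name, hist in seeds.items():
        report = detect_limit_cycle(
            spec, config, delays, free_program, hist, t_s=t_s, max_horizon=max_horizon
        )
        if not report.found:
            continue
        if best is None:
            best = (name, report)
        if report.period > 0 and abs(report.period - spec.tau_fr) <= (
            period_tolerance * spec.tau_fr
        ):
            qualifying = (name, report)
            break

    if qualifying is None:
        period = best[1].period if best else np.nan
        dev = abs(period - spec.tau_fr) / spec.tau_fr if best else np.nan
        return ViabilityReport(
            free_run_period=period,
            rel_deviation=dev,
            free_run_viable=False,
            entrained=None,
            viable=False,
            seed=best[0] if best else "",
        )

    seed_name, cycle_report = qualifying
    period = cycle_report.period
    dev = abs(period - spec.tau_fr) / spec.tau_fr

    entrained: bool | None = None
    if require_entrainment:
        ld_program = spec.light_program(photoperiod)
        # feed the free-running cycle into the light-dark cycle
        cyc = cycle_report.cycle
        window = max(1, int(round(max(delays, default=t_s) / t_s)))
        reps = int(np.ceil(window / cyc.shape[0])) + 1
        hist = np.tile(cyc, (reps, 1))[-window:]
        ld_report = detect_limit_cycle(
            spec, config, delays, ld_program, hist, t_s=t_s, max_horizon=max_horizon
        )
        entrained = bool(
            ld_report.found
            and ld_report.period == DAY_HOURS
            and not (ld_report.cycle == ld_report.cycle[0]).all()
        )

    viable = bool(entrained) if require_entrainment else True
    return ViabilityReport(
        free_run_period=period,
        rel_deviation=dev,
        free_run_viable=True,
        entrained=entrained,
        viable=viable,
        seed=seed_name,
    )
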