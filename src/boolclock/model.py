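"""Model/results interface tying the pipeline together.

``BooleanClockModel`` is constructed from expression data (one series
per light regime) and a clock circuit; ``fit`` searches logic
configurations and parameters and returns ``ClockFitResults`` carrying
the ranked configurations, their fitted delays/thresholds, viability
diagnostics and a text summary.  Simulation and phase analysis of the
fitted clock hang off the results object.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LogicConfiguration, enumerate_lcs
from .discretize import ContinuousSeries
from .fitting import (
    AnnealSchedule,
    FitResult,
    SearchGrid,
    anneal_fit,
    exhaustive_fit,
    regime_program,
    total_cost,
)
from .io import read_timeseries
from .models import ModelSpec, builtin_model
from .phase import PhaseTable, classify_locking, phase_photoperiod_curve
from .simulate import BitTrajectory, detect_limit_cycle, seed_bank

__all__ = ["BooleanClockModel", "ClockFitResults"]


def _coerce_series(obj, regime: str, t_s: float | None) -> ContinuousSeries:
    if isinstance(obj, ContinuousSeries):
        return obj
    df = pd.DataFrame(obj)
    if "time" in df.columns:
        t = df["time"].to_numpy(dtype=float)
        dt = np.diff(t)
        if not np.allclose(dt, dt[0]):
            raise ValueError("non-uniform time grid")
        return ContinuousSeries(
            t_s=float(dt[0]), data=df.drop(columns="time"), regime=regime, t0=float(t[0])
        )
    if t_s is None:
        raise ValueError("t_s required for data without a time column")
    return ContinuousSeries(t_s=t_s, data=df, regime=regime)


class BooleanClockModel:
    """A clock circuit to be fitted to discretized expression time courses.

    Parameters
    ----------
    data : mapping of regime label to time series
        Keys are ``'LD'`` and/or the circuit's free-run regime
        (``'DD'``/``'LL'``); values are :class:`ContinuousSeries` or
        DataFrames (with a ``time`` column in hours, or ``t_s`` given).
    model : str or ModelSpec
        A built-in circuit name or an explicit specification.
    exclude, alias
        Genes excluded from scoring, and gene-to-proxy-species mappings
        for unobserved components.
    """

    def __init__(
        self,
        data: Mapping[str, object],
        model: str | ModelSpec,
        t_s: float | None = None,
        photoperiod: float = 12.0,
        exclude: Sequence[str] = (),
        alias: Mapping[str, str] | None = None,
    ) -> None:
        self.spec = builtin_model(model) if isinstance(model, str) else model
        self.data = {
            regime: _coerce_series(obj, regime, t_s) for regime, obj in data.items()
        }
        if not self.data:
            raise ValueError("at least one regime of data is required")
        for regime in self.data:
            regime_program(self.spec, regime, photoperiod)  # validates labels
        self.photoperiod = photoperiod
        self.exclude = tuple(exclude)
        self.alias = dict(alias or {})

    @classmethod
    def from_files(
        cls, paths: Mapping[str, str], model: str | ModelSpec, **kwargs
    ) -> "BooleanClockModel":
        data = {regime: read_timeseries(p, regime=regime) for regime, p in paths.items()}
        return cls(data, model, **kwargs)

    def fit(
        self,
        lcs: Iterable[LogicConfiguration] | None = None,
        grid: SearchGrid | None = None,
        fixed_gates: Mapping[int, int] | None = None,
        fixed_delays: Mapping[int, float] | None = None,
        check_viable: bool = True,
        require_entrainment: bool | None = None,
    ) -> "ClockFitResults":
        """Exhaustively score configurations; return the ranked results.

        By default all ``2**d`` configurations are searched (restricted
        by ``fixed_gates``).  ``require_entrainment`` defaults to True
        when LD data are present and False for free-run-only fits.
        """
        if lcs is None:
            lcs = list(enumerate_lcs(self.spec.topology, fixed_gates))
        elif fixed_gates:
            raise ValueError("pass either lcs or fixed_gates, not both")
        if require_entrainment is None:
            require_entrainment = "LD" in self.data
        results = exhaustive_fit(
            self.spec,
            self.data,
            lcs=lcs,
            grid=grid,
            photoperiod=self.photoperiod,
            fixed_delays=fixed_delays,
            exclude=self.exclude,
            alias=self.alias,
            check_viable=check_viable,
            require_entrainment=require_entrainment,
        )
        return ClockFitResults(self, results, grid or SearchGrid(), method="exhaustive")

    def fit_annealing(
        self,
        config: LogicConfiguration | None = None,
        grid: SearchGrid | None = None,
        schedule: AnnealSchedule | None = None,
        seed: int | None = None,
        start=None,
        check_viable: bool = True,
    ) -> "ClockFitResults":
        """Simulated-annealing fit of a single configuration's parameters."""
        config = config if config is not None else self.spec.default_lc
        res = anneal_fit(
            self.spec,
            config,
            self.data,
            grid=grid,
            schedule=schedule,
            seed=seed,
            start=start,
            photoperiod=self.photoperiod,
            exclude=self.exclude,
            alias=self.alias,
            check_viable=check_viable,
            require_entrainment="LD" in self.data,
        )
        return ClockFitResults(self, [res], grid or SearchGrid(), method="annealing")

    def score(self, config, delays, thresholds) -> float:
        """Cost of an explicit parametrization against this model's data."""
        return total_cost(
            self.spec, config, delays, thresholds, self.data,
            self.photoperiod, exclude=self.exclude, alias=self.alias,
        )


class ClockFitResults:
    """Ranked fit results with diagnostics, simulation and phase analysis."""

    def __init__(
        self,
        model: BooleanClockModel,
        results: Sequence[FitResult],
        grid: SearchGrid,
        method: str,
    ) -> None:
        self.model = model
        self.spec = model.spec
        self.results = list(results)
        self.grid = grid
        self.method = method

    @property
    def best(self) -> FitResult:
        return self.results[0]

    @property
    def best_viable(self) -> FitResult | None:
        for r in self.results:
            if r.viable:
                return r
        return None

    @property
    def ranking(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.results, start=1):
            row = {
                "rank": rank,
                "encoding": r.encoding,
                "bitstring": r.lc.bitstring,
                "score": r.score,
                "viable": r.viable,
            }
            if r.viability is not None:
                row["free_run_period"] = r.viability.free_run_period
                row["entrained"] = r.viability.entrained
            for i, d in enumerate(r.delays, start=1):
                row[f"tau_{i}"] = d
            for sp, t in sorted(r.thresholds.items()):
                row[f"T_{sp}"] = t
            rows.append(row)
        return pd.DataFrame(rows)

    def simulate(
        self,
        regime: str = "LD",
        horizon: float = 120.0,
        result: FitResult | None = None,
        history=None,
    ) -> BitTrajectory:
        """Simulate the fitted clock in a labelled regime."""
        from .simulate import simulate as _simulate

        r = result or self.best
        program = regime_program(self.spec, regime, self.model.photoperiod)
        if history is None:
            history = seed_bank(self.spec.topology)["all_off"]
        return _simulate(
            self.spec, r.lc, r.delays, program, history, horizon,
            t_s=self.model.data[next(iter(self.model.data))].t_s,
        )

    def phase_curve(
        self, photoperiods: Sequence[float] | None = None, result: FitResult | None = None
    ) -> list[PhaseTable]:
        r = result or self.best
        return phase_photoperiod_curve(
            self.spec, r.lc, r.delays, photoperiods=photoperiods
        )

    def locking(self, photoperiods: Sequence[float] | None = None) -> dict[str, str]:
        return classify_locking(self.phase_curve(photoperiods))

    def summary(self, top: int = 10) -> str:
        """Plain-text summary table of the top-ranked configurations."""
        lines = []
        spec = self.spec
        lines.append("Boolean clock fit".center(64))
        lines.append("=" * 64)
        lines.append(f"Circuit:            {spec.name}")
        lines.append(
            f"Genes / edges:      {spec.topology.n_genes} / {len(spec.topology.gene_edges)}"
            f" (+{len(spec.topology.light_edges)} light)"
        )
        lines.append(f"Gate slots (d):     {spec.topology.n_gate_slots}")
        lines.append(f"Target period:      {spec.tau_fr} h ({spec.free_run_regime} free run)")
        lines.append(f"Regimes fitted:     {', '.join(self.model.data)}")
        n_obs = sum(s.n_steps for s in self.model.data.values())
        lines.append(f"Samples:            {n_obs}")
        lines.append(f"Method:             {self.method}")
        lines.append(f"Configurations:     {len(self.results)}")
        lines.append("-" * 64)
        lines.append(f"{'rank':>4} {'D(G)':>6}  {'G':<12} {'score':>8} {'viable':>7} {'period':>7}")
        for rank, r in enumerate(self.results[:top], start=1):
            period = (
                f"{r.viability.free_run_period:7.1f}" if r.viability is not None else "      -"
            )
            viable = {True: "yes", False: "no", None: "-"}[r.viable]
            lines.append(
                f"{rank:>4} {r.encoding:>6}  {r.lc.bitstring:<12} {r.score:8.4f} "
                f"{viable:>7} {period}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ClockFitResults {self.spec.name}: {len(self.results)} configurations, "
            f"best D(G)={self.best.encoding} score={self.best.score:.4f}>"
        )
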