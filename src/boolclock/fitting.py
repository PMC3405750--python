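"""Fitting logic configurations and parameters to discretized data.

The cost of a candidate (configuration, delays, thresholds) triple is a
one-step-prediction score: for every gene, the observed (not simulated)
upstream bitstrings are lagged by the candidate delays and pushed
through the gene's logic gates, and the prediction is compared with the
gene's own observed bitstring.  The default comparison is the
normalized Hamming distance (fraction of mismatching samples, 0 = best,
1 = worst); a correlation mode, ``(1 - phi)/2`` with ``phi`` the binary
(Pearson/Matthews) correlation, is available for sensitivity analysis
and falls back to the Hamming score when either bitstring is constant.
Vertex scores are averaged over all scored genes and light regimes, so
the total stays in [0, 1].

Because each gene's score depends only on the delays of its own
incoming edges, the search decomposes per vertex; the loop constraints
(delays around each feedback loop sum to at most the free-running
period) couple the vertices and are enforced on the recombined delay
vector by a small exact branch-and-bound over cost-sorted per-vertex
options.  Thresholds enter only through the finitely many distinct
bitstrings they induce, so each threshold lattice collapses to its
informative representatives before the sweep.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import LogicConfiguration, Topology, build_vertex_rules, enumerate_lcs
from .discretize import ContinuousSeries, ThresholdLattice, binarize, distinct_thresholds, normalize
from .light import DAY_HOURS, LightProgram
from .models import LoopConstraint, ModelSpec, loop_constraints
from .simulate import BitTrajectory, ViabilityReport, check_viability

__all__ = [
    "SearchGrid",
    "FitResult",
    "predict_vertex",
    "vertex_cost",
    "total_cost",
    "exhaustive_fit",
    "anneal_fit",
    "experimental_fit_protocol",
]


@dataclass(frozen=True)
class SearchGrid:
    """Finite search lattice for delays and thresholds.

    Delays run over multiples of ``tau_r = k_tau * t_s`` in
    ``[0, t_max]`` (``t_max`` defaults to the model's free-running
    period, which also bounds every loop sum); thresholds run over the
    lattice ``[t_min, t_max] step t_r``.  With ``refine`` set, a second
    pass re-scores at full resolution (``k_tau=1`` and
    ``refine_t_r``) inside windows of ``refine_delay_radius`` coarse
    delay steps and ``refine_threshold_radius`` coarse threshold steps
    around each configuration's coarse optimum.
    """

    k_tau: int = 2
    t_max: float | None = None
    lattice: ThresholdLattice = field(default_factory=lambda: ThresholdLattice(t_r=0.1))
    refine: bool = False
    refine_t_r: float = 0.025
    refine_delay_radius: int = 3
    refine_threshold_radius: int = 5

    def tau_r(self, t_s: float) -> float:
        if self.k_tau < 1:
            raise ValueError("k_tau must be a positive integer")
        return self.k_tau * t_s

    def delay_values(self, t_s: float, t_max: float) -> np.ndarray:
        step = self.tau_r(t_s)
        n = int(math.floor(t_max / step + 1e-9))
        return step * np.arange(n + 1)


@dataclass
class FitResult:
    """One configuration's optimal parameters and score."""

    lc: LogicConfiguration
    score: float
    delays: tuple[float, ...]
    thresholds: dict[str, float]
    breakdown: dict[str, float] = field(default_factory=dict)
    viability: ViabilityReport | None = None
    refined: bool = False

    @property
    def encoding(self) -> int:
        return self.lc.encoding

    @property
    def viable(self) -> bool | None:
        return None if self.viability is None else self.viability.viable


# ---------------------------------------------------------------------------
# direct (oracle) cost path
# ---------------------------------------------------------------------------

def regime_program(spec: ModelSpec, regime: str, photoperiod: float = 12.0) -> LightProgram:
    """Light program for a labelled regime: 'LD' or the free-run label (DD/LL)."""
    if regime.upper() == "LD":
        return spec.light_program(photoperiod)
    if regime.upper() == spec.free_run_regime:
        return spec.free_run_program()
    raise ValueError(
        f"regime {regime!r} not applicable to {spec.name} "
        f"(expected 'LD' or {spec.free_run_regime!r})"
    )


def predict_vertex(
    spec: ModelSpec,
    config: LogicConfiguration,
    delays: Sequence[float],
    data: BitTrajectory,
    gene: str,
    program: LightProgram,
    alias: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, int]:
    """One-step prediction of ``gene`` from observed upstream bits.

    Returns ``(predicted bits, start)``: predictions are defined from
    sample index ``start`` (the largest lag of the gene's inputs)
    onward.  ``alias`` redirects missing input species to proxy columns
    in the data.
    """
    alias = dict(alias or {})
    topo = spec.topology
    rule = {r.gene: r for r in build_vertex_rules(topo, config)}[gene]
    t_s, n = data.t_s, data.n_steps

    def column(name: str) -> np.ndarray:
        name = alias.get(name, name)
        if name not in data.genes:
            raise ValueError(f"no observed series for input species {name!r}")
        return data.series(name)

    shifted, starts = [], [0]
    for src, slot, g in rule.gene_inputs:
        d = int(round(delays[slot - 1] / t_s))
        x = column(src)
        s = np.zeros(n, dtype=np.int8)
        s[d:] = x[: n - d] if d > 0 else x
        shifted.append(1 - s if g == 1 else s)
        starts.append(d)
    if len(shifted) == 1:
        pred = shifted[0]
    else:
        pred = (shifted[0] | shifted[1]) if rule.combiner == 0 else (shifted[0] & shifted[1])
    if rule.light_inputs:
        t = data.times
        light = np.zeros(n, dtype=np.int8)
        for k, slot in rule.light_inputs:
            light |= np.asarray(program.signal(k, t - delays[slot - 1]), dtype=np.int8)
        pred = (pred | light) if rule.h == 0 else (pred & light)
    start = max(starts)
    if start >= n:
        raise ValueError("delays exceed the length of the data")
    return pred[start:], start


def vertex_cost(
    predicted: np.ndarray, observed: np.ndarray, mode: str = "hamming"
) -> float:
    """Score a predicted against an observed bitstring (0 best, 1 worst)."""
    p = np.asarray(predicted).ravel()
    o = np.asarray(observed).ravel()
    if p.size != o.size or p.size == 0:
        raise ValueError("bitstrings must be non-empty and of equal length")
    hamming = float(np.mean(p != o))
    if mode == "hamming":
        return hamming
    if mode != "correlation":
        raise ValueError(f"unknown cost mode {mode!r}")
    n = p.size
    sx, sy, sxy = int(p.sum()), int(o.sum()), int((p & o).sum())
    denom = sx * (n - sx) * sy * (n - sy)
    if denom == 0:  # constant series carry no correlation signal
        return hamming
    phi = (n * sxy - sx * sy) / math.sqrt(denom)
    return (1.0 - phi) / 2.0


def _scored_genes(topo: Topology, exclude: Sequence[str]) -> list[str]:
    genes = [g for g in topo.genes if topo.gene_parents(g) and g not in exclude]
    if not genes:
        raise ValueError("no scorable vertex")
    return genes


def total_cost(
    spec: ModelSpec,
    config: LogicConfiguration,
    delays: Sequence[float],
    thresholds: Mapping[str, float],
    datasets: Mapping[str, ContinuousSeries],
    photoperiod: float = 12.0,
    exclude: Sequence[str] = (),
    alias: Mapping[str, str] | None = None,
    mode: str = "hamming",
) -> float:
    """Mean one-step-prediction cost over all scored vertices and regimes.

    This is the reference scalar evaluation the search engine must
    reproduce; it normalizes and discretizes each regime's data at the
    given thresholds and scores every vertex.
    """
    alias = dict(alias or {})
    genes = _scored_genes(spec.topology, exclude)
    costs = []
    for regime, series in datasets.items():
        program = regime_program(spec, regime, photoperiod)
        norm = normalize(series)
        th = {s: thresholds[s] for s in norm.species if s in thresholds}
        bits = binarize(norm, th)
        for gene in genes:
            pred, start = predict_vertex(spec, config, delays, bits, gene, program, alias)
            obs = bits.series(alias.get(gene, gene))[start:]
            costs.append(vertex_cost(pred, obs, mode))
    return float(np.mean(costs))


# ---------------------------------------------------------------------------
# vectorized exhaustive search
# ---------------------------------------------------------------------------

class _VertexTask:
    """Static description of one scored vertex for the sweep."""

    def __init__(self, topo: Topology, gene: str, alias: Mapping[str, str]):
        self.gene = gene
        self.target = alias.get(gene, gene)
        self.gene_edges = [
            (j, alias.get(topo.gene_edges[j][0], topo.gene_edges[j][0]), topo.edge_delay_slot(j))
            for j in topo.gene_parents(gene)
        ]
        self.edge_gate_slots = [topo.edge_gate_slot(j) for j, _, _ in self.gene_edges]
        self.combiner_slot = (
            topo.combiner_gate_slot(gene) if len(self.gene_edges) == 2 else None
        )
        self.light_edges = [
            (topo.light_edges[k][0], topo.light_delay_slot(k))
            for k in topo.light_parents(gene)
        ]
        self.h = 0 if topo.free_run_light == 0 else 1
        self.slots = [slot for _, _, slot in self.gene_edges] + [
            slot for _, slot in self.light_edges
        ]

    def gates_of(self, config: LogicConfiguration) -> tuple:
        gates = tuple(config[s] for s in self.edge_gate_slots)
        comb = config[self.combiner_slot] if self.combiner_slot is not None else None
        return gates + (comb,)


def _windowed_mism(mism: np.ndarray, start: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts and window sizes for per-combo valid windows."""
    n = mism.shape[-1]
    c = np.cumsum(mism, axis=-1, dtype=np.int32)
    total = c[..., -1]
    s = np.broadcast_to(start, total.shape).astype(np.int64)
    idx = np.clip(s - 1, 0, n - 1)
    before = np.take_along_axis(c, idx[..., None], axis=-1)[..., 0]
    before = np.where(s > 0, before, 0)
    return total - before, (n - s)


def _task_cost_table(
    task: _VertexTask,
    gates: tuple,
    bits: Mapping[str, Mapping[str, np.ndarray]],  # regime -> species -> bits
    light_bits: Mapping[str, Mapping[tuple[int, int], np.ndarray]],
    delay_values: Mapping[int, np.ndarray],
    t_s: float,
) -> np.ndarray:
    """Cost of one vertex for all candidate delay combinations.

    Gene-input delay axes are fully vectorized; light-input delay
    combinations are iterated.  Returned shape is the per-slot candidate
    list lengths in ``task.slots`` order.
    """
    regime_costs = []
    for regime, series_bits in bits.items():
        target = series_bits[task.target]
        n = target.shape[0]
        shifted, starts = [], []
        for (j, src, slot), g in zip(task.gene_edges, gates[: len(task.gene_edges)]):
            vals = delay_values[slot]
            steps = np.rint(vals / t_s).astype(int)
            x = series_bits[src]
            sh = np.zeros((len(vals), n), dtype=np.int8)
            for a, d in enumerate(steps):
                sh[a, d:] = x[: n - d] if d > 0 else x
            shifted.append(1 - sh if g == 1 else sh)
            starts.append(steps)
        if len(shifted) == 1:
            pred = shifted[0]
            gene_start = starts[0]
        else:
            comb = gates[-1]
            a, b = shifted[0][:, None, :], shifted[1][None, :, :]
            pred = (a | b) if comb == 0 else (a & b)
            gene_start = np.maximum(starts[0][:, None], starts[1][None, :])
        if not task.light_edges:
            mism = pred != target
            count, size = _windowed_mism(mism, gene_start)
            regime_costs.append(count / size)
            continue
        dims = tuple(len(delay_values[slot]) for slot in task.slots)
        out = np.empty(dims, dtype=float)
        light_axes_sizes = dims[len(task.gene_edges) :]
        # light signals are closed-form in t, so lagging them never shrinks
        # the prediction window; identical lagged signals share one pass
        cache: dict[bytes, np.ndarray] = {}
        for combo in itertools.product(*(range(sz) for sz in light_axes_sizes)):
            light = None
            for (k, slot), ci in zip(task.light_edges, combo):
                lb = light_bits[regime][(k, int(round(delay_values[slot][ci] / t_s)))]
                light = lb if light is None else (light | lb)
            lkey = light.tobytes()
            if lkey not in cache:
                full = (pred | light) if task.h == 0 else (pred & light)
                mism = full != target
                count, size = _windowed_mism(mism, gene_start)
                cache[lkey] = count / size
            out[(...,) + combo] = cache[lkey]
        regime_costs.append(out)
    return np.mean(regime_costs, axis=0)


def _sorted_options(table: np.ndarray, delay_values, slots) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a cost table into (costs, delay rows), cost-ascending, stable."""
    flat = table.ravel()
    order = np.argsort(flat, kind="stable")
    grids = np.meshgrid(*(delay_values[s] for s in slots), indexing="ij")
    rows = np.stack([g.ravel() for g in grids], axis=1) if slots else np.zeros((1, 0))
    return flat[order], rows[order]


def _min_assignment(
    tasks: Sequence[_VertexTask],
    options: Sequence[tuple[np.ndarray, np.ndarray]],
    constraints: Sequence[LoopConstraint],
    base_delays: Mapping[int, float],
) -> tuple[float, dict[int, float]] | None:
    """Exact min of summed vertex costs under the loop-sum constraints.

    Depth-first search over cost-sorted per-vertex options; at each node
    the options of the current vertex are filtered in one vectorized
    pass against the remaining loop budgets, and subtrees that cannot
    beat the incumbent (partial cost plus the sum of the remaining
    vertices' unconstrained minima) are pruned.  ``base_delays`` holds
    fixed contributions of slots not owned by any scored vertex (e.g.
    delays through excluded genes).
    """
    n_cons = len(constraints)
    order = sorted(range(len(tasks)), key=lambda i: -len(options[i][0]))
    suffix_lb = [0.0] * (len(order) + 1)
    for pos in range(len(order) - 1, -1, -1):
        suffix_lb[pos] = suffix_lb[pos + 1] + float(options[order[pos]][0][0])
    # per-option contribution of each vertex to each loop sum
    contribs = []
    for i in range(len(tasks)):
        rows = options[i][1]
        mat = np.zeros((rows.shape[0], n_cons))
        for m, c in enumerate(constraints):
            cols = [j for j, s in enumerate(tasks[i].slots) if s in c.delay_slots]
            if cols:
                mat[:, m] = rows[:, cols].sum(axis=1)
        contribs.append(mat)
    budgets0 = np.array(
        [
            c.bound + 1e-9 - sum(base_delays.get(s, 0.0) for s in c.delay_slots)
            for c in constraints
        ]
    )
    best_cost = math.inf
    best_choice: list[int] | None = None
    choice = [0] * len(order)

    def dfs(pos: int, partial: float, budgets: np.ndarray) -> None:
        nonlocal best_cost, best_choice
        if pos == len(order):
            if partial < best_cost:
                best_cost = partial
                best_choice = list(choice)
            return
        ti = order[pos]
        costs, _ = options[ti]
        lb_rest = suffix_lb[pos + 1]
        feasible = np.nonzero((contribs[ti] <= budgets).all(axis=1))[0]
        for ci in feasible:
            cand = partial + float(costs[ci]) + lb_rest
            if cand >= best_cost:
                break  # costs ascend: no later option can improve
            choice[pos] = int(ci)
            dfs(pos + 1, partial + float(costs[ci]), budgets - contribs[ti][ci])

    dfs(0, 0.0, budgets0)
    if best_choice is None:
        return None
    assign: dict[int, float] = {}
    for pos, ci in enumerate(best_choice):
        ti = order[pos]
        for s, v in zip(tasks[ti].slots, options[ti][1][ci]):
            assign[s] = float(v)
    return best_cost, assign


class _Sweep:
    """Shared state of one exhaustive sweep (normalized data, programs, tasks)."""

    def __init__(
        self,
        spec: ModelSpec,
        datasets: Mapping[str, ContinuousSeries],
        photoperiod: float,
        exclude: Sequence[str],
        alias: Mapping[str, str],
        t_s: float | None,
    ) -> None:
        self.spec = spec
        self.alias = dict(alias)
        self.photoperiod = photoperiod
        self.norm = {r: normalize(s) for r, s in datasets.items()}
        t_ss = {s.t_s for s in self.norm.values()}
        if len(t_ss) != 1:
            raise ValueError("all regimes must share one sampling interval")
        self.t_s = t_s if t_s is not None else t_ss.pop()
        self.programs = {
            r: regime_program(spec, r, photoperiod) for r in self.norm
        }
        self.genes = _scored_genes(spec.topology, exclude)
        self.tasks = [_VertexTask(spec.topology, g, self.alias) for g in self.genes]
        self.species = sorted({t.target for t in self.tasks} | {
            src for t in self.tasks for _, src, _ in t.gene_edges
        })
        for sp in self.species:
            for r, s in self.norm.items():
                if sp not in s.species:
                    raise ValueError(f"regime {r!r} is missing species {sp!r}")
        self.constraints = loop_constraints(spec)
        self.owned = {s for t in self.tasks for s in t.slots}

    def threshold_reps(self, candidates: Mapping[str, Sequence[float]]) -> dict[str, list[float]]:
        """Deduplicate candidate thresholds per species across all regimes."""
        reps: dict[str, list[float]] = {}
        for sp in self.species:
            concat = np.concatenate([s.values(sp) for s in self.norm.values()])
            seen: set[bytes] = set()
            keep = []
            for t in candidates[sp]:
                key = (concat > t).tobytes()
                if key not in seen:
                    seen.add(key)
                    keep.append(float(t))
            reps[sp] = keep
        return reps

    def bits_for(self, thresholds: Mapping[str, float]):
        bits = {}
        for r, s in self.norm.items():
            bits[r] = {
                sp: (s.values(sp) > thresholds[sp]).astype(np.int8)
                for sp in self.species
            }
        return bits

    def light_bits_for(self, delay_values: Mapping[int, np.ndarray]):
        """Lagged light signals per regime, keyed by (light index, lag steps)."""
        out: dict[str, dict[tuple[int, int], np.ndarray]] = {}
        for r, s in self.norm.items():
            t = s.times
            prog = self.programs[r]
            table: dict[tuple[int, int], np.ndarray] = {}
            for task in self.tasks:
                for k, slot in task.light_edges:
                    for v in delay_values[slot]:
                        d = int(round(v / self.t_s))
                        if (k, d) not in table:
                            table[(k, d)] = np.asarray(
                                prog.signal(k, t - d * self.t_s), dtype=np.int8
                            )
            out[r] = table
        return out

    def optimize_lc(
        self,
        config: LogicConfiguration,
        delay_values: Mapping[int, np.ndarray],
        threshold_reps: Mapping[str, Sequence[float]],
        light_bits,
        table_cache: dict | None = None,
        bits_cache: dict | None = None,
    ) -> tuple[float, dict[int, float], dict[str, float]] | None:
        """Best (cost sum, delays, thresholds) of one configuration."""
        base = {
            s: float(delay_values[s][0])
            for s in range(1, self.spec.topology.n_delay_slots + 1)
            if s not in self.owned and len(delay_values[s]) == 1
        }
        best: tuple[float, dict[int, float], dict[str, float]] | None = None
        names = list(threshold_reps)
        for combo in itertools.product(*(threshold_reps[sp] for sp in names)):
            th = dict(zip(names, combo))
            key = tuple(combo)
            if bits_cache is not None and key in bits_cache:
                bits = bits_cache[key]
            else:
                bits = self.bits_for(th)
                if bits_cache is not None:
                    bits_cache[key] = bits
            options = []
            for task in self.tasks:
                gates = task.gates_of(config)
                ckey = (key, task.gene, gates)
                if table_cache is not None and ckey in table_cache:
                    options.append(table_cache[ckey])
                    continue
                table = _task_cost_table(
                    task, gates, bits, light_bits, delay_values, self.t_s
                )
                opt = _sorted_options(table, delay_values, task.slots)
                if table_cache is not None:
                    table_cache[ckey] = opt
                options.append(opt)
            res = _min_assignment(self.tasks, options, self.constraints, base)
            if res is None:
                continue
            cost, assign = res
            if best is None or cost < best[0] - 1e-12:
                best = (cost, assign, th)
        return best

    def full_delays(
        self, assign: Mapping[int, float], delay_values: Mapping[int, np.ndarray]
    ) -> tuple[float, ...]:
        out = []
        for s in range(1, self.spec.topology.n_delay_slots + 1):
            if s in assign:
                out.append(assign[s])
            else:
                out.append(float(delay_values[s][0]))
        return tuple(out)


def exhaustive_fit(
    spec: ModelSpec,
    datasets: Mapping[str, ContinuousSeries],
    lcs: Iterable[LogicConfiguration] | None = None,
    grid: SearchGrid | None = None,
    t_s: float | None = None,
    photoperiod: float = 12.0,
    fixed_delays: Mapping[int, float] | None = None,
    exclude: Sequence[str] = (),
    alias: Mapping[str, str] | None = None,
    mode: str = "hamming",
    check_viable: bool = True,
    require_entrainment: bool = True,
) -> list[FitResult]:
    """Score every candidate configuration and rank by optimal cost.

    For each configuration the minimum cost over all loop-feasible delay
    vectors and informative thresholds is found (two-stage if
    ``grid.refine``); results are sorted by ascending score, ties broken
    by ascending decimal encoding, then lexicographic delays.  When
    ``check_viable`` is set, each configuration's fitted parameters are
    classified with the discretized free-run data as initial history.

    ``fixed_delays`` pins delay slots (1-based) to fixed values;
    ``exclude`` removes genes from scoring; ``alias`` maps a gene to the
    species whose observed series stands in for it.
    """
    if mode != "hamming":
        raise NotImplementedError(
            "the lattice sweep scores with the normalized Hamming distance; "
            "use total_cost/anneal_fit for the correlation mode"
        )
    grid = grid or SearchGrid()
    fixed_delays = dict(fixed_delays or {})
    sweep = _Sweep(spec, datasets, photoperiod, exclude, alias or {}, t_s)
    lcs = list(lcs) if lcs is not None else list(enumerate_lcs(spec.topology))
    if not lcs:
        raise ValueError("empty configuration set")
    t_max = grid.t_max if grid.t_max is not None else spec.tau_fr

    def value_map(values: np.ndarray) -> dict[int, np.ndarray]:
        out = {}
        for s in range(1, spec.topology.n_delay_slots + 1):
            if s in fixed_delays:
                out[s] = np.array([float(fixed_delays[s])])
            else:
                out[s] = values
        return out

    coarse_values = value_map(grid.delay_values(sweep.t_s, t_max))
    if any(len(v) == 0 for v in coarse_values.values()):
        raise ValueError("delay grid is empty")
    lat = grid.lattice
    reps = sweep.threshold_reps({sp: lat.values() for sp in sweep.species})
    light_bits = sweep.light_bits_for(coarse_values)

    n_v = len(sweep.tasks)
    results: list[FitResult] = []
    table_cache: dict = {}
    bits_cache: dict = {}
    for config in lcs:
        best = sweep.optimize_lc(
            config, coarse_values, reps, light_bits, table_cache, bits_cache
        )
        if best is None:
            raise ValueError("no loop-feasible delay vector on the grid")
        cost, assign, th = best
        delays = sweep.full_delays(assign, coarse_values)
        refined = False
        if grid.refine:
            fine = _refined_search(
                sweep, spec, config, grid, delays, th, t_max, fixed_delays
            )
            if fine is not None and fine[0] < cost - 1e-12:
                cost, delays, th = fine
                refined = True
        results.append(
            FitResult(
                lc=config,
                score=cost / n_v,
                delays=delays,
                thresholds=dict(th),
                refined=refined,
            )
        )

    for res in results:
        res.breakdown = _breakdown(sweep, res)
        if check_viable:
            res.viability = _fit_viability(
                sweep, res, require_entrainment=require_entrainment
            )

    results.sort(key=lambda r: (r.score, r.encoding, r.delays))
    return results


def _refined_search(
    sweep: _Sweep,
    spec: ModelSpec,
    config: LogicConfiguration,
    grid: SearchGrid,
    coarse_delays: tuple[float, ...],
    coarse_th: Mapping[str, float],
    t_max: float,
    fixed_delays: Mapping[int, float],
):
    """Full-resolution re-score inside windows around the coarse optimum."""
    tau_r = grid.tau_r(sweep.t_s)
    radius = grid.refine_delay_radius * tau_r
    values: dict[int, np.ndarray] = {}
    for s in range(1, spec.topology.n_delay_slots + 1):
        if s in fixed_delays:
            values[s] = np.array([float(fixed_delays[s])])
            continue
        center = coarse_delays[s - 1]
        lo = max(0.0, center - radius)
        hi = min(t_max, center + radius)
        n = int(round((hi - lo) / sweep.t_s))
        values[s] = lo + sweep.t_s * np.arange(n + 1)
    lat = grid.lattice
    t_radius = grid.refine_threshold_radius * lat.t_r
    cands: dict[str, list[float]] = {}
    for sp in sweep.species:
        c = coarse_th[sp]
        fine = ThresholdLattice(lat.t_min, lat.t_max, grid.refine_t_r).values()
        cands[sp] = [float(v) for v in fine if c - t_radius - 1e-9 <= v <= c + t_radius + 1e-9]
    reps = sweep.threshold_reps(cands)
    light_bits = sweep.light_bits_for(values)
    best = sweep.optimize_lc(config, values, reps, light_bits)
    if best is None:
        return None
    cost, assign, th = best
    return cost, sweep.full_delays(assign, values), th


def _breakdown(sweep: _Sweep, res: FitResult) -> dict[str, float]:
    """Per-vertex mean cost across regimes at the fitted parameters."""
    out: dict[str, list[float]] = {g: [] for g in sweep.genes}
    for regime, series in sweep.norm.items():
        keep = [sp for sp in series.species if sp in res.thresholds]
        sub = replace(series, data=series.data[keep])
        bits = binarize(sub, res.thresholds)
        for gene in sweep.genes:
            pred, start = predict_vertex(
                sweep.spec, res.lc, res.delays, bits, gene,
                sweep.programs[regime], sweep.alias,
            )
            obs = bits.series(sweep.alias.get(gene, gene))[start:]
            out[gene].append(vertex_cost(pred, obs))
    return {g: float(np.mean(v)) for g, v in out.items()}


def _fit_viability(
    sweep: _Sweep, res: FitResult, require_entrainment: bool
) -> ViabilityReport:
    spec = sweep.spec
    free_regime = spec.free_run_regime
    init = None
    if free_regime in sweep.norm:
        series = sweep.norm[free_regime]
        keep = [sp for sp in series.species if sp in res.thresholds]
        bits = binarize(replace(series, data=series.data[keep]), res.thresholds)
        cols = []
        for g in spec.topology.genes:
            name = sweep.alias.get(g, g)
            cols.append(
                bits.series(name)
                if name in bits.genes
                else np.zeros(bits.n_steps, dtype=np.int8)
            )
        init = BitTrajectory(
            t_s=bits.t_s, genes=spec.topology.genes, states=np.stack(cols, axis=1)
        )
    return check_viability(
        spec,
        res.lc,
        res.delays,
        init_data=init,
        t_s=sweep.t_s,
        require_entrainment=require_entrainment,
    )


# ---------------------------------------------------------------------------
# simulated annealing on the same lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling; temperature 0 gives pure greedy descent."""

    t0: float = 0.1
    cooling: float = 0.95
    steps: int = 500


def anneal_fit(
    spec: ModelSpec,
    config: LogicConfiguration,
    datasets: Mapping[str, ContinuousSeries],
    grid: SearchGrid | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
    start: tuple[Sequence[float], Mapping[str, float]] | None = None,
    photoperiod: float = 12.0,
    fixed_delays: Mapping[int, float] | None = None,
    exclude: Sequence[str] = (),
    alias: Mapping[str, str] | None = None,
    mode: str = "hamming",
    check_viable: bool = True,
    require_entrainment: bool = True,
) -> FitResult:
    """Stochastic descent over the delay/threshold lattice for one configuration.

    Moves change a single delay by one delay-resolution step or a single
    threshold by one threshold step, rejecting loop-infeasible
    proposals; the best visited point is returned, so the result is
    never worse than the start.  Fully reproducible given ``seed``.
    """
    grid = grid or SearchGrid()
    schedule = schedule or AnnealSchedule()
    fixed_delays = dict(fixed_delays or {})
    sweep = _Sweep(spec, datasets, photoperiod, exclude, alias or {}, None)
    rng = np.random.default_rng(seed)
    t_max = grid.t_max if grid.t_max is not None else spec.tau_fr
    tau_r = grid.tau_r(sweep.t_s)
    lat = grid.lattice
    tgrid = lat.values()
    cons = sweep.constraints

    def feasible(d: Sequence[float]) -> bool:
        return all(c.satisfied(d) for c in cons)

    n_slots = spec.topology.n_delay_slots
    free_slots = [s for s in range(1, n_slots + 1) if s not in fixed_delays]
    if start is not None:
        delays = list(start[0])
        th = dict(start[1])
        if not feasible(delays):
            raise ValueError("infeasible starting delays")
    else:
        for _ in range(1000):
            delays = [
                fixed_delays.get(
                    s, float(rng.choice(grid.delay_values(sweep.t_s, t_max)))
                )
                for s in range(1, n_slots + 1)
            ]
            if feasible(delays):
                break
        else:  # pragma: no cover - degenerate constraint sets
            raise ValueError("could not sample a feasible start")
        th = {sp: float(rng.choice(tgrid)) for sp in sweep.species}

    def cost_of(d, t):
        return total_cost(
            spec, config, d, t, sweep.norm, photoperiod,
            exclude=[g for g in spec.topology.genes if g not in sweep.genes],
            alias=sweep.alias, mode=mode,
        )

    cur = cost_of(delays, th)
    best_d, best_th, best_c = list(delays), dict(th), cur
    temp = schedule.t0
    for _ in range(schedule.steps):
        prop_d, prop_th = list(delays), dict(th)
        if free_slots and (not sweep.species or rng.random() < 0.5):
            s = int(rng.choice(free_slots))
            step = tau_r if rng.random() < 0.5 else -tau_r
            v = prop_d[s - 1] + step
            if not 0.0 <= v <= t_max:
                continue
            prop_d[s - 1] = v
            if not feasible(prop_d):
                continue
        else:
            sp = str(rng.choice(sweep.species))
            step = lat.t_r if rng.random() < 0.5 else -lat.t_r
            v = prop_th[sp] + step
            if not lat.t_min - 1e-9 <= v <= lat.t_max + 1e-9:
                continue
            prop_th[sp] = float(v)
        c = cost_of(prop_d, prop_th)
        if c <= cur or (temp > 0 and rng.random() < math.exp((cur - c) / temp)):
            delays, th, cur = prop_d, prop_th, c
            if cur < best_c:
                best_d, best_th, best_c = list(delays), dict(th), cur
        temp *= schedule.cooling

    res = FitResult(
        lc=config, score=best_c, delays=tuple(best_d), thresholds=dict(best_th)
    )
    res.breakdown = _breakdown(sweep, res)
    if check_viable:
        res.viability = _fit_viability(sweep, res, require_entrainment)
    return res


# ---------------------------------------------------------------------------
# luciferase-data protocol for the 3-loop circuit
# ---------------------------------------------------------------------------

LUC_SPECIES_MAP = {"CCA1": "LHY", "TOC1": "TOC1", "GI": "Y", "PRR9": "PRR"}


def experimental_fit_protocol(
    spec: ModelSpec,
    data_ll: ContinuousSeries,
    grid: SearchGrid | None = None,
    extra_fixed_gates: Mapping[int, int] | None = None,
    check_viable: bool = True,
) -> list[FitResult]:
    """Fit the 3-loop circuit to free-running (LL) expression data.

    Conventions of the luciferase fit: reporter genes are mapped onto
    model species (CCA1->LHY, GI->Y, PRR9->PRR); the hypothetical gene X
    has no biological correlate, so it is excluded from costing, its
    input gate and delay are fixed (g2 = 0, tau2 = 0, which leaves 1024
    candidate configurations) and the observed TOC1 bits proxy for X
    when scoring LHY; all light pulses are 24 h and the light delays,
    dynamically irrelevant in LL, are fixed at 0.  Viability requires
    only a free-running limit cycle with period within 20% of 24 h.

    ``extra_fixed_gates`` pins additional gate slots, e.g. ``{1: 1, 3: 0}``
    (with the always-fixed g2=0) constrains the LHY–TOC1 loop to
    repression of TOC1 by LHY and activation of LHY by TOC1.
    """
    if spec.name != "arabidopsis_3loop":
        raise ValueError("the experimental protocol is defined for arabidopsis_3loop")
    mapped = data_ll.rename(
        {k: v for k, v in LUC_SPECIES_MAP.items() if k in data_ll.species}
    )
    missing = {"LHY", "TOC1", "Y", "PRR"} - set(mapped.species)
    if missing:
        raise ValueError(f"missing mapped species: {sorted(missing)}")
    fixed_gates = {2: 0, **(extra_fixed_gates or {})}
    lcs = list(enumerate_lcs(spec.topology, fixed_gates))
    fixed_delays = {2: 0.0}
    for k in range(len(spec.topology.light_edges)):
        fixed_delays[spec.topology.light_delay_slot(k)] = 0.0
    # all light pulses at 24 h == the LL free-run program
    return exhaustive_fit(
        spec,
        {"LL": mapped},
        lcs=lcs,
        grid=grid or SearchGrid(lattice=ThresholdLattice(t_r=0.2)),
        fixed_delays=fixed_delays,
        exclude=("X",),
        alias={"X": "TOC1"},
        check_viable=check_viable,
        require_entrainment=False,
    )
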