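"""Built-in clock circuits and their published optimal parameter sets.

Four circuits of increasing complexity are shipped:

``neurospora_1loop``
    *frq*/FRQ single negative feedback loop, one light input, free-runs
    in darkness (DD), target free-running period 22 h.
``neurospora_2loop``
    *frq* with two FRQ isoforms forming two interlocked negative loops,
    one light input, DD free-run, 22 h.
``arabidopsis_2loop``
    LHY–TOC1 loop closed through the hypothetical gene X, interlocked
    with the Y–TOC1 loop; three light inputs; free-runs in constant
    light (LL), 25 h.
``arabidopsis_3loop``
    Adds the PRR gene (light-driven repressor of LHY) and a fourth,
    pulsed light input; LL free-run, 24 h.

For each circuit the module records the optimal logic configuration and
delay/threshold vector obtained by fitting to synthetic data, plus the
fixed light-pulse parameters (``None`` marks the continuous LD input
whose pulse length equals the photoperiod).  For the 3-loop circuit the
two top parameter sets from the luciferase-data fit (``G_OPT`` and
``G_DE``) are also included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx

from .core import COMBINER, EDGE, LogicConfiguration, Topology
from .light import DAY_HOURS, LightProgram

__all__ = [
    "ModelSpec",
    "LoopConstraint",
    "builtin_model",
    "builtin_names",
    "loop_constraints",
    "experimental_parameter_sets",
]


@dataclass(frozen=True)
class LoopConstraint:
    """Delays of one feedback loop must sum to at most the free-running period."""

    delay_slots: tuple[int, ...]  # 1-based slots
    bound: float

    def satisfied(self, delays: Sequence[float]) -> bool:
        return sum(delays[s - 1] for s in self.delay_slots) <= self.bound + 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """A topology together with its target period and default parameters."""

    topology: Topology
    tau_fr: float
    default_lc: LogicConfiguration
    default_delays: tuple[float, ...]
    default_thresholds: Mapping[str, float]
    light_pulses: tuple[float | None, ...]  # None = pulse length equals photoperiod
    de_pattern: tuple[int, ...]
    omega: float  # system-size parameter of the emulated stochastic datasets

    def __post_init__(self) -> None:
        if len(self.default_delays) != self.topology.n_delay_slots:
            raise ValueError("delay vector length does not match topology")
        if len(self.light_pulses) != self.topology.m_lights:
            raise ValueError("one pulse parameter per light input required")
        for c in loop_constraints(self):
            if not c.satisfied(self.default_delays):
                raise ValueError(f"default delays violate loop constraint {c}")

    @property
    def name(self) -> str:
        return self.topology.name

    def light_program(self, photoperiod: float = 12.0) -> LightProgram:
        """LD program with the model's fixed impulse inputs and the given photoperiod."""
        pulses = tuple(
            photoperiod if p is None else float(p) for p in self.light_pulses
        )
        return LightProgram(pulses=pulses, photoperiod=photoperiod)

    def free_run_program(self) -> LightProgram:
        """Constant-light program of the free-running regime (DD or LL)."""
        level = DAY_HOURS if self.topology.free_run_light == 1 else 0.0
        return LightProgram(
            pulses=(level,) * self.topology.m_lights, photoperiod=12.0
        )

    @property
    def free_run_regime(self) -> str:
        return "LL" if self.topology.free_run_light == 1 else "DD"


def loop_constraints(spec: ModelSpec) -> list[LoopConstraint]:
    """One delay bound per elementary cycle of the gene-edge digraph.

    Every closed signalling loop must traverse its delays within one
    free-running period, which bounds the sum of the delays around each
    elementary cycle by ``tau_fr``.
    """
    topo = spec.topology
    graph = nx.DiGraph()
    graph.add_nodes_from(topo.genes)
    slot_of = {}
    for j, (src, dst) in enumerate(topo.gene_edges):
        graph.add_edge(src, dst)
        slot_of[(src, dst)] = topo.edge_delay_slot(j)
    constraints = []
    for cycle in nx.simple_cycles(graph):
        slots = tuple(
            sorted(
                slot_of[(cycle[i], cycle[(i + 1) % len(cycle)])]
                for i in range(len(cycle))
            )
        )
        constraints.append(LoopConstraint(delay_slots=slots, bound=spec.tau_fr))
    constraints.sort(key=lambda c: c.delay_slots)
    return constraints


# ---------------------------------------------------------------------------
# Built-in circuit definitions
# ---------------------------------------------------------------------------

def _neurospora_1loop() -> ModelSpec:
    topo = Topology(
        name="neurospora_1loop",
        genes=("frq", "FRQ"),
        gene_edges=(("frq", "FRQ"), ("FRQ", "frq")),
        light_edges=((1, "frq"),),
        free_run_light=0,
    )
    return ModelSpec(
        topology=topo,
        tau_fr=22.0,
        default_lc=LogicConfiguration.from_bitstring("01"),
        default_delays=(5.0, 6.5, 7.5),
        default_thresholds={"frq": 0.35, "FRQ": 0.40},
        light_pulses=(None,),
        de_pattern=(0, 1),
        omega=25.0,
    )


def _neurospora_2loop() -> ModelSpec:
    topo = Topology(
        name="neurospora_2loop",
        genes=("frq", "FRQ1", "FRQ2"),
        gene_edges=(
            ("frq", "FRQ1"),
            ("frq", "FRQ2"),
            ("FRQ1", "frq"),
            ("FRQ2", "frq"),
        ),
        light_edges=((1, "frq"),),
        free_run_light=0,
    )
    return ModelSpec(
        topology=topo,
        tau_fr=22.0,
        default_lc=LogicConfiguration.from_bitstring("00111"),
        default_delays=(5.0, 1.5, 6.0, 10.0, 9.0),
        default_thresholds={"frq": 0.425, "FRQ1": 0.525, "FRQ2": 0.250},
        light_pulses=(None,),
        de_pattern=(0, 0, 1, 1),
        omega=50.0,
    )


_ARABIDOPSIS_2LOOP_EDGES = (
    ("LHY", "TOC1"),
    ("TOC1", "X"),
    ("X", "LHY"),
    ("LHY", "Y"),
    ("TOC1", "Y"),
    ("Y", "TOC1"),
)


def _arabidopsis_2loop() -> ModelSpec:
    topo = Topology(
        name="arabidopsis_2loop",
        genes=("LHY", "TOC1", "X", "Y"),
        gene_edges=_ARABIDOPSIS_2LOOP_EDGES,
        light_edges=((1, "LHY"), (2, "Y"), (3, "Y")),
        free_run_light=1,
        gate_order=(
            (EDGE, 0),
            (EDGE, 1),
            (EDGE, 2),
            (EDGE, 3),
            (EDGE, 4),
            (EDGE, 5),
            (COMBINER, "Y"),
            (COMBINER, "TOC1"),
        ),
    )
    return ModelSpec(
        topology=topo,
        tau_fr=25.0,
        default_lc=LogicConfiguration.from_bitstring("10011011"),
        default_delays=(1.5, 5.5, 6.5, 0.0, 7.5, 4.0, 0.0, 2.5, 1.0),
        default_thresholds={"LHY": 0.250, "TOC1": 0.375, "X": 0.575, "Y": 0.150},
        light_pulses=(2.0, None, 0.5),
        de_pattern=(1, 0, 0, 1, 1, 0),
        omega=1000.0,
    )


def _arabidopsis_3loop() -> ModelSpec:
    topo = Topology(
        name="arabidopsis_3loop",
        genes=("LHY", "TOC1", "X", "Y", "PRR"),
        gene_edges=_ARABIDOPSIS_2LOOP_EDGES + (("LHY", "PRR"), ("PRR", "LHY")),
        light_edges=((1, "LHY"), (2, "Y"), (3, "Y"), (4, "PRR")),
        free_run_light=1,
        gate_order=(
            (EDGE, 0),
            (EDGE, 1),
            (EDGE, 2),
            (EDGE, 3),
            (EDGE, 4),
            (EDGE, 5),
            (COMBINER, "Y"),
            (COMBINER, "TOC1"),
            (EDGE, 6),
            (EDGE, 7),
            (COMBINER, "LHY"),
        ),
    )
    return ModelSpec(
        topology=topo,
        tau_fr=24.0,
        default_lc=LogicConfiguration.from_bitstring("10011011011"),
        default_delays=(0.0, 5.5, 7.0, 0.0, 8.0, 5.0, 4.5, 6.0, 1.0, 1.0, 0.5, 3.0),
        default_thresholds={
            "LHY": 0.1250,
            "TOC1": 0.3000,
            "X": 0.6250,
            "Y": 0.2250,
            "PRR": 0.8250,
        },
        light_pulses=(2.0, None, 0.5, 3.0),
        de_pattern=(1, 0, 0, 1, 1, 0, 0, 1),
        omega=1000.0,
    )


_BUILDERS = {
    "neurospora_1loop": _neurospora_1loop,
    "neurospora_2loop": _neurospora_2loop,
    "arabidopsis_2loop": _arabidopsis_2loop,
    "arabidopsis_3loop": _arabidopsis_3loop,
}


def builtin_names() -> list[str]:
    return list(_BUILDERS)


def builtin_model(name: str) -> ModelSpec:
    """Return one of the four built-in circuits by name."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_BUILDERS)}"
        ) from None


def experimental_parameter_sets() -> dict[str, dict]:
    """Top two fits of the 3-loop circuit to luciferase data recorded in LL.

    ``G_OPT`` is the best-scoring configuration (LHY and TOC1 repress
    each other); ``G_DE`` ranks second overall and first when the
    LHY-represses-TOC1 / TOC1-activates-LHY loop is imposed.  The X
    threshold is absent because X was not scored against data; light
    delays are 0 (arbitrary in LL) and all light pulses are 24 h.
    """
    return {
        "G_OPT": {
            "lc": LogicConfiguration.from_bitstring("10101011011"),
            "delays": (1.5, 0.0, 1.5, 9.0, 6.0, 4.5, 1.5, 10.5, 0.0, 0.0, 0.0, 0.0),
            "thresholds": {"LHY": 0.30, "TOC1": 0.40, "Y": 0.15, "PRR": 0.50},
        },
        "G_DE": {
            "lc": LogicConfiguration.from_bitstring("10011011011"),
            "delays": (1.5, 0.0, 10.5, 0.0, 7.5, 4.5, 3.0, 6.0, 0.0, 0.0, 0.0, 0.0),
            "thresholds": {"LHY": 0.35, "TOC1": 0.35, "Y": 0.10, "PRR": 0.45},
        },
    }
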