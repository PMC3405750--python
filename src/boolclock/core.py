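"""Core Boolean-logic machinery for delayed clock-gene networks.

A clock circuit is an *abstract topology*: a set of genes, directed
gene–gene edges, and light inputs wired to particular genes.  Each gene
edge carries a one-input logic gate (identity = activation, NOT =
repression) and each gene with two gene inputs carries a two-input
combiner gate (OR / AND).  The ordered vector of gate bits is the
network's *logic configuration* (LC); its MSB-first decimal expansion
``D(G)`` indexes configurations compactly.

Light inputs do not carry free gates: multiple light signals into one
gene are combined with a fixed OR, and the combined light bit enters the
gene's update through a fixed outer gate ``H`` chosen so that clamping
the lights at the free-running level (0 for dark-free-running circuits,
1 for light-free-running ones) recovers the light-free update rule
exactly (OR with 0 and AND with 1 are identities).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "gate1",
    "gate2",
    "Topology",
    "LogicConfiguration",
    "VertexRule",
    "encode_decimal",
    "decode_decimal",
    "build_vertex_rules",
    "enumerate_lcs",
    "de_consistent_lcs",
]

DAY_HOURS = 24.0


def _check_bit(value: int, name: str) -> int:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")
    return value


def gate1(y: int, g: int) -> int:
    """One-input logic gate: identity (``g=0``, activation) or NOT (``g=1``, repression)."""
    _check_bit(y, "y")
    _check_bit(g, "g")
    return y if g == 0 else 1 - y


def gate2(y: int, z: int, g: int) -> int:
    """Two-input logic gate: inclusive OR (``g=0``) or AND (``g=1``)."""
    _check_bit(y, "y")
    _check_bit(z, "z")
    _check_bit(g, "g")
    return (y | z) if g == 0 else (y & z)


# Gate-slot roles.  A slot is either the single-input gate of one gene edge
# or the two-input combiner of a gene with two gene inputs.
EDGE = "edge"
COMBINER = "combiner"


@dataclass(frozen=True)
class Topology:
    """Abstract topology of a clock circuit.

    Parameters
    ----------
    name : str
        Identifier of the circuit.
    genes : tuple of str
        Gene names, in a fixed order.
    gene_edges : tuple of (str, str)
        Directed regulatory edges ``(source, target)``.  Their order
        fixes the delay slots: gene edge ``j`` (0-based) owns delay slot
        ``j + 1``.
    light_edges : tuple of (int, str)
        Light inputs ``(light index 1..m, target gene)``.  Light edge
        ``k`` (0-based) owns delay slot ``len(gene_edges) + k + 1``.
    free_run_light : int
        Light level of the free-running regime: 0 for constant darkness
        (DD), 1 for constant light (LL).  Fixes the outer light gate H
        (OR for DD, AND for LL) so that free-running conditions recover
        the light-free rules.
    gate_order : tuple
        Ordered gate slots, each ``(EDGE, edge_index)`` or
        ``(COMBINER, gene)``.  If omitted, defaults to all gene edges in
        order followed by combiners in gene order.
    """

    name: str
    genes: tuple[str, ...]
    gene_edges: tuple[tuple[str, str], ...]
    light_edges: tuple[tuple[int, str], ...] = ()
    free_run_light: int = 0
    gate_order: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.free_run_light not in (0, 1):
            raise ValueError("free_run_light must be 0 (DD) or 1 (LL)")
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene names")
        for src, dst in self.gene_edges:
            if src not in gene_set or dst not in gene_set:
                raise ValueError(f"edge ({src}, {dst}) references unknown gene")
        for _, dst in self.light_edges:
            if dst not in gene_set:
                raise ValueError(f"light edge targets unknown gene {dst!r}")
        for gene in self.genes:
            if len(self.gene_parents(gene)) > 2:
                raise ValueError(
                    f"gene {gene!r} has more than two gene inputs; "
                    "only 1- and 2-input gates are supported"
                )
        if not self.gate_order:
            object.__setattr__(self, "gate_order", self._default_gate_order())
        self._validate_gate_order()

    # -- gate slots -----------------------------------------------------

    def _default_gate_order(self) -> tuple[tuple[str, object], ...]:
        slots: list[tuple[str, object]] = [(EDGE, j) for j in range(len(self.gene_edges))]
        slots += [(COMBINER, g) for g in self.genes if len(self.gene_parents(g)) == 2]
        return tuple(slots)

    def _validate_gate_order(self) -> None:
        edges = [s[1] for s in self.gate_order if s[0] == EDGE]
        combiners = [s[1] for s in self.gate_order if s[0] == COMBINER]
        if sorted(edges) != list(range(len(self.gene_edges))):
            raise ValueError("gate_order must contain each gene edge exactly once")
        expected = sorted(g for g in self.genes if len(self.gene_parents(g)) == 2)
        if sorted(combiners) != expected:
            raise ValueError(
                "gate_order must contain exactly one combiner per two-input gene"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def m_lights(self) -> int:
        return max((k for k, _ in self.light_edges), default=0)

    @property
    def n_gate_slots(self) -> int:
        """Number d of free gate bits; the topology admits ``2**d`` LCs."""
        return len(self.gate_order)

    @property
    def n_delay_slots(self) -> int:
        return len(self.gene_edges) + len(self.light_edges)

    def gene_parents(self, gene: str) -> list[int]:
        """Indices of gene edges targeting ``gene``, in edge order."""
        return [j for j, (_, dst) in enumerate(self.gene_edges) if dst == gene]

    def light_parents(self, gene: str) -> list[int]:
        """Indices (0-based, into light_edges) of light edges into ``gene``."""
        return [k for k, (_, dst) in enumerate(self.light_edges) if dst == gene]

    def edge_delay_slot(self, edge_index: int) -> int:
        """1-based delay slot of gene edge ``edge_index``."""
        return edge_index + 1

    def light_delay_slot(self, light_edge_index: int) -> int:
        """1-based delay slot of light edge ``light_edge_index``."""
        return len(self.gene_edges) + light_edge_index + 1

    def edge_gate_slot(self, edge_index: int) -> int:
        """0-based position of gene edge ``edge_index`` in the gate vector."""
        return self.gate_order.index((EDGE, edge_index))

    def combiner_gate_slot(self, gene: str) -> int:
        return self.gate_order.index((COMBINER, gene))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "genes": list(self.genes),
            "gene_edges": [list(e) for e in self.gene_edges],
            "light_edges": [list(e) for e in self.light_edges],
            "free_run_light": self.free_run_light,
            "gate_order": [
                {"role": role, "edge": ref} if role == EDGE else {"role": role, "gene": ref}
                for role, ref in self.gate_order
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Topology":
        gate_order = tuple(
            (EDGE, slot["edge"]) if slot["role"] == EDGE else (COMBINER, slot["gene"])
            for slot in doc.get("gate_order", [])
        )
        return cls(
            name=doc["name"],
            genes=tuple(doc["genes"]),
            gene_edges=tuple((s, d) for s, d in doc["gene_edges"]),
            light_edges=tuple((int(k), d) for k, d in doc.get("light_edges", [])),
            free_run_light=int(doc.get("free_run_light", 0)),
            gate_order=gate_order,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Topology":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class LogicConfiguration:
    """Ordered gate bits ``(g_1, ..., g_d)``; bit semantics depend on the slot role.

    Edge slots: 0 = identity (activation), 1 = NOT (repression).
    Combiner slots: 0 = OR, 1 = AND.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        for b in self.bits:
            _check_bit(b, "gate bit")

    def __len__(self) -> int:
        return len(self.bits)

    def __getitem__(self, i: int) -> int:
        return self.bits[i]

    def __iter__(self):
        return iter(self.bits)

    @property
    def encoding(self) -> int:
        return encode_decimal(self)

    @property
    def bitstring(self) -> str:
        """MSB-first rendering, first gate leftmost (e.g. ``'00111'``)."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_bitstring(cls, s: str) -> "LogicConfiguration":
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.bitstring


def encode_decimal(config: LogicConfiguration | Sequence[int]) -> int:
    """MSB-first decimal expansion ``D(G) = sum_l g_l 2^(d-l)`` of a configuration."""
    bits = config.bits if isinstance(config, LogicConfiguration) else tuple(config)
    value = 0
    for b in bits:
        value = (value << 1) | _check_bit(b, "gate bit")
    return value


def decode_decimal(value: int, d: int) -> LogicConfiguration:
    """Inverse of :func:`encode_decimal` for a configuration of length ``d``."""
    if value < 0 or value >= (1 << d):
        raise ValueError(f"encoding {value} out of range for {d} gate bits")
    bits = tuple((value >> (d - 1 - i)) & 1 for i in range(d))
    return LogicConfiguration(bits)


@dataclass(frozen=True)
class VertexRule:
    """Per-gene Boolean update rule.

    The free-running part passes each gene input through its edge gate
    and, for two inputs, combines them with the combiner gate.  Light
    inputs (if any) are ORed together and enter through the fixed outer
    gate ``h`` (0 = OR for DD circuits, 1 = AND for LL circuits).

    ``gene_inputs`` holds ``(source gene, delay slot, gate bit)`` triples;
    ``light_inputs`` holds ``(light index, delay slot)`` pairs.
    """

    gene: str
    gene_inputs: tuple[tuple[str, int, int], ...]
    combiner: int | None = None
    light_inputs: tuple[tuple[int, int], ...] = ()
    h: int | None = None

    def __post_init__(self) -> None:
        if len(self.gene_inputs) == 2 and self.combiner is None:
            raise ValueError(f"gene {self.gene!r} has two inputs but no combiner gate")
        if self.light_inputs and self.h is None:
            raise ValueError(f"gene {self.gene!r} has light inputs but no outer gate H")

    def free_run_value(self, gene_bits: Sequence[int]) -> int:
        """Evaluate the light-free part s_i^F on the (already lagged) gene input bits."""
        if not self.gene_inputs:
            raise ValueError(f"gene {self.gene!r} has no gene inputs")
        vals = [gate1(_check_bit(b, "input"), g) for b, (_, _, g) in zip(gene_bits, self.gene_inputs)]
        if len(vals) == 1:
            return vals[0]
        return gate2(vals[0], vals[1], self.combiner)

    def __call__(self, gene_bits: Sequence[int], light_bits: Sequence[int] = ()) -> int:
        """Evaluate the full rule on lagged gene input bits and lagged light bits."""
        out = self.free_run_value(gene_bits)
        if not self.light_inputs:
            return out
        if len(light_bits) != len(self.light_inputs):
            raise ValueError("wrong number of light input bits")
        light = 0
        for b in light_bits:
            light |= _check_bit(b, "light")
        return gate2(out, light, self.h)

    def check_consistency(self, free_run_light: int) -> bool:
        """H(s^F(X), L_free) == s^F(X) for every input combination X."""
        q = len(self.gene_inputs)
        for bits in itertools.product((0, 1), repeat=q):
            f = self.free_run_value(bits)
            full = self(bits, (free_run_light,) * len(self.light_inputs))
            if full != f:
                return False
        return True


def build_vertex_rules(
    topology: Topology, config: LogicConfiguration
) -> list[VertexRule]:
    """Compose per-gene update rules from a topology and a logic configuration."""
    if len(config) != topology.n_gate_slots:
        raise ValueError(
            f"configuration has {len(config)} bits, topology has "
            f"{topology.n_gate_slots} gate slots"
        )
    h = 0 if topology.free_run_light == 0 else 1  # OR for DD, AND for LL
    rules = []
    for gene in topology.genes:
        parents = topology.gene_parents(gene)
        gene_inputs = tuple(
            (
                topology.gene_edges[j][0],
                topology.edge_delay_slot(j),
                config[topology.edge_gate_slot(j)],
            )
            for j in parents
        )
        combiner = (
            config[topology.combiner_gate_slot(gene)] if len(parents) == 2 else None
        )
        lights = topology.light_parents(gene)
        light_inputs = tuple(
            (topology.light_edges[k][0], topology.light_delay_slot(k)) for k in lights
        )
        rules.append(
            VertexRule(
                gene=gene,
                gene_inputs=gene_inputs,
                combiner=combiner,
                light_inputs=light_inputs,
                h=h if light_inputs else None,
            )
        )
    return rules


def enumerate_lcs(
    topology: Topology, fixed: Mapping[int, int] | None = None
) -> Iterator[LogicConfiguration]:
    """Yield all logic configurations, in ascending order of decimal encoding.

    ``fixed`` maps 1-based gate-slot numbers to pinned bit values; the
    remaining slots range over all combinations.
    """
    d = topology.n_gate_slots
    fixed = dict(fixed or {})
    for slot, bit in fixed.items():
        if not 1 <= slot <= d:
            raise KeyError(f"unknown gate slot g{slot}")
        _check_bit(bit, f"g{slot}")
    free = [i for i in range(d) if (i + 1) not in fixed]
    template = [0] * d
    for slot, bit in fixed.items():
        template[slot - 1] = bit
    for combo in itertools.product((0, 1), repeat=len(free)):
        bits = list(template)
        for i, b in zip(free, combo):
            bits[i] = b
        yield LogicConfiguration(tuple(bits))


def de_consistent_lcs(
    topology: Topology, sign_pattern: Sequence[int] | Mapping[tuple[str, str], int]
) -> list[LogicConfiguration]:
    """Configurations whose edge gates match a given activation/repression pattern.

    ``sign_pattern`` gives, for every gene edge, 0 for activation and 1
    for repression — either as a sequence in edge order or as a mapping
    from ``(source, target)`` pairs.  Combiner gates remain free, so the
    result has ``2**(#two-input genes)`` configurations.
    """
    if isinstance(sign_pattern, Mapping):
        try:
            pattern = [sign_pattern[e] for e in topology.gene_edges]
        except KeyError as exc:
            raise ValueError(f"sign pattern missing edge {exc.args[0]!r}") from exc
    else:
        pattern = list(sign_pattern)
    if len(pattern) != len(topology.gene_edges):
        raise ValueError(
            f"sign pattern covers {len(pattern)} edges, topology has "
            f"{len(topology.gene_edges)}"
        )
    fixed = {
        topology.edge_gate_slot(j) + 1: _check_bit(s, "sign")
        for j, s in enumerate(pattern)
    }
    return list(enumerate_lcs(topology, fixed))
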