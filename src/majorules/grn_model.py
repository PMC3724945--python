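"""Signed regulatory networks, configurations and state-space indexing.

A threshold Boolean gene regulatory network is a signed directed graph:
nodes are genes (or regulatory components), a positive edge is an
activation and a negative edge is a repression.  Gene values evolve
synchronously under a majority rule evaluated over each gene's regulators;
ties (equal activating and repressing contributions) are resolved at
random, ON with a per-node probability ``p`` and OFF with ``1 - p``.

Two value representations are used, matching the two families of rules:

* *spin*: values in {-1, +1}; an absent regulator contributes with the
  sign opposite to its present effect (plain and inertial majority rules).
* *boolean*: values in {0, 1}; an absent regulator contributes nothing
  (null and inertial-null majority rules).

The state space of an ``n``-node network is indexed big-endian: the first
node in the declared order is the most significant bit, and a high value
(+1 spin / 1 boolean) maps to bit 1.  Node order is therefore part of the
model and is preserved by serialisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from numbers import Real
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Rule",
    "SPIN",
    "BOOLEAN",
    "SignedEdge",
    "RegulatoryNetwork",
    "Configuration",
    "StateIndex",
    "NetworkFormatError",
    "load_network",
    "save_network",
    "convert_representation",
    "yeast_network",
    "YEAST_NODES",
    "YEAST_G1_LEVELS",
]

SPIN = "spin"
BOOLEAN = "boolean"

HALF = Fraction(1, 2)


class Rule(str, Enum):
    """The four majority-rule variants.

    MR   -- spin values; tie broken ON with probability p.
    IMR  -- spin values; tie keeps the current value with probability p.
    NMR  -- boolean values (absent regulators play no role); tie -> ON w.p. p.
    INMR -- boolean values; tie keeps the current value with probability p.
    """

    MR = "MR"
    IMR = "IMR"
    NMR = "NMR"
    INMR = "INMR"

    @property
    def representation(self) -> str:
        return SPIN if self in (Rule.MR, Rule.IMR) else BOOLEAN

    @property
    def inertial(self) -> bool:
        """Whether ties are resolved toward the node's current value."""
        return self in (Rule.IMR, Rule.INMR)

    @property
    def null(self) -> bool:
        """Whether absent regulators contribute nothing (boolean levels)."""
        return self in (Rule.NMR, Rule.INMR)


class NetworkFormatError(ValueError):
    """Raised for malformed network files or inconsistent model data."""


_SIGN_TOKENS = {
    "+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1,
    "activate": 1, "inhibit": -1, "activation": 1, "inhibition": -1,
}


@dataclass(frozen=True)
class SignedEdge:
    """A signed regulatory interaction ``source -> target``.

    ``sign`` is +1 for an activation, -1 for a repression.  ``tag`` is a
    free label used e.g. to mark the yeast self-degradation loops
    ("self_degradation") and the two revision edges ("revision").
    """

    source: str
    target: str
    sign: int
    tag: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkFormatError(f"edge sign must be +1 or -1, got {self.sign!r}")


def _as_prob(value) -> Fraction | float:
    """Normalise a tie probability to Fraction (exact) or float."""
    if isinstance(value, Fraction):
        p = value
    elif isinstance(value, int):
        p = Fraction(value)
    elif isinstance(value, str):
        p = Fraction(value)
    elif isinstance(value, float):
        p = value
    elif isinstance(value, Real):
        p = float(value)
    else:
        raise NetworkFormatError(f"cannot interpret tie probability {value!r}")
    if not 0 <= p <= 1:
        raise NetworkFormatError(f"tie probability {value!r} outside [0, 1]")
    return p


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A signed directed regulatory network with per-node tie probabilities.

    Parameters
    ----------
    nodes
        Ordered node identifiers; the order fixes state indexing.
    edges
        Signed interactions; at most one edge per ordered (source, target).
    rule
        The update rule (default MR).
    tie_prob
        Mapping node -> probability of choosing the high value on a tie
        (MR/NMR) or of keeping the current value (IMR/INMR).  Nodes absent
        from the mapping default to 1/2.
    clamped
        Mapping node -> level in {0, 1}; a clamped node is frozen at that
        level regardless of its regulators.
    """

    nodes: tuple[str, ...]
    edges: frozenset[SignedEdge]
    rule: Rule = Rule.MR
    tie_prob: Mapping[str, Fraction | float] = field(default_factory=dict)
    clamped: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        if len(set(nodes)) != len(nodes):
            raise NetworkFormatError("duplicate node identifiers")
        object.__setattr__(self, "nodes", nodes)
        edges = frozenset(self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "rule", Rule(self.rule))
        node_set = set(nodes)
        seen: set[tuple[str, str]] = set()
        for e in edges:
            if e.source not in node_set or e.target not in node_set:
                raise NetworkFormatError(f"edge {e.source}->{e.target} references undeclared node")
            if (e.source, e.target) in seen:
                raise NetworkFormatError(f"duplicate edge {e.source}->{e.target}")
            seen.add((e.source, e.target))
        tie = {k: _as_prob(v) for k, v in dict(self.tie_prob).items()}
        for k in tie:
            if k not in node_set:
                raise NetworkFormatError(f"tie probability for unknown node {k!r}")
        object.__setattr__(self, "tie_prob", tie)
        clamp = {k: int(v) for k, v in dict(self.clamped).items()}
        for k, v in clamp.items():
            if k not in node_set:
                raise NetworkFormatError(f"clamp on unknown node {k!r}")
            if v not in (0, 1):
                raise NetworkFormatError(f"clamp level must be 0 or 1, got {v!r}")
        object.__setattr__(self, "clamped", clamp)
        # regulator lists in stable (node-order, then source-order) form
        order = {name: i for i, name in enumerate(nodes)}
        regs: dict[str, tuple[tuple[str, int], ...]] = {v: () for v in nodes}
        for e in sorted(edges, key=lambda e: (order[e.target], order[e.source])):
            regs[e.target] = regs[e.target] + ((e.source, e.sign),)
        object.__setattr__(self, "_regulators", regs)

    # -- structure ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def regulators(self, node: str) -> tuple[tuple[str, int], ...]:
        """Incoming interactions of ``node`` as (source, sign) pairs."""
        try:
            return self._regulators[node]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def in_degree(self, node: str) -> int:
        return len(self.regulators(node))

    def edge(self, source: str, target: str) -> SignedEdge | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def tie_probability(self, node: str) -> Fraction | float:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        return self.tie_prob.get(node, HALF)

    def clamp_value(self, node: str, representation: str | None = None) -> int | None:
        """The clamped value of ``node`` in the requested representation."""
        if node not in self.clamped:
            return None
        level = self.clamped[node]
        rep = representation or self.rule.representation
        return level if rep == BOOLEAN else 2 * level - 1

    # -- functional updates ------------------------------------------------

    def with_rule(self, rule: Rule | str) -> "RegulatoryNetwork":
        return replace(self, rule=Rule(rule))

    def with_tie_prob(self, tie_prob: Mapping[str, Fraction | float] | Fraction | float) -> "RegulatoryNetwork":
        if isinstance(tie_prob, Mapping):
            merged = {**self.tie_prob, **tie_prob}
        else:
            merged = {v: tie_prob for v in self.nodes}
        return replace(self, tie_prob=merged)

    def with_clamps(self, clamped: Mapping[str, int]) -> "RegulatoryNetwork":
        return replace(self, clamped={**self.clamped, **clamped})

    def without_clamps(self) -> "RegulatoryNetwork":
        return replace(self, clamped={})

    # -- serialisation -----------------------------------------------------

    def to_json_dict(self) -> dict:
        order = {name: i for i, name in enumerate(self.nodes)}
        edges = sorted(self.edges, key=lambda e: (order[e.source], order[e.target]))
        d: dict = {
            "nodes": list(self.nodes),
            "edges": [[e.source, e.target, e.sign] + ([e.tag] if e.tag else []) for e in edges],
            "rule": self.rule.value,
        }
        if self.tie_prob:
            d["tie_prob"] = {
                k: (str(v) if isinstance(v, Fraction) else v) for k, v in self.tie_prob.items()
            }
        if self.clamped:
            d["clamped"] = dict(self.clamped)
        return d

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "RegulatoryNetwork":
        edges = []
        for entry in d.get("edges", []):
            src, tgt, sign = entry[0], entry[1], entry[2]
            tag = entry[3] if len(entry) > 3 else ""
            if isinstance(sign, str):
                try:
                    sign = _SIGN_TOKENS[sign.strip().lower()]
                except KeyError:
                    raise NetworkFormatError(f"unknown sign token {sign!r}") from None
            edges.append(SignedEdge(src, tgt, int(sign), tag))
        return cls(
            nodes=tuple(d["nodes"]),
            edges=frozenset(edges),
            rule=Rule(d.get("rule", "MR")),
            tie_prob=d.get("tie_prob", {}),
            clamped=d.get("clamped", {}),
        )


# -- configurations --------------------------------------------------------


@dataclass(frozen=True)
class Configuration:
    """A full assignment of node values, in spin or boolean representation."""

    values: tuple[int, ...]
    representation: str = SPIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        allowed = (-1, 1) if self.representation == SPIN else (0, 1)
        if self.representation not in (SPIN, BOOLEAN):
            raise ValueError(f"unknown representation {self.representation!r}")
        for v in self.values:
            if v not in allowed:
                raise ValueError(
                    f"value {v} invalid for {self.representation} representation"
                )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def flipped(self) -> "Configuration":
        """The mirror configuration: every value inverted."""
        if self.representation == BOOLEAN:
            return Configuration(tuple(1 - v for v in self.values), BOOLEAN)
        return Configuration(tuple(-v for v in self.values), SPIN)

    def as_bits(self) -> tuple[int, ...]:
        """Values as 0/1 bits regardless of representation."""
        if self.representation == BOOLEAN:
            return self.values
        return tuple((v + 1) // 2 for v in self.values)

    def to_string(self) -> str:
        if self.representation == BOOLEAN:
            return "".join(str(v) for v in self.values)
        return "".join("+" if v == 1 else "-" for v in self.values)

    @classmethod
    def from_string(cls, s: str, representation: str | None = None) -> "Configuration":
        s = s.strip()
        if representation is None:
            representation = SPIN if set(s) <= {"+", "-"} else BOOLEAN
        if representation == SPIN:
            vals = tuple(1 if c == "+" else -1 for c in s)
            if set(s) - {"+", "-"}:
                raise ValueError(f"invalid spin string {s!r}")
        else:
            if set(s) - {"0", "1"}:
                raise ValueError(f"invalid boolean string {s!r}")
            vals = tuple(int(c) for c in s)
        return cls(vals, representation)


def convert_representation(config: Configuration) -> Configuration:
    """Map between boolean {0,1} and spin {-1,+1} values componentwise.

    0 <-> -1 and 1 <-> +1; applying the conversion twice is the identity.
    """
    if config.representation == BOOLEAN:
        return Configuration(tuple(2 * v - 1 for v in config.values), SPIN)
    return Configuration(tuple((v + 1) // 2 for v in config.values), BOOLEAN)


@dataclass(frozen=True)
class StateIndex:
    """Big-endian indexing of the 2^n configuration space.

    Node 1 (first in network order) is the most significant bit; a high
    value (+1 spin / 1 boolean) is bit 1.  The all-low configuration is
    index 0 and the all-high configuration is index 2^n - 1.
    """

    n: int
    representation: str = SPIN

    @property
    def size(self) -> int:
        return 1 << self.n

    def to_index(self, config: Configuration) -> int:
        if len(config) != self.n:
            raise ValueError(f"configuration length {len(config)} != n = {self.n}")
        idx = 0
        for bit in config.as_bits():
            idx = (idx << 1) | bit
        return idx

    def to_config(self, index: int) -> Configuration:
        if not 0 <= index < self.size:
            raise ValueError(f"index {index} out of range for n = {self.n}")
        bits = [(index >> (self.n - 1 - i)) & 1 for i in range(self.n)]
        if self.representation == BOOLEAN:
            return Configuration(tuple(bits), BOOLEAN)
        return Configuration(tuple(2 * b - 1 for b in bits), SPIN)

    def all_configs(self) -> Iterable[Configuration]:
        for i in range(self.size):
            yield self.to_config(i)


def state_index_for(net: RegulatoryNetwork) -> StateIndex:
    return StateIndex(net.n, net.rule.representation)


# -- file I/O ---------------------------------------------------------------


def load_network(path: str | Path, format: str | None = None) -> RegulatoryNetwork:
    """Load a network from a TSV edge list or a JSON model file.

    The format is inferred from the extension when not given: ``.json`` is
    a JSON model, anything else a TSV edge list with lines
    ``source<TAB>target<TAB>sign`` (sign in +, -, +1, -1, activate,
    inhibit; '#' starts a comment).  Node order is the explicit node list
    (JSON) or order of first appearance (TSV).
    """
    path = Path(path)
    if format is None:
        format = "json_model" if path.suffix.lower() == ".json" else "tsv_edgelist"
    if format == "json_model":
        with open(path) as fh:
            return RegulatoryNetwork.from_json_dict(json.load(fh))
    if format != "tsv_edgelist":
        raise ValueError(f"unknown format {format!r}")
    nodes: list[str] = []
    edges: list[SignedEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise NetworkFormatError(f"{path}:{lineno}: expected source, target, sign")
            src, tgt, sign_tok = parts[0], parts[1], parts[2]
            tag = parts[3] if len(parts) > 3 else ""
            try:
                sign = _SIGN_TOKENS[sign_tok.strip().lower()]
            except KeyError:
                raise NetworkFormatError(f"{path}:{lineno}: unknown sign token {sign_tok!r}") from None
            for name in (src, tgt):
                if name not in nodes:
                    nodes.append(name)
            edges.append(SignedEdge(src, tgt, sign, tag))
    return RegulatoryNetwork(nodes=tuple(nodes), edges=frozenset(edges))


def save_network(net: RegulatoryNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a network as JSON model or TSV edge list (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "json_model" if path.suffix.lower() == ".json" else "tsv_edgelist"
    if format == "json_model":
        with open(path, "w") as fh:
            json.dump(net.to_json_dict(), fh, indent=1)
            fh.write("\n")
        return
    if format != "tsv_edgelist":
        raise ValueError(f"unknown format {format!r}")
    # lexicographic order makes the TSV canonical (it carries no node list)
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tsign\n")
        for e in sorted(net.edges, key=lambda e: (e.source, e.target)):
            line = f"{e.source}\t{e.target}\t{'+' if e.sign > 0 else '-'}"
            if e.tag:
                line += f"\t{e.tag}"
            fh.write(line + "\n")


# -- the budding-yeast cell-cycle fixture -----------------------------------

# Node order follows the original model's listing; slashes and ampersands in
# protein names are replaced by underscores so the names survive file formats.
YEAST_NODES = (
    "Cln3",
    "MBF",
    "SBF",
    "Cln1_2",
    "Cdh1",
    "Swi5",
    "Cdc20_Cdc14",
    "Clb5_6",
    "Sic1",
    "Clb1_2",
    "Mcm1_SFF",
)

# The 29 cross-regulatory interactions of the 11-node budding-yeast
# cell-cycle network (activations +1, inhibitions -1).
_YEAST_EDGES: tuple[tuple[str, str, int], ...] = (
    ("Cln3", "MBF", 1),
    ("Cln3", "SBF", 1),
    ("SBF", "Cln1_2", 1),
    ("MBF", "Clb5_6", 1),
    ("Cln1_2", "Sic1", -1),
    ("Cln1_2", "Cdh1", -1),
    ("Clb5_6", "Sic1", -1),
    ("Clb5_6", "Cdh1", -1),
    ("Clb5_6", "Mcm1_SFF", 1),
    ("Clb5_6", "Clb1_2", 1),
    ("Sic1", "Clb5_6", -1),
    ("Sic1", "Clb1_2", -1),
    ("Cdh1", "Clb1_2", -1),
    ("Clb1_2", "Cdh1", -1),
    ("Clb1_2", "Sic1", -1),
    ("Clb1_2", "Swi5", -1),
    ("Clb1_2", "MBF", -1),
    ("Clb1_2", "SBF", -1),
    ("Clb1_2", "Mcm1_SFF", 1),
    ("Clb1_2", "Cdc20_Cdc14", 1),
    ("Mcm1_SFF", "Clb1_2", 1),
    ("Mcm1_SFF", "Cdc20_Cdc14", 1),
    ("Mcm1_SFF", "Swi5", 1),
    ("Cdc20_Cdc14", "Swi5", 1),
    ("Cdc20_Cdc14", "Cdh1", 1),
    ("Cdc20_Cdc14", "Sic1", 1),
    ("Swi5", "Sic1", 1),
    ("Cdc20_Cdc14", "Clb5_6", -1),
    ("Cdc20_Cdc14", "Clb1_2", -1),
)

# Self-degradation loops added in the original inertial model to the nodes
# lacking dedicated degradation control.
_YEAST_SELF_LOOPS = ("Cln3", "Cln1_2", "Swi5", "Cdc20_Cdc14", "Mcm1_SFF")

# The two revision edges that make the G1 state absorbing under the
# stochastic majority rule.
_YEAST_REVISION_EDGES: tuple[tuple[str, str, int], ...] = (
    ("Cln1_2", "SBF", 1),
    ("Clb5_6", "MBF", 1),
)

# G1 levels (boolean): only Cdh1 and Sic1 are ON.
YEAST_G1_LEVELS: dict[str, int] = {v: 0 for v in YEAST_NODES}
YEAST_G1_LEVELS["Cdh1"] = 1
YEAST_G1_LEVELS["Sic1"] = 1


def yeast_network(variant: str = "mr_pruned") -> RegulatoryNetwork:
    """The 11-node budding-yeast cell-cycle network.

    Variants
    --------
    ``original_with_selfloops``
        The published wiring including the five self-inhibition
        (self-degradation) loops; rule INMR, as in the original model.
    ``mr_pruned``
        Same wiring minus the self-loops (under the plain majority rule an
        absent regulator already contributes, so the artificial
        self-degradations can be discarded); rule MR.
    ``revised``
        ``mr_pruned`` plus the two activations Cln1_2 -> SBF and
        Clb5_6 -> MBF, which make the G1 state absorbing; rule MR.
    """
    edges = [SignedEdge(s, t, sign) for s, t, sign in _YEAST_EDGES]
    if variant == "original_with_selfloops":
        edges += [SignedEdge(v, v, -1, tag="self_degradation") for v in _YEAST_SELF_LOOPS]
        rule = Rule.INMR
    elif variant == "mr_pruned":
        rule = Rule.MR
    elif variant == "revised":
        edges += [SignedEdge(s, t, sign, tag="revision") for s, t, sign in _YEAST_REVISION_EDGES]
        rule = Rule.MR
    else:
        raise ValueError(f"unknown yeast variant {variant!r}")
    return RegulatoryNetwork(nodes=YEAST_NODES, edges=frozenset(edges), rule=rule)


def yeast_g1(representation: str = SPIN) -> Configuration:
    """The G1 configuration (only Cdh1 and Sic1 ON) of the yeast model."""
    bits = tuple(YEAST_G1_LEVELS[v] for v in YEAST_NODES)
    cfg = Configuration(bits, BOOLEAN)
    return cfg if representation == BOOLEAN else convert_representation(cfg)
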