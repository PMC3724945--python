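"""Semantics of the four majority-rule variants.

Each node is updated from the signed sum of its regulator contributions
(its *module*).  In the spin representation (MR, IMR) a regulator at -1
contributes the opposite of its sign, so absence acts like presence with
inverted effect; in the boolean representation (NMR, INMR) a regulator at
0 contributes nothing.  A strictly positive sum switches the node high, a
strictly negative sum switches it low, and a zero sum (a *tie*) is
resolved at random: toward the high value with probability ``p`` for the
plain variants (MR, NMR), or toward the node's current value with
probability ``p`` for the inertial variants (IMR, INMR).

A node is *deterministic* when its update is deterministic for every
configuration, *probabilistic* otherwise.  Under MR/IMR this is decided by
in-degree parity (odd = deterministic); under the null variants every
unclamped node can tie (all regulators absent), so all are probabilistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping

from .grn_model import (
    BOOLEAN,
    Configuration,
    RegulatoryNetwork,
    Rule,
    SPIN,
)

__all__ = [
    "NodeUpdateDistribution",
    "contribution_sum",
    "next_value_distribution",
    "node_is_probabilistic",
    "probabilistic_nodes",
    "deterministic_nodes",
    "extreme_deterministic_map",
]


@dataclass(frozen=True)
class NodeUpdateDistribution:
    """One node's next-value law: probability of the high value."""

    node: str
    prob_high: Fraction | float

    @property
    def deterministic(self) -> bool:
        return self.prob_high == 0 or self.prob_high == 1

    def prob_of(self, value: int) -> Fraction | float:
        """Probability of a specific next value (spin or boolean level)."""
        high = value in (1,)
        return self.prob_high if high else 1 - self.prob_high


def _check_representation(net: RegulatoryNetwork, config: Configuration) -> None:
    want = net.rule.representation
    if config.representation != want:
        raise ValueError(
            f"rule {net.rule.value} uses the {want} representation, "
            f"got a {config.representation} configuration"
        )
    if len(config) != net.n:
        raise ValueError(f"configuration length {len(config)} != {net.n} nodes")


def contribution_sum(net: RegulatoryNetwork, node: str, config: Configuration) -> int:
    """Signed regulator contribution sum U for ``node`` at ``config``.

    Spin rules sum sign * s_source over incoming edges (s in {-1,+1});
    boolean rules sum sign * S_source (S in {0,1}).  An empty sum is 0,
    i.e. a perpetual tie for an unclamped in-degree-0 node.
    """
    _check_representation(net, config)
    pos = {name: i for i, name in enumerate(net.nodes)}
    if node not in pos:
        raise KeyError(f"unknown node {node!r}")
    return sum(sign * config[pos[src]] for src, sign in net.regulators(node))


def next_value_distribution(
    net: RegulatoryNetwork, node: str, config: Configuration
) -> NodeUpdateDistribution:
    """The next-value law of one node given the current configuration."""
    clamp = net.clamp_value(node)
    if clamp is not None:
        return NodeUpdateDistribution(node, Fraction(1) if clamp == 1 else Fraction(0))
    u = contribution_sum(net, node, config)
    if u > 0:
        return NodeUpdateDistribution(node, Fraction(1))
    if u < 0:
        return NodeUpdateDistribution(node, Fraction(0))
    p = net.tie_probability(node)
    if net.rule.inertial:
        current_high = config[net.nodes.index(node)] == 1
        return NodeUpdateDistribution(node, p if current_high else 1 - p)
    return NodeUpdateDistribution(node, p)


def node_is_probabilistic(net: RegulatoryNetwork, node: str) -> bool:
    """Whether the node's module is probabilistic for some configuration.

    Clamped nodes are deterministic.  Under MR/IMR determinism is
    equivalent to odd in-degree (self-loops included); under NMR/INMR
    every unclamped node ties in the all-absent configuration.
    """
    if node not in net.nodes:
        raise KeyError(f"unknown node {node!r}")
    if node in net.clamped:
        return False
    if net.rule.null:
        return True
    return net.in_degree(node) % 2 == 0


def probabilistic_nodes(net: RegulatoryNetwork) -> tuple[str, ...]:
    return tuple(v for v in net.nodes if node_is_probabilistic(net, v))


def deterministic_nodes(net: RegulatoryNetwork) -> tuple[str, ...]:
    return tuple(v for v in net.nodes if not node_is_probabilistic(net, v))


def extreme_deterministic_map(
    net: RegulatoryNetwork, corner: Mapping[str, int]
) -> Callable[[Configuration], Configuration]:
    """The deterministic successor map at an extreme tie corner.

    ``corner`` assigns each probabilistic node a tie outcome: 1 (ties go
    high; for inertial rules, ties keep the current value) or 0 (ties go
    low / flip the current value).  Resolving every tie to that outcome
    makes the whole system deterministic; the returned function maps a
    configuration to its unique successor.
    """
    for v in probabilistic_nodes(net):
        if v not in corner:
            raise ValueError(f"corner missing tie outcome for probabilistic node {v!r}")
        if corner[v] not in (0, 1):
            raise ValueError(f"tie outcome must be 0 or 1, got {corner[v]!r}")
    low = 0 if net.rule.representation == BOOLEAN else -1

    def step(config: Configuration) -> Configuration:
        _check_representation(net, config)
        out = []
        for i, v in enumerate(net.nodes):
            clamp = net.clamp_value(v)
            if clamp is not None:
                out.append(clamp)
                continue
            u = contribution_sum(net, v, config)
            if u > 0:
                out.append(1)
            elif u < 0:
                out.append(low)
            elif net.rule.inertial:
                cur = config[i]
                out.append(cur if corner[v] == 1 else (low if cur == 1 else 1))
            else:
                out.append(1 if corner[v] == 1 else low)
        return Configuration(tuple(out), config.representation)

    return step
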