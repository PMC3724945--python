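"""The complete atlas of two-node models with doubly-regulated nodes.

A *module* is one node together with its incoming interactions; here each
node carries a self-regulation (sign sigma) and a cross-regulation from
the other node (sign tau), so there are four modules and 16 two-node
models, one per ordered module pair.  Under the majority rule both nodes
are probabilistic (in-degree 2), with tie probabilities p (node 1) and
q (node 2).

The module update tables are related by a rotation ``rho``: listing the
four module configurations in the Gray-cycle order (+,+), (+,-), (-,-),
(-,+), a cyclic shift of the table rows maps each module onto the next,
so the four modules form a single rho-orbit.

The 16 models split into two phases.  *In phase* (IP) models tie both
nodes on the same two configurations: their 4x4 matrix has two fully
probabilistic rows (four entries mixing p and q) and two deterministic
rows, i.e. 10 support transitions.  *Out of phase* (OP) models tie
exactly one node per configuration: every row has two probabilistic
entries, i.e. 8 support transitions.  Up to a renaming of the state
space and a bijective correspondence of the parameters within
{p, 1-p, q, 1-q}, the 8 IP models fall into three isomorphism classes of
sizes (2, 2, 4) -- IP1 (self-activations, symmetric cross), IP2
(self-inhibitions, symmetric cross), IP3 (the asymmetric ones) -- and
likewise OP1, OP2, OP3 for the 8 OP models.

At the four extreme tie corners the dynamics is deterministic and each
node's rule becomes a logical connector (AND/OR over possibly negated
inputs); for intermediate parameters the chain is exactly realised as a
random walk over the four extreme deterministic maps, drawn
independently each step with the product probabilities of the per-node
tie outcomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from .grn_model import (
    Configuration,
    RegulatoryNetwork,
    Rule,
    SignedEdge,
    StateIndex,
)
from .markov_engine import TransitionModel, build_transition_model
from .update_rules import extreme_deterministic_map

__all__ = [
    "ModuleSpec",
    "TwoNodeModel",
    "AtlasClass",
    "MODULES",
    "MODULE_ROW_ORDER",
    "module_table",
    "rho_rotate",
    "enumerate_models",
    "phase_of",
    "isomorphic",
    "atlas_classes",
    "logic_corner_table",
    "RandomMapSampler",
    "random_map_sampler",
]

NODE_1 = "g1"
NODE_2 = "g2"

# Module configurations (self value, cross-regulator value) in the Gray-cycle
# order under which the rho rotation is literally a row shift.
MODULE_ROW_ORDER: tuple[tuple[int, int], ...] = ((1, 1), (1, -1), (-1, -1), (-1, 1))

TIE = "tie"


@dataclass(frozen=True)
class ModuleSpec:
    """A doubly-regulated module: self sign sigma, cross sign tau."""

    self_sign: int
    cross_sign: int

    def __post_init__(self) -> None:
        if self.self_sign not in (1, -1) or self.cross_sign not in (1, -1):
            raise ValueError("module signs must be +1 or -1")

    def symbol(self) -> str:
        s = "+" if self.self_sign > 0 else "-"
        c = "+" if self.cross_sign > 0 else "-"
        return f"({s}{c})"


MODULES: tuple[ModuleSpec, ...] = (
    ModuleSpec(1, 1),
    ModuleSpec(1, -1),
    ModuleSpec(-1, -1),
    ModuleSpec(-1, 1),
)


def module_table(m: ModuleSpec) -> tuple[object, ...]:
    """The module's majority-rule outputs over MODULE_ROW_ORDER.

    Entries are +1, -1 or ``"tie"`` (the probabilistic choice).
    """
    out = []
    for s, c in MODULE_ROW_ORDER:
        u = m.self_sign * s + m.cross_sign * c
        out.append(TIE if u == 0 else (1 if u > 0 else -1))
    return tuple(out)


def rho_rotate(m: ModuleSpec) -> ModuleSpec:
    """The rotation relating the four modules: a row shift of the table.

    In the Gray-cycle row order, shifting every table row down by one
    (modulo 4) turns the table of ``m`` into the table of ``rho(m)``;
    applying rho four times is the identity and the four modules form a
    single orbit.
    """
    if m.self_sign * m.cross_sign > 0:
        return ModuleSpec(m.self_sign, -m.cross_sign)
    return ModuleSpec(-m.self_sign, m.cross_sign)


@dataclass(frozen=True)
class TwoNodeModel:
    """Composition of two modules: node 1 under module_1, node 2 under module_2.

    Node 1's cross input is node 2 and vice versa; p and q are the tie
    probabilities of nodes 1 and 2.
    """

    module_1: ModuleSpec
    module_2: ModuleSpec
    rule: Rule = Rule.MR

    def symbol(self) -> str:
        return f"{self.module_1.symbol()}(+){self.module_2.symbol()}"

    def network(
        self,
        p: Fraction | float = Fraction(1, 2),
        q: Fraction | float = Fraction(1, 2),
    ) -> RegulatoryNetwork:
        edges = frozenset(
            {
                SignedEdge(NODE_1, NODE_1, self.module_1.self_sign),
                SignedEdge(NODE_2, NODE_1, self.module_1.cross_sign),
                SignedEdge(NODE_2, NODE_2, self.module_2.self_sign),
                SignedEdge(NODE_1, NODE_2, self.module_2.cross_sign),
            }
        )
        return RegulatoryNetwork(
            nodes=(NODE_1, NODE_2),
            edges=edges,
            rule=self.rule,
            tie_prob={NODE_1: p, NODE_2: q},
        )

    def transition_model(
        self,
        p: Fraction | float = Fraction(1, 2),
        q: Fraction | float = Fraction(1, 2),
    ) -> TransitionModel:
        return build_transition_model(self.network(p, q))


def enumerate_models(rule: Rule | str = Rule.MR) -> tuple[TwoNodeModel, ...]:
    """All 16 ordered module compositions under the given rule."""
    rule = Rule(rule)
    return tuple(
        TwoNodeModel(m1, m2, rule) for m1, m2 in itertools.product(MODULES, MODULES)
    )


# generic, distinct rational parameters strictly inside (0, 1)
GENERIC_P = Fraction(1, 3)
GENERIC_Q = Fraction(2, 7)


def _row_pattern(tm: TransitionModel) -> tuple[int, ...]:
    return tuple(sorted(len(row) for row in tm.rows))


def phase_of(model: TwoNodeModel) -> str:
    """``"IP"`` or ``"OP"`` by the operational row-pattern test.

    IP: two rows with four probabilistic entries and two rows with a
    single deterministic entry (10 transitions); OP: two probabilistic
    entries in every row (8 transitions).
    """
    tm = model.transition_model(GENERIC_P, GENERIC_Q)
    pattern = _row_pattern(tm)
    if pattern == (1, 1, 4, 4):
        return "IP"
    if pattern == (2, 2, 2, 2):
        return "OP"
    raise AssertionError(
        f"model {model.symbol()} fits neither the IP nor the OP row pattern: {pattern}"
    )


# The 8 injective parameter correspondences mapping (p, q) into {p, 1-p, q, 1-q}.
def _substitutions():
    subs = []
    for swap in (False, True):
        for flip_a in (False, True):
            for flip_b in (False, True):
                def f(p, q, swap=swap, fa=flip_a, fb=flip_b):
                    a, b = (q, p) if swap else (p, q)
                    return (1 - a if fa else a, 1 - b if fb else b)

                name_a = ("1-" if flip_a else "") + ("q" if swap else "p")
                name_b = ("1-" if flip_b else "") + ("p" if swap else "q")
                subs.append(((name_a, name_b), f))
    return tuple(subs)


PARAMETER_SUBSTITUTIONS = _substitutions()

# Matrix entries are polynomials of degree <= 1 in each of p and q, so exact
# agreement at three generic points implies identity.
_TEST_POINTS = (
    (Fraction(1, 3), Fraction(2, 7)),
    (Fraction(2, 5), Fraction(3, 7)),
    (Fraction(1, 7), Fraction(5, 11)),
)

_matrix_cache: dict = {}


def _matrix_at(model: TwoNodeModel, p: Fraction, q: Fraction):
    key = (model, p, q)
    if key not in _matrix_cache:
        tm = model.transition_model(p, q)
        _matrix_cache[key] = tuple(
            tuple(tm.rows[i].get(j, Fraction(0)) for j in range(4)) for i in range(4)
        )
    return _matrix_cache[key]


def isomorphic(a: TwoNodeModel, b: TwoNodeModel):
    """Equivalence up to state renaming and parameter correspondence.

    Searches the 24 state permutations combined with the 8 injective
    substitutions of (p, q) into {p, 1-p, q, 1-q}; equality of the two
    4x4 matrices is checked exactly at three generic rational parameter
    points, which suffices because every entry is multilinear in (p, q).

    Returns ``(True, witness)`` with ``witness = (permutation, (name_p,
    name_q))`` on success, else ``(False, None)``.
    """
    for perm in itertools.permutations(range(4)):
        for names, sub in PARAMETER_SUBSTITUTIONS:
            ok = True
            for p0, q0 in _TEST_POINTS:
                ma = _matrix_at(a, p0, q0)
                pb, qb = sub(p0, q0)
                mb = _matrix_at(b, pb, qb)
                if any(
                    ma[i][j] != mb[perm[i]][perm[j]]
                    for i in range(4)
                    for j in range(4)
                ):
                    ok = False
                    break
            if ok:
                return True, (perm, names)
    return False, None


@dataclass(frozen=True)
class AtlasClass:
    """An isomorphism class of two-node models."""

    label: str
    members: tuple[TwoNodeModel, ...]
    witnesses: Mapping[TwoNodeModel, object] = field(default_factory=dict)


def _structural_label(model: TwoNodeModel, phase: str) -> str:
    """Class label from the self-sign pattern within each phase family.

    1: both self-activations; 2: both self-inhibitions; 3: asymmetric.
    """
    s1, s2 = model.module_1.self_sign, model.module_2.self_sign
    if s1 == s2 == 1:
        return f"{phase}1"
    if s1 == s2 == -1:
        return f"{phase}2"
    return f"{phase}3"


def atlas_classes(rule: Rule | str = Rule.MR) -> tuple[AtlasClass, ...]:
    """Partition the 16 models into isomorphism classes.

    For MR and IMR the classes carry the structural labels IP1-3/OP1-3
    (consistency between the structural label and the computed partition
    is asserted).  For the null variants the same engine is used and the
    classes are labelled descriptively (C1, C2, ...).
    """
    rule = Rule(rule)
    models = enumerate_models(rule)
    # union-find by pairwise isomorphism
    parent = {m: m for m in models}

    def find(m):
        while parent[m] is not m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    witnesses: dict[TwoNodeModel, object] = {}
    for a, b in itertools.combinations(models, 2):
        if find(a) is find(b):
            continue
        ok, wit = isomorphic(a, b)
        if ok:
            parent[find(b)] = find(a)
            witnesses[b] = (a, wit)
    groups: dict[TwoNodeModel, list[TwoNodeModel]] = {}
    for m in models:
        groups.setdefault(find(m), []).append(m)

    classes = []
    if rule in (Rule.MR, Rule.IMR):
        for root, members in groups.items():
            labels = {_structural_label(m, phase_of(TwoNodeModel(m.module_1, m.module_2, Rule.MR))) for m in members}
            if len(labels) != 1:
                raise AssertionError(
                    f"isomorphism class mixes structural labels: {sorted(labels)}"
                )
            classes.append(AtlasClass(labels.pop(), tuple(members),
                                      {m: witnesses[m] for m in members if m in witnesses}))
        classes.sort(key=lambda c: c.label)
    else:
        groups_sorted = sorted(groups.values(), key=lambda ms: (-len(ms), ms[0].symbol()))
        for k, members in enumerate(groups_sorted, 1):
            classes.append(AtlasClass(f"C{k}", tuple(members),
                                      {m: witnesses[m] for m in members if m in witnesses}))
    return tuple(classes)


def convergence_census(
    rule: Rule | str = Rule.MR,
    p: Fraction | float = GENERIC_P,
    q: Fraction | float = GENERIC_Q,
) -> dict[str, int]:
    """Asymptotic-behaviour census of the 16 models at generic parameters.

    Returns counts over the 16 models:

    * ``absorbing_extended`` -- every ergodic set is deterministic (a
      fixed point or a deterministic cycle);
    * ``small_attractor`` -- every ergodic set is a proper subset of the
      four states, i.e. the dynamics converges to a fixed point or a
      small (possibly stochastic) cycle rather than wandering the whole
      space; this is the superset of the absorbing models;
    * ``regular`` -- a single aperiodic ergodic set covers the space;
    * ``mixed`` -- anything else.

    Under the null majority rule the small-attractor count (11 of 16)
    exceeds the strict absorbing count (9): two models converge to a
    two-state attractor in which one node fluctuates stochastically.
    """
    from .markov_engine import classify_chain, ergodic_sets

    census = {"absorbing_extended": 0, "small_attractor": 0, "regular": 0, "mixed": 0}
    for model in enumerate_models(rule):
        tm = model.transition_model(p, q)
        cls = classify_chain(tm)
        census[cls] += 1
        if all(len(e.states) < tm.size for e in ergodic_sets(tm)):
            census["small_attractor"] += 1
    return census


# -- extreme corners and logical connectors ---------------------------------


def _truth_table(fn: Callable[[int, int], int]) -> tuple[int, ...]:
    return tuple(fn(s, c) for s in (1, -1) for c in (1, -1))


def logic_corner_table(model: TwoNodeModel) -> dict:
    """Logical connectors of both nodes at each extreme tie corner.

    The corner is a pair (tie outcome node 1, tie outcome node 2) with 1
    meaning ties resolve high and 0 low.  Each node's deterministic rule
    is identified by truth-table match as an AND or OR over its two
    (possibly negated) input literals; with positive cross signs these
    are the plain AND/OR of the class descriptions.
    """
    net = model.network()
    out: dict[tuple[int, int], tuple[str, str]] = {}
    for t1 in (0, 1):
        for t2 in (0, 1):
            step = extreme_deterministic_map(net, {NODE_1: t1, NODE_2: t2})
            connectors = []
            for node_pos, (sigma, tau) in enumerate(
                (
                    (model.module_1.self_sign, model.module_1.cross_sign),
                    (model.module_2.self_sign, model.module_2.cross_sign),
                )
            ):
                def update(s, c, node_pos=node_pos):
                    cfg = [0, 0]
                    cfg[node_pos] = s
                    cfg[1 - node_pos] = c
                    return step(Configuration(tuple(cfg), "spin"))[node_pos]

                table = _truth_table(update)
                lit_and = _truth_table(
                    lambda s, c: 1 if (sigma * s > 0 and tau * c > 0) else -1
                )
                lit_or = _truth_table(
                    lambda s, c: 1 if (sigma * s > 0 or tau * c > 0) else -1
                )
                if table == lit_and:
                    connectors.append("AND")
                elif table == lit_or:
                    connectors.append("OR")
                else:  # cannot occur for doubly-regulated majority modules
                    connectors.append("?")
            out[(t1, t2)] = tuple(connectors)
    return out


# -- random-map realisation --------------------------------------------------


class RandomMapSampler:
    """Random walk over the four extreme deterministic maps.

    At every step one of the corner maps is drawn independently with the
    product probability of the per-node tie outcomes (high with p for
    node 1, q for node 2) and its unique transition is applied.  The
    induced one-step law coincides exactly with the model's transition
    matrix row.
    """

    def __init__(
        self,
        model: TwoNodeModel,
        p: Fraction | float = Fraction(1, 2),
        q: Fraction | float = Fraction(1, 2),
        seed: int | None = None,
    ):
        self.model = model
        self.net = model.network(p, q)
        self.p = p
        self.q = q
        self.rng = np.random.default_rng(seed)
        self.corners = [(t1, t2) for t1 in (1, 0) for t2 in (1, 0)]
        self.maps = {
            corner: extreme_deterministic_map(self.net, {NODE_1: corner[0], NODE_2: corner[1]})
            for corner in self.corners
        }

    def corner_probability(self, corner: tuple[int, int]) -> Fraction | float:
        t1, t2 = corner
        pp = self.p if t1 == 1 else 1 - self.p
        qq = self.q if t2 == 1 else 1 - self.q
        return pp * qq

    def draw_corner(self) -> tuple[int, int]:
        u = self.rng.random()
        acc = 0.0
        for corner in self.corners:
            acc += float(self.corner_probability(corner))
            if u < acc:
                return corner
        return self.corners[-1]

    def step(self, config: Configuration) -> Configuration:
        return self.maps[self.draw_corner()](config)

    def sample_path(self, init: Configuration, steps: int) -> list[Configuration]:
        path = [init]
        for _ in range(steps):
            path.append(self.step(path[-1]))
        return path


def random_map_sampler(
    model: TwoNodeModel,
    p: Fraction | float = Fraction(1, 2),
    q: Fraction | float = Fraction(1, 2),
    seed: int | None = None,
) -> RandomMapSampler:
    return RandomMapSampler(model, p, q, seed)
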