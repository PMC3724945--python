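"""Exact Markov-chain analytics on the configuration space.

A network with at least one probabilistic node defines a finite Markov
chain on its 2^n configurations: under the synchronous update, the
probability of moving from x to y is the product over nodes of the
probability that node i takes value y_i given x (tie resolutions are
independent across nodes).

Attractors are the minimal ergodic sets of this chain, i.e. the terminal
strongly connected components of the transition diagram.  Extending the
usual notion, the chain is *absorbing* when every ergodic set is
deterministic -- a fixed point or a deterministic cycle; it is *regular*
when a single aperiodic ergodic set covers the whole space.  For
absorbing chains the fundamental matrix N = (I - Q)^{-1} over the
transient states gives expected sojourn times, and B = N R the absorption
probabilities; for regular chains the stationary vector pi gives the mean
return times m_i = 1/pi_i.

Entries are exact rationals whenever all tie probabilities are rational;
linear algebra then runs through sympy so results like N (I - Q) = I hold
exactly.  Large or float-valued models fall back to numpy/scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import sympy

from .grn_model import (
    Configuration,
    RegulatoryNetwork,
    StateIndex,
    state_index_for,
)
from .update_rules import next_value_distribution

__all__ = [
    "TransitionModel",
    "ErgodicSet",
    "ChainAnalysis",
    "build_transition_model",
    "support_digraph",
    "ergodic_sets",
    "classify_chain",
    "transient_states",
    "fundamental_matrix",
    "absorption_probabilities",
    "stationary_and_return_times",
    "analyse_chain",
    "write_matrix_csv",
    "write_matrix_triplets",
    "write_dot",
]

# Exact (sympy) linear algebra is used up to this many transient/recurrent
# states; beyond it the engine falls back to floating point.
EXACT_SIZE_LIMIT = 64


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition matrix of a network's synchronous chain.

    ``rows[i]`` maps successor state index -> probability (Fraction when
    all tie probabilities are rational).  ``state_nodes`` lists the nodes
    spanned by the state space: clamped nodes may be collapsed out, in
    which case they act as constant inputs and the chain lives on the
    2^(n-c) free-node configurations.
    """

    net: RegulatoryNetwork
    state_nodes: tuple[str, ...]
    index: StateIndex
    rows: tuple[Mapping[int, Fraction | float], ...]

    @property
    def n(self) -> int:
        return len(self.state_nodes)

    @property
    def size(self) -> int:
        return self.index.size

    @property
    def exact(self) -> bool:
        return all(
            isinstance(p, (Fraction, int)) for row in self.rows for p in row.values()
        )

    def probability(self, i: int, j: int) -> Fraction | float:
        return self.rows[i].get(j, Fraction(0))

    def state_label(self, i: int) -> str:
        return self.index.to_config(i).to_string()

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.size, self.size))
        for i, row in enumerate(self.rows):
            for j, p in row.items():
                m[i, j] = float(p)
        return m

    def to_sympy(self) -> sympy.Matrix:
        m = sympy.zeros(self.size, self.size)
        for i, row in enumerate(self.rows):
            for j, p in row.items():
                m[i, j] = _to_rational(p)
        return m


def _to_rational(p) -> sympy.Expr:
    if isinstance(p, Fraction):
        return sympy.Rational(p.numerator, p.denominator)
    if isinstance(p, int):
        return sympy.Integer(p)
    return sympy.Float(p)


def build_transition_model(
    net: RegulatoryNetwork, collapse_clamped: bool = False
) -> TransitionModel:
    """Construct the synchronous-update transition matrix.

    Entry (x -> y) is the product over nodes of the probability that the
    node moves to y's value given x; tie resolutions are independent.  A
    clamped node transitions to its clamp with probability one; with
    ``collapse_clamped`` clamped nodes are removed from the state space
    altogether (they still feed their fixed value into the sums), giving
    the reduced 2^(n-c) chain.
    """
    rep = net.rule.representation
    low = 0 if rep == "boolean" else -1
    if collapse_clamped:
        state_nodes = tuple(v for v in net.nodes if v not in net.clamped)
    else:
        state_nodes = net.nodes
    pos = {v: i for i, v in enumerate(state_nodes)}
    index = StateIndex(len(state_nodes), rep)

    def full_config(state: Configuration) -> Configuration:
        if len(state_nodes) == net.n:
            return state
        vals = []
        for v in net.nodes:
            if v in pos:
                vals.append(state[pos[v]])
            else:
                vals.append(net.clamp_value(v))
        return Configuration(tuple(vals), rep)

    rows: list[dict[int, Fraction | float]] = []
    for i in range(index.size):
        state = index.to_config(i)
        cfg = full_config(state)
        dists = [next_value_distribution(net, v, cfg) for v in state_nodes]
        # deterministic bits are fixed; branch only over genuinely random nodes
        base_bits = [0] * len(state_nodes)
        random_positions: list[int] = []
        for k, d in enumerate(dists):
            if d.prob_high == 1:
                base_bits[k] = 1
            elif d.prob_high == 0:
                base_bits[k] = 0
            else:
                random_positions.append(k)
        row: dict[int, Fraction | float] = {}
        for mask in range(1 << len(random_positions)):
            bits = list(base_bits)
            prob: Fraction | float = Fraction(1)
            for b, k in enumerate(random_positions):
                high = (mask >> b) & 1
                bits[k] = high
                prob = prob * (dists[k].prob_high if high else 1 - dists[k].prob_high)
            j = 0
            for bit in bits:
                j = (j << 1) | bit
            row[j] = row.get(j, Fraction(0)) + prob
        rows.append(row)
    return TransitionModel(net=net, state_nodes=state_nodes, index=index, rows=tuple(rows))


def support_digraph(tm: TransitionModel, generic: bool = False) -> nx.DiGraph:
    """Directed graph of structurally positive transitions.

    With ``generic=True`` the caller asserts that every tie probability
    lies strictly inside (0, 1), so the support is parameter independent;
    an extreme tie probability then raises instead of silently deleting
    arcs.
    """
    if generic:
        for v in tm.net.nodes:
            if v in tm.net.clamped:
                continue
            p = tm.net.tie_probability(v)
            if not 0 < p < 1:
                raise ValueError(
                    f"generic support requires tie probabilities in (0,1); "
                    f"node {v!r} has {p}"
                )
    g = nx.DiGraph()
    g.add_nodes_from(range(tm.size))
    for i, row in enumerate(tm.rows):
        for j, p in row.items():
            if p != 0:
                g.add_edge(i, j, probability=p)
    return g


@dataclass(frozen=True)
class ErgodicSet:
    """A terminal SCC of the transition diagram (an attractor)."""

    states: frozenset[int]
    kind: str  # "fixed_point" | "deterministic_cycle" | "stochastic"
    period: int | None = None  # cycle length for deterministic cycles

    @property
    def deterministic(self) -> bool:
        return self.kind in ("fixed_point", "deterministic_cycle")


def ergodic_sets(tm: TransitionModel) -> list[ErgodicSet]:
    """Attractors: terminal SCCs, labelled by their internal dynamics."""
    g = support_digraph(tm)
    cond = nx.condensation(g)
    out: list[ErgodicSet] = []
    for comp in cond.nodes:
        if cond.out_degree(comp) != 0:
            continue
        states = frozenset(cond.nodes[comp]["members"])
        if len(states) == 1:
            (s,) = states
            out.append(ErgodicSet(states, "fixed_point"))
            continue
        # deterministic cycle: every member has a single successor
        if all(len(tm.rows[s]) == 1 for s in states):
            out.append(ErgodicSet(states, "deterministic_cycle", period=len(states)))
        else:
            out.append(ErgodicSet(states, "stochastic"))
    out.sort(key=lambda e: min(e.states))
    return out


def transient_states(tm: TransitionModel) -> list[int]:
    recurrent = {s for e in ergodic_sets(tm) for s in e.states}
    return [i for i in range(tm.size) if i not in recurrent]


def classify_chain(tm: TransitionModel) -> str:
    """Classify as ``absorbing_extended``, ``regular`` or ``mixed``.

    The chain is absorbing in the extended sense when every ergodic set
    is deterministic (fixed point or deterministic cycle); regular when a
    single ergodic set covers the whole space and is aperiodic.
    """
    sets_ = ergodic_sets(tm)
    if all(e.deterministic for e in sets_):
        return "absorbing_extended"
    if len(sets_) == 1 and len(sets_[0].states) == tm.size:
        if nx.is_aperiodic(support_digraph(tm)):
            return "regular"
    return "mixed"


def _power_rows(tm: TransitionModel, k: int) -> tuple[Mapping[int, Fraction | float], ...]:
    """Rows of T^k in the same sparse form."""
    rows = tm.rows
    if k == 1:
        return rows
    out = rows
    for _ in range(k - 1):
        nxt: list[dict[int, Fraction | float]] = []
        for row in out:
            acc: dict[int, Fraction | float] = {}
            for m, pm in row.items():
                for j, pj in rows[m].items():
                    acc[j] = acc.get(j, Fraction(0)) + pm * pj
            nxt.append(acc)
        out = tuple(nxt)
    return out


def _cycle_lcm(sets_: Sequence[ErgodicSet]) -> int:
    k = 1
    for e in sets_:
        if e.kind == "deterministic_cycle":
            k = math.lcm(k, e.period)
    return k


def fundamental_matrix(tm: TransitionModel):
    """Fundamental matrix N over the transient states of an absorbing chain.

    N = (I - Q)^{-1} with Q the transient-state restriction of T.  When
    ergodic sets include deterministic cycles (period lcm k > 1), Q is
    taken from T^k, whose absorbing states are the classical ones; the
    resulting visit counts are per k-step block and are converted to
    per-step counts by multiplying by k.

    Returns ``(N, transients)`` where N is a sympy Matrix (exact entries
    when the model is rational and small) or a numpy array, and
    ``transients`` is the ordered list of transient state indices.
    """
    sets_ = ergodic_sets(tm)
    if not all(e.deterministic for e in sets_):
        raise ValueError("fundamental matrix requires an absorbing (extended) chain")
    trans = transient_states(tm)
    k = _cycle_lcm(sets_)
    rows = _power_rows(tm, k)
    tpos = {s: r for r, s in enumerate(trans)}
    nt = len(trans)
    if tm.exact and nt <= EXACT_SIZE_LIMIT:
        q = sympy.zeros(nt, nt)
        for s in trans:
            for j, p in rows[s].items():
                if j in tpos:
                    q[tpos[s], tpos[j]] = _to_rational(p)
        n_mat = (sympy.eye(nt) - q).inv()
        if k > 1:
            n_mat = n_mat * k
        return n_mat, trans
    q = np.zeros((nt, nt))
    for s in trans:
        for j, p in rows[s].items():
            if j in tpos:
                q[tpos[s], tpos[j]] = float(p)
    n_mat = np.linalg.inv(np.eye(nt) - q)
    if k > 1:
        n_mat = n_mat * k
    return n_mat, trans


def absorption_probabilities(tm: TransitionModel):
    """Absorption split B over ergodic sets: B = N R, rows summing to one.

    Returns ``(B, transients, sets)``; B[r, c] is the probability that the
    chain started at ``transients[r]`` is absorbed by ``sets[c]``.
    Deterministic-cycle sets are handled through the same T^k construction
    as the fundamental matrix (absorption events are identical under T and
    T^k because ergodic sets are closed).
    """
    sets_ = ergodic_sets(tm)
    if not all(e.deterministic for e in sets_):
        raise ValueError("absorption probabilities require an absorbing (extended) chain")
    trans = transient_states(tm)
    k = _cycle_lcm(sets_)
    rows = _power_rows(tm, k)
    tpos = {s: r for r, s in enumerate(trans)}
    set_of = {s: c for c, e in enumerate(sets_) for s in e.states}
    nt, ns = len(trans), len(sets_)
    if tm.exact and nt <= EXACT_SIZE_LIMIT:
        q = sympy.zeros(nt, nt)
        r = sympy.zeros(nt, ns)
        for s in trans:
            for j, p in rows[s].items():
                if j in tpos:
                    q[tpos[s], tpos[j]] += _to_rational(p)
                else:
                    r[tpos[s], set_of[j]] += _to_rational(p)
        b = (sympy.eye(nt) - q).inv() * r
        return b, trans, sets_
    q = np.zeros((nt, nt))
    r = np.zeros((nt, ns))
    for s in trans:
        for j, p in rows[s].items():
            if j in tpos:
                q[tpos[s], tpos[j]] += float(p)
            else:
                r[tpos[s], set_of[j]] += float(p)
    b = np.linalg.solve(np.eye(nt) - q, r)
    return b, trans, sets_


def _stationary_of_block(tm: TransitionModel, states: Sequence[int]):
    """Stationary vector of the chain restricted to a closed state set."""
    states = list(states)
    pos = {s: r for r, s in enumerate(states)}
    m = len(states)
    if tm.exact and m <= EXACT_SIZE_LIMIT:
        a = sympy.zeros(m, m)
        for s in states:
            for j, p in tm.rows[s].items():
                a[pos[j], pos[s]] += _to_rational(p)  # columns are sources: A = T^t
        null = (a - sympy.eye(m)).nullspace()
        if len(null) != 1:
            raise ValueError("stationary distribution is not unique on this set")
        v = null[0]
        total = sum(v)
        return {s: sympy.nsimplify(v[pos[s]] / total) for s in states}
    a = np.zeros((m, m))
    for s in states:
        for j, p in tm.rows[s].items():
            a[pos[j], pos[s]] += float(p)
    # replace last balance equation by normalisation
    sys = a - np.eye(m)
    sys[-1, :] = 1.0
    rhs = np.zeros(m)
    rhs[-1] = 1.0
    v = np.linalg.solve(sys, rhs)
    return {s: float(v[pos[s]]) for s in states}


def stationary_and_return_times(tm: TransitionModel, per_set: bool = False):
    """Stationary vector(s) pi and mean return times m_i = 1/pi_i.

    For a regular chain (default) pi spans the whole space.  With
    ``per_set`` the quantities are computed separately on each ergodic
    set (states outside every ergodic set get no entry).
    """
    if per_set:
        pi: dict[int, object] = {}
        for e in ergodic_sets(tm):
            pi.update(_stationary_of_block(tm, sorted(e.states)))
    else:
        if classify_chain(tm) != "regular":
            raise ValueError(
                "chain is not regular; pass per_set=True for per-attractor analysis"
            )
        pi = _stationary_of_block(tm, range(tm.size))
    mean_return = {s: (1 / p if p != 0 else math.inf) for s, p in pi.items()}
    return pi, mean_return


@dataclass(frozen=True)
class ChainAnalysis:
    """Bundle of the chain-level quantities for reporting."""

    classification: str
    ergodic: tuple[ErgodicSet, ...]
    transients: tuple[int, ...]
    fundamental: object | None
    stationary: Mapping[int, object]
    mean_return: Mapping[int, object]


def analyse_chain(tm: TransitionModel) -> ChainAnalysis:
    """Run the full pipeline: classification, attractors, N, pi, m."""
    cls = classify_chain(tm)
    sets_ = tuple(ergodic_sets(tm))
    trans = tuple(transient_states(tm))
    n_mat = None
    if cls == "absorbing_extended" and trans:
        n_mat, _ = fundamental_matrix(tm)
    pi, mret = stationary_and_return_times(tm, per_set=(cls != "regular"))
    return ChainAnalysis(cls, sets_, trans, n_mat, pi, mret)


# -- exports ----------------------------------------------------------------


def _fmt(p) -> str:
    if isinstance(p, Fraction):
        return str(p)
    return repr(float(p))


def write_matrix_csv(tm: TransitionModel, path: str | Path) -> None:
    """Dense CSV with state labels as header row/column."""
    labels = [tm.state_label(i) for i in range(tm.size)]
    with open(path, "w") as fh:
        fh.write("state," + ",".join(labels) + "\n")
        for i in range(tm.size):
            cells = [_fmt(tm.rows[i].get(j, 0)) if j in tm.rows[i] else "0" for j in range(tm.size)]
            fh.write(labels[i] + "," + ",".join(cells) + "\n")


def write_matrix_triplets(tm: TransitionModel, path: str | Path) -> None:
    """Sparse triplet text: row_state, col_state, probability."""
    with open(path, "w") as fh:
        fh.write("# row_state\tcol_state\tprobability\n")
        for i in range(tm.size):
            for j in sorted(tm.rows[i]):
                fh.write(f"{tm.state_label(i)}\t{tm.state_label(j)}\t{_fmt(tm.rows[i][j])}\n")


def write_dot(tm: TransitionModel, path: str | Path) -> None:
    """DOT digraph of the support, probabilities as edge labels."""
    with open(path, "w") as fh:
        fh.write("digraph chain {\n")
        for i in range(tm.size):
            fh.write(f'  s{i} [label="{tm.state_label(i)}"];\n')
        for i in range(tm.size):
            for j in sorted(tm.rows[i]):
                p = tm.rows[i][j]
                if p != 0:
                    fh.write(f'  s{i} -> s{j} [label="{_fmt(p)}"];\n')
        fh.write("}\n")
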