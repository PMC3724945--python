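"""Seeded stochastic trajectory sampling and empirical estimators.

The simulator realises exactly the chain the analytics describe: at each
synchronous step every node's next value is drawn independently from its
next-value distribution.  One NumPy ``default_rng`` (PCG64) stream is
used per trajectory and node draws happen in network node order, so
trajectories are bit-reproducible for a given seed.

Estimators report a mean with its standard error; runs that exceed the
horizon before the event of interest (return, absorption) are counted as
censored, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grn_model import Configuration, RegulatoryNetwork, state_index_for
from .markov_engine import TransitionModel, build_transition_model, ergodic_sets
from .update_rules import next_value_distribution

__all__ = [
    "Trajectory",
    "sample_trajectory",
    "estimate_return_times",
    "estimate_absorption",
    "Estimate",
]


@dataclass(frozen=True)
class Trajectory:
    """A sampled path: ``states[0]`` is the initial configuration."""

    states: tuple[Configuration, ...]
    seed: int | None
    rule: str

    @property
    def initial(self) -> Configuration:
        return self.states[0]

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Estimate:
    """An empirical mean with standard error and censoring count."""

    mean: float
    stderr: float
    n: int
    n_censored: int = 0


def _step(net: RegulatoryNetwork, config: Configuration, rng: np.random.Generator) -> Configuration:
    low = -1 if config.representation == "spin" else 0
    out = []
    for v in net.nodes:
        ph = float(next_value_distribution(net, v, config).prob_high)
        if ph == 1.0:
            out.append(1)
        elif ph == 0.0:
            out.append(low)
        else:
            out.append(1 if rng.random() < ph else low)
    return Configuration(tuple(out), config.representation)


def sample_trajectory(
    net: RegulatoryNetwork,
    init: Configuration,
    steps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Sample a synchronous trajectory of the given length."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    states = [init]
    for _ in range(steps):
        states.append(_step(net, states[-1], rng))
    return Trajectory(tuple(states), seed, net.rule.value)


def _mean_stderr(samples: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def estimate_return_times(
    net: RegulatoryNetwork,
    state: Configuration,
    n_runs: int,
    horizon: int = 10_000,
    seed: int | None = None,
) -> Estimate:
    """Empirical mean first-return time to ``state``.

    For a regular chain this estimates m_i = 1/pi_i.  Runs not returning
    within the horizon are censored.
    """
    rng = np.random.default_rng(seed)
    times: list[float] = []
    censored = 0
    for _ in range(n_runs):
        cfg = state
        for t in range(1, horizon + 1):
            cfg = _step(net, cfg, rng)
            if cfg.values == state.values:
                times.append(t)
                break
        else:
            censored += 1
    mean, stderr = _mean_stderr(times)
    return Estimate(mean, stderr, len(times), censored)


def estimate_absorption(
    net: RegulatoryNetwork,
    init: Configuration,
    n_runs: int,
    horizon: int = 10_000,
    seed: int | None = None,
    tm: TransitionModel | None = None,
):
    """Empirical absorption frequencies and mean absorption time.

    The attractors are taken from the exact engine; a run is absorbed
    when it first enters any ergodic set.  Returns ``(frequencies,
    time_estimate, sets)`` where ``frequencies[c]`` is the fraction of
    uncensored runs absorbed by set ``c``.
    """
    if tm is None:
        tm = build_transition_model(net)
    sets_ = ergodic_sets(tm)
    idx = tm.index
    set_of: dict[int, int] = {s: c for c, e in enumerate(sets_) for s in e.states}
    state_nodes = tm.state_nodes
    pos = [net.nodes.index(v) for v in state_nodes]

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(sets_), dtype=int)
    times: list[float] = []
    censored = 0
    for _ in range(n_runs):
        cfg = init
        absorbed = None
        for t in range(0, horizon + 1):
            i = idx.to_index(Configuration(tuple(cfg[k] for k in pos), cfg.representation))
            if i in set_of:
                absorbed = set_of[i]
                times.append(t)
                break
            cfg = _step(net, cfg, rng)
        if absorbed is None:
            censored += 1
        else:
            counts[absorbed] += 1
    total = counts.sum()
    freqs = counts / total if total else counts.astype(float)
    mean, stderr = _mean_stderr(times)
    return freqs, Estimate(mean, stderr, len(times), censored), sets_
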