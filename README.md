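# majorules

Stochastic threshold Boolean gene regulatory networks with majority-rule
updates and random tie-breaking: exact Markov-chain analytics, the
complete two-node model atlas, and steady-state search with
edge-addition repair, demonstrated on the budding-yeast cell-cycle
network.

## The problem

A Boolean gene regulatory network (GRN) is a signed directed graph:
nodes are genes, a positive edge `j -> i` is an activation
(`a_ij = +1`), a negative edge a repression (`a_ij = -1`).  Under the
**majority rule (MR)**, gene `i` is switched ON at the next synchronous
step when the signed sum of its regulator contributions

    U_i(t) = sum_j a_ij * s_j(t),      s_j in {-1, +1}

is positive, and OFF when it is negative.  The interesting case is the
**tie** `U_i = 0`: instead of fixing an arbitrary outcome, the next
value is drawn ON with probability `p_i` and OFF with `1 - p_i`.  Nodes
with odd in-degree can never tie (they are *deterministic*); nodes with
even in-degree are *probabilistic*.  The resulting dynamics is a finite
Markov chain on the `2^n` configurations that mixes deterministic and
random transitions — enough structure for exact analysis, enough noise
to probe robustness.

Three rule variants are included: **IMR** (inertial: a tied node keeps
its current value with probability `p_i`), **NMR** (null: values in
{0, 1}, an absent regulator contributes nothing) and **INMR** (both);
the deterministic INMR limit (`p = 1`) is the update rule of the
classical 11-node budding-yeast cell-cycle model, which ships as a
built-in fixture.

The package computes, exactly (rational arithmetic end to end when tie
probabilities are rational):

* the `2^n x 2^n` transition matrix and its support digraph;
* attractors as terminal strongly connected components, with the
  extended absorbing-chain classification (fixed points *and*
  deterministic cycles count as absorbing);
* the fundamental matrix `N = (I - Q)^-1`, absorption probabilities
  `B = N R`, stationary vectors `pi` and mean return times
  `m_i = 1 / pi_i`;
* the full atlas of the 16 two-node models with doubly-regulated nodes:
  in-phase / out-of-phase partition, the six isomorphism classes
  IP1–3 / OP1–3, extreme-corner AND/OR logic tables, and the
  random-map realisation of the chain;
* steady configurations (positive self-transition probability) by brute
  force over the matrix diagonal and by the scalable
  deterministic-modules-first search, plus single-edge additions that
  make a target configuration absorbing.

A seeded simulator cross-validates every exact quantity empirically.

## Worked example

The mutual-activation motif with self-activations (both nodes
probabilistic, tie probabilities 1/2) is bistable:

```python
from fractions import Fraction
import majorules as mj

m = mj.TwoNodeModel(mj.ModuleSpec(1, 1), mj.ModuleSpec(1, 1))
tm = m.transition_model(Fraction(1, 2), Fraction(1, 2))
print(mj.classify_chain(tm))                   # absorbing_extended
for e in mj.ergodic_sets(tm):
    print(e.kind, [tm.state_label(s) for s in e.states])
N, trans = mj.fundamental_matrix(tm)
print([tm.state_label(s) for s in trans], N.tolist())
```

prints

```
absorbing_extended
fixed_point ['--']
fixed_point ['++']
['-+', '+-'] [[3/2, 1/2], [1/2, 3/2]]
```

— the all-OFF and all-ON states are the two fixed points, and a chain
started in a mixed state spends on average 3/2 steps there and 1/2 a
step in the other mixed state (2 transient steps in total) before being
absorbed.

On the yeast network with the artificial self-degradation loops
discarded, the steady-state search singles out the biological G1 state
(only Cdh1 and Sic1 ON) and its global mirror:

```
$ majorules steady yeast:mr_pruned
2 steady configuration(s)
  ----+---+--  probability (1-p[Cln3])*(1-p[MBF])*(1-p[SBF])
  ++++-+++-++  probability (p[Cln3])*(p[MBF])*(p[SBF])
```

G1 holds only with probability `(1-p_Cln3)(1-p_MBF)(1-p_SBF)` because
three modules tie there.  The repair engine lists the single-edge
additions that determinise the tied modules — among them the two
biologically supported activations Cln1/2 -> SBF and Clb5/6 -> MBF.
With those edges added and the input Cln3 clamped OFF, G1 becomes the
unique attractor of the 1024-state chain:

```
$ majorules analyze yeast:revised --clamp Cln3=0 --collapse-clamped
rule: MR  states: 1024
classification: absorbing_extended
attractors: 1
  fixed_point: ---+---+--
transient states: 1023
```

Clamping Cln3 ON instead yields the value-flipped mirror attractor.

## CLI

`majorules analyze | atlas | steady | suggest-edges | simulate | export`
— run any subcommand with `--help`.  Networks are TSV edge lists
(`source<TAB>target<TAB>sign`), JSON model files, or the built-in
`yeast:{original_with_selfloops,mr_pruned,revised}` fixtures.

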