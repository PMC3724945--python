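# Methods

## Model

A regulatory network is a signed digraph on `n` named nodes with at
most one edge per ordered pair; all interaction weights are 1 and all
activation thresholds are 0 (non-zero thresholds and weights are out of
scope).  Each node `i` carries a tie probability `p_i` (default 1/2,
accepted as an exact rational) and, optionally, a clamp freezing it at
a level in {0, 1}.  Updates are synchronous.

The four rules differ in two independent choices:

| rule | values | absent regulator | tie (`U_i = 0`) resolution      |
|------|--------|------------------|---------------------------------|
| MR   | ±1     | opposite effect  | ON with probability `p_i`       |
| IMR  | ±1     | opposite effect  | keep current value w.p. `p_i`   |
| NMR  | 0/1    | no contribution  | ON with probability `p_i`       |
| INMR | 0/1    | no contribution  | keep current value w.p. `p_i`   |

The inertial tie resolution is read as *keep with probability `p_i`*
because its `p = 1` limit must reproduce the deterministic inertial
rule (ties never change a node); equivalently, the probability of the
high value is `p_i` when the node is currently high and `1 - p_i`
otherwise.  A node is deterministic iff its update is deterministic in
every configuration: odd in-degree under MR/IMR, never (unless clamped)
under the null variants, where the all-absent configuration ties every
node.  An unclamped in-degree-0 node has an empty contribution sum and
is perpetually tied; clamping it is the mechanism for input scenarios.

## State indexing

Configurations are indexed big-endian: the first node in declared order
is the most significant bit and the high value (+1 / 1) is bit 1, so
all-low is index 0.  Node order is therefore part of the model; the
JSON serialisation preserves it exactly, while the TSV edge list (which
carries no node list) orders nodes by first appearance and is written
with lexicographically sorted rows so that it is canonical.

## Chain analytics

The transition probability from `x` to `y` is the product over nodes of
the per-node next-value probabilities (independent tie resolutions).
Matrices are stored sparsely row by row; entries stay `Fraction`s
whenever every tie probability is rational, so row sums equal 1 exactly
and all derived identities are exact.

Attractors are the terminal SCCs of the support digraph (networkx
condensation).  Classification follows the extended absorbing notion:
*absorbing* when every ergodic set is a fixed point or a deterministic
cycle (every member state has a single successor), *regular* when one
aperiodic ergodic set covers the space (aperiodicity via networkx on
the support), *mixed* otherwise.  "Generic parameters" means tie
probabilities strictly inside (0, 1); analyses at generic parameters
are run at the distinct rationals 1/3 and 2/7 so that no structurally
positive entry vanishes, and the support-digraph builder refuses the
`generic` flag when a probability is extreme.

For absorbing chains, `N = (I - Q)^-1` over the transient states and
`B = N R` over the ergodic sets.  When deterministic cycles are present
(lcm of periods `k > 1`), both are computed from the transient
restriction of `T^k`, whose absorbing states are classical; the visit
counts of `N` are per `k`-step block and are converted to per-step
counts by multiplying by `k`.  This convention is covered by the
Monte-Carlo cross-checks.  Absorption events are identical under `T`
and `T^k` because ergodic sets are closed, so `B` needs no correction.
Stationary vectors solve `pi T = pi` per closed set; mean return times
are `m_i = 1 / pi_i`.

Exact linear algebra (inverse, nullspace) goes through sympy Rational
matrices up to 64 states per block and falls back to numpy beyond that
or when probabilities are floats.  Clamped nodes can be collapsed out
of the state space (`collapse_clamped`), giving the reduced
`2^(n-c)`-state chain with the clamps acting as constant inputs; by
default they stay in the space as deterministically self-restoring
coordinates.

## The two-node atlas

The third class of two-node networks — both nodes self-regulated and
cross-regulated — is enumerated as the 16 ordered pairs of the four
modules `(sigma, tau)`.  In the Gray-cycle row order (+,+), (+,-),
(-,-), (-,+) the module update tables are related by the rotation
`rho(sigma, tau) = (sigma, -tau)` if `sigma tau > 0` else
`(-sigma, tau)`, which is literally a row shift; `rho^4 = id` and the
four modules form one orbit.

A model is in phase (IP) when both nodes tie on the same two
configurations (`sigma_1 tau_1 = sigma_2 tau_2`): its matrix has two
fully probabilistic rows and two deterministic rows, 10 support
transitions.  Out-of-phase (OP) models tie exactly one node per state:
two entries per row, 8 transitions.  The implementation decides the
phase by the operational row-pattern test and asserts agreement with
the structural sign criterion.

Isomorphism (equality of matrices up to state renaming and a bijective
parameter correspondence within {p, 1-p, q, 1-q}) is decided by
exhausting the 24 state permutations and 8 injective substitutions,
comparing exactly at the three parameter points (1/3, 2/7), (2/5, 3/7),
(1/7, 5/11): entries are multilinear in (p, q), so agreement at three
generic points implies identity.  The classes come out as IP1/IP2/IP3
and OP1/OP2/OP3 with sizes (2, 2, 4) in each phase family, labelled by
their self-sign pattern (both activations / both inhibitions / mixed);
the label is asserted to be constant on each computed class.

Under IMR the class structure is identical, but no IMR model has the
same matrix as its MR counterpart (nor is any related to it by the
witness search above): every module table ties at both current values,
so the keep rule replaces one `p` by `1 - p` in every composition.
What does carry over, and is tested, is the support, the row pattern,
and the collapse of the OP loop probabilities: at the tied loop states
an MR model carries complementary pairs `x` and `1 - x` while the IMR
model carries two equal loops.  Under NMR the four models built from
the two balanced modules (one activator, one repressor) coincide
exactly with their MR counterparts, since the boolean sum is then half
the spin sum.

At the four extreme tie corners the dynamics is deterministic and each
node's rule is identified by truth-table match as AND or OR over its
(possibly negated) literals.  The chain is realised exactly as a random
walk over these four corner maps, drawn each step with the product
probabilities of the per-node tie outcomes; the induced one-step law is
asserted (exactly) to equal the matrix rows.

## Steady-state search and repair

A configuration is steady when its self-transition probability is
positive; it is absorbing when that probability is 1.  The probability
is the product over tied modules of `p_i` or `1 - p_i` (under the
inertial rules always `p_i`), reported symbolically and numerically.
Brute force enumerates the `2^n` diagonal up to `n = 20`.

The staged procedure enumerates the `2^k` assignments of the `k`
deterministic (odd in-degree, unclamped) modules and keeps those that
admit a *steady extension*: a completion of the remaining nodes in
which every module holds its value with positive probability.  The
plain weaker test — each deterministic module steady for some
completion, checked independently of the consistency of the values
forced on probabilistic modules — keeps 6 of the yeast's 32 cores
rather than 2; only the steady-extension test reproduces the published
2-candidates / 30-discarded split, so it is the definition used.
Extensions are found by constraint propagation (a module whose known
inputs bound its sum away from zero forces its node's value) plus
branching, and every complete configuration is verified against the
self-transition probability, which makes the staged result equal the
brute-force restriction by construction (asserted on fixtures).
Discarded cores are annotated with the deterministic modules blamed by
the completions with the fewest unsteady modules.

MR dynamics has an exact mirror symmetry: flipping every value and
replacing each `p_i` by `1 - p_i` conjugates the chain.  Steady
configurations therefore come in mirror pairs, and with the same
generic parameters both members have positive probability.  On the
yeast network the unclamped brute force accordingly finds exactly two
steady configurations — G1 and its mirror; the statement that G1 is
*the* unique steady configuration holds in the input scenario with
Cln3 clamped OFF, which kills the mirror core's extensions.  Both
statements are tested.

Repair: a module tied at a target configuration is determinised by any
single added edge whose contribution at the target pushes the sum
toward the node's target value — a positive edge from a node sharing
that value, or a negative edge from a node opposing it — excluding
existing ordered pairs.  Suggestions are ordered by tied node, then
source, then sign.  On the yeast G1 target this recovers the two
biologically supported revisions Cln1/2 -> SBF and Clb5/6 -> MBF; with
both added and Cln3 clamped, G1 (input OFF) and its mirror (input ON)
are the unique attractors of the respective 1024-state chains at tie
probabilities 1/2.

## The yeast fixture

The 11-node budding-yeast cell-cycle wiring is transcribed from the
published threshold model: 29 cross-regulatory edges plus five
self-degradation loops (Cln3, Cln1/2, Swi5, Cdc20/Cdc14, Mcm1/SFF) that
the original inertial-null formulation needed and that the plain MR
makes redundant (an absent regulator already pushes its targets down).
The transcription is gated by structural invariants — a single
in-degree-0 input (Cln3), exactly five odd-in-degree non-input modules
— and by the deterministic INMR census: the original model has exactly
seven fixed points, the G1 state (only Cdh1 and Sic1 ON) plus six
others, reproduced by exhaustive enumeration of the 2048 boolean
configurations.  Under the deterministic inertial rules a tie keeps the
node value, so the deterministic INMR map is implemented as the
extreme corner `p = 1` of the stochastic rule.

## Null-rule census

At generic parameters, 11 of the 16 NMR models converge to an attractor
strictly smaller than the state space ("a fixed point or a small
cycle"): 9 are absorbing in the strict extended sense and 2 end in a
two-state attractor in which one node keeps flickering (one
deterministic arrow plus one stochastic state, hence not a
deterministic cycle).  The remaining 5 models are regular.  The census
function reports all four counts.

## Simulator

One `numpy.random.default_rng` (PCG64) stream per trajectory; per step,
node values are drawn in network node order, so trajectories are
bit-reproducible given the seed.  Estimators (transition frequencies,
first-return times, absorption frequencies and times) report mean ±
standard error; runs exceeding the horizon are counted as censored,
never dropped.  Agreement with the exact quantities is tested at fixed
seeds with a 3-standard-error band (10^4–10^5 samples).

## Problem sizes and defaults

The test suite and the acceptance script run the two-node models
exactly (4 states), the yeast chains at 1024–2048 states, Monte-Carlo
checks at 10^4 runs / 10^5 steps, and the atlas classification over all
120 model pairs; everything completes in well under a minute on one
core.

## Known limitations

* Non-zero thresholds, non-unit weights, multi-valued variables and
  asynchronous updating are out of scope.
* Exact linear algebra is capped at 64 states per block; larger blocks
  use floating point (the yeast-scale analyses need only SCC structure,
  which stays exact).
* The repair engine proposes single-edge additions per tied module;
  multi-edge repairs are compositions obtained by iterating.
* The brute-force steady-state enumeration is capped at `n = 20`; the
  staged search scales further but assumes an MR/IMR
  deterministic/probabilistic split.
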