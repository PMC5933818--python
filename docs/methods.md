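# Methods

## Scope and model

`switchdyn` computes qualitative dynamics of switching (Glass-type)
models of gene regulation over *all* of parameter space, organized as a
finite parameter graph, and answers signal-path queries about bistable
switching. The continuous model behind the combinatorics is

    dx_n/dt = -gamma_n x_n + Lambda_n(x),   gamma_n > 0,

with Lambda_n a product of sums of two-level step functions: an
activating input contributes ell (low) below its threshold and u (high)
above it; a repressing input contributes u below and ell above; ell < u
always. The conclusions drawn from the combinatorial layer hold for any
vector field that agrees with the switching field's wall directions, not
only for the literal step-function system; the ODE layer here is a
numeric spot-check, not a proof.

### Domains and the state transition graph

With all thresholds of a node distinct (the non-degeneracy assumption),
phase space [0, inf)^N splits into prod_n (T_n + 1) rectangular domains,
where T_n is node n's out-degree; kappa_n counts node n's own
out-thresholds below x_n. For a fixed parameter region, the flow target
Phi(kappa)_n = g_n(input combination of kappa) determines the transition
graph on domains: an edge toward kappa +/- e_n whenever Phi differs from
kappa in coordinate n, and a self-edge exactly when Phi(kappa) = kappa.
This domain-level graph is the package's single STG semantics; the
bipartite presentation with explicit wall vertices is emitted only in
DOT export (`walls=True`) for didactic purposes — it has the same
recurrent structure. A consequence of the domain semantics: opposing
wall directions (possible under negative self-regulation) appear as a
2-cycle between adjacent domains, i.e. a legitimate non-FP recurrent
component, never an error.

### Morse graphs

Recurrent components (SCCs containing at least one edge, self-loops
included) are the Morse nodes, partially ordered by reachability;
minimal nodes are the attractors. A singleton component whose only edge
is a self-loop is labeled FP(kappa), with 0-based coordinates in node
declaration order. Two implementations coexist deliberately: a
networkx-based one behind the public API and a hand-rolled iterative
Tarjan inside the batch engine (object overhead dominates at ~10^5 small
graphs); the test suite checks both against a reachability-closure
oracle.

## The parameter graph

Per node, a parameter region is a pair (g, O): a monotone map from the
2^S low/high input combinations to the T + 1 output states, and a total
order of the node's out-thresholds. Adjacency = exactly one inequality
flips: one adjacent transposition in O, or one unit change of g at one
input combination. The full parameter graph is the product over nodes.

Two modeling decisions matter here:

* **Cells finer than (g, O) are collapsed.** The relative order of
  products of ell/u values across different input combinations subdivides
  (g, O) regions further, but the state transition graph depends only on
  (g, O), so the finer subdivision is dropped. Consequence: the node
  logic (AND/OR) does not restrict the factor graph — every monotone map
  is admitted, including, for in-degree >= 3, maps that a specific
  algebraic logic cannot realize. The ODE sampler reports such cases as
  infeasible rather than silently ignoring them (for pure product logic
  the realizable maps are exactly the positive threshold functions, which
  is how the infeasibility path is exercised in tests).
* **Lows and highs are sets.** A factor graph has one g == 0 vertex and
  one g == T vertex *per threshold order*; uniqueness holds only for
  T = 1 and is not assumed anywhere.

Monotone maps are enumerated by depth-first lattice extension in
lexicographic order; a configurable candidate cap (default 10^6 on
(T+1)^(2^S)) turns pathological nodes into an explicit `CapacityError`,
never a truncation.

### Essential regions

An edge j -> i is *input-essential* at a region if flipping only its
input bit changes g_i somewhere, and *output-essential* if g_j attains
values on both sides of the edge's threshold rank. Both conditions are
local to a single node's (g, O) — input-essentiality to the target's
map, output-essentiality to the source's — so essentiality of a full
parameter node factorizes over nodes, and the essential parameter graph
is a product of per-node essential vertex sets. The batch queries
restrict every node outside the signal chain to its essential vertices
(a region where some edge is inessential represents the dynamics of a
strictly smaller network); chain nodes are exempt, since a pure relay
head has no inputs and its out-edge can never be output-essential.

## The signal model

The external signal S never appears as a numeric quantity. Its entry
point is resolved by walking from the receiving node while the current
node is a pure relay (one out-edge, no other in-edge); the first node W
with more than one input or output is the query node. The walk's
repression parity fixes the orientation: with an odd number of
repressing relay edges the signal-low end of W's factor graph is its
*high* vertex, and every reported path is reversed accordingly.

A **full path** is a monotone chain in PG(W) from the signal-low to the
signal-high vertex with the threshold order held fixed — the signal
shifts production levels relative to thresholds, never the order of the
node's own thresholds — raising g by one unit at one input combination
per step (T * 2^S steps). **Partial paths** are all contiguous subpaths,
constant single-vertex paths included, deduplicated by vertex sequence.
Copies of PG(W) fix the factors of every other node (essential for
non-chain nodes, all factors for chain nodes); a path lifts vertex-wise
into each copy.

An optional joint-sweep mode (`sweep_chain_factors=True`) instead drags
the chain nodes' factor chains monotonically along with W, counting
monotone interleavings in the product; it is provided for sensitivity
analysis and is not the default.

## Phenotype states and path queries

Through the phenotype node's coordinate, each Morse graph's attractor
set is summarized as: QS (unique attractor, an FP at coordinate 0), PS
(unique FP attractor at coordinate >= 1), B (both a QS-FP and a PS-FP
present), (QS,*) / (PS,*) (two or more FP attractors, only one side
present), or OTHER. Non-FP attractors are wildcards: they block the
monostable classes and never count as QS or PS.

* *Resettable bistability to QS*: the sequence starts (at the
  signal-withdrawn end) in QS, reaches a B vertex, and every vertex up to
  it is QS-compatible ({QS, B, (QS,*)}). The default is this prefix
  reading; `whole_path_resettable=True` demands the entire path stay
  compatible (so a path that commits to PS at the far end no longer
  counts).
* *Hysteresis*: resettable to QS from the low end and resettable to PS
  from the high end. The default predicate is this literal double
  condition, which tolerates unclassified vertices strictly between the
  two compatible runs; `strict_hysteresis=True` instead requires the
  exact segment pattern QS+ B+ PS+.

Both prevalence normalizations are always computed: the fraction of
lifted (copy, path) pairs exhibiting a query, and the fraction of copies
in which at least one path does. Every report records its convention
flags in metadata.

Counting is done by dynamic programming over the product of the factor
graph's unit-increment DAG with a small deterministic automaton per
query, which is exactly equivalent to classifying every enumerated path
(asserted by tests on small factor graphs) but remains polynomial when
the path sets explode — the densest screened 3-node network has ~3.4
million full and ~5 x 10^7 partial paths.

### Calibrated convention

Published prevalence figures for this family of case studies do not
fully specify the counting convention, and the two predicate readings
above genuinely differ on paths with unclassified middles. The
convention used by `scripts/acceptance.py` — strict-segment hysteresis
with per-pair normalization — was selected because it is the unique
combination under which the 49-network screen reproduces the structural
fingerprint of the reference results (exactly five networks exhibiting
hysteresis on every full path, and 27 networks with positive
partial-path hysteresis). Some individual published percentages are
nevertheless not reproduced by any convention expressible in this
framework; the acceptance script reports what the package computes, and
the discrepancies are visible rather than patched.

## ODE cross-validation

`realize_parameters` places thresholds at integer ranks + 1 and fixes
gamma = 1 (the queries tested are invariant under these normalizations;
both are overridable by editing the returned point), then chooses
production levels so that each Lambda_n lands in the open interval
dictated by g_n: constructive for in-degree <= 1, rejection sampling
with ell, u log-uniform in [1e-2, 1e2] (cap 10^5 draws) otherwise.
Every accepted point is re-verified against all inequalities by an
independent recheck; a capped sampler yields an `InfeasibilityReport`
(informative output, not an error). Integration is fixed-step explicit
Euler with step <= 0.1/max(gamma); threshold crossings are not located
exactly, values exactly at a threshold resolve as "below", and the
trapping check allows 0.05 of wall overshoot at the horizon. Trapping
runs use 50 trajectories per fixed point at horizon 50 with step 0.05 in
the validation suite, which keeps the full battery (20 random parameter
regions per network for the toggle and a 3-node fixture) under a minute.

## Determinism and problem sizes

Everything outside the ODE sampler is deterministic: node declaration
order fixes coordinates, factor vertices carry stable ids (orders in
lexicographic permutation order x maps in lexicographic value order),
copies and paths enumerate in fixed order, and screens are checkpointed
by network id. The bundled screens are desk-scale by construction: the
3-node template's 49 subnetworks complete in ~2.5 minutes on one core
(dominated by the one network with a 3-input, 3-output node), the START
and 5-node fixtures in well under a second each.

## Known limitations

* Logic-realizability of monotone maps is not enforced in the parameter
  graph (see above); for in-degree >= 3 the screen therefore counts
  regions a specific algebraic logic might not realize.
* Oscillation-oriented queries are out of scope: non-FP recurrent
  components are detected and labeled but only enter the path queries as
  wildcards.
* The ODE layer validates trapping of FP domains; it does not verify
  Morse-graph edges or non-FP components.
* Multi-edge interactions, dual-sign pairs, and stochastic or delayed
  semantics are unsupported by design.
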