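# Methods

This note documents the statistical model behind capskel, the estimators
and decision rules it uses, the design choices that were genuinely open,
and what the synthetic benchmarks do and do not demonstrate.

## Channels, capacity, path information

All variables are discrete (categorical strings); each variable carries a
fixed lexicographic alphabet, so a pair (X, Y) defines a transition
tensor `A[x, y] = p(y | x)` — the discrete memoryless channel from X to
Y. The working assumptions are the usual information-theoretic ones:
samples are i.i.d. draws from a stationary joint distribution, the system
is causally sufficient (no hidden common causes), faithful (independence
in the data reflects structure, not parameter coincidence), and noisy
(all channels strictly stochastic). Because mutual information is
symmetric, only the undirected skeleton is identifiable; orientation is
out of scope.

Capacity is computed by Blahut–Arimoto alternating maximization from the
uniform input distribution. The iteration maintains a certified bracket:
`Σ_x r(x) D(P_x‖q)` is a lower bound on capacity and `max_x D(P_x‖q)` an
upper bound, and iteration stops when the gap falls below a tolerance (in
bits) or after `max_iterations` (default 10 000, flagged unconverged).
All information quantities are in bits.

Paths compose by matrix product: the tensor of {X}{Y}{Z} is
`A_XY · B_YZ`, and the path information is the mutual information induced
by the composed tensor and the input marginal. Backward traversal uses
the Bayes-inverted dagger tensor `A‡[y, x] = p_x A[x, y] / p_y` (defined
whenever all output marginals are positive; it is stochastic but is not
the matrix inverse of `A`). Two exact consequences anchor the test suite:
along a population chain the composed tensor equals the end-to-end tensor
and path information equals `I(X;Z)`; and a fork traversed either way
yields identical path information.

## Estimation

* **Tensor cells.** `p̂(y|x) = (n_xy + 1/2) / (n_x + K_out/2)` —
  Dirichlet–Jeffreys add-1/2 smoothing per row. This matches the
  Jeffreys-interval choice below, keeps every tensor strictly positive
  (the noisy-system assumption), and inflicts O(1/n) bias only.
* **Confidence bands.** Each cell gets the equal-tailed 95% interval of
  `Beta(n_xy + 1/2, n_x − n_xy + 1/2)` — the Jeffreys interval of the
  cell against its complement. For output alphabets larger than two the
  band is applied cellwise, i.e. rows are covered marginally rather than
  jointly; a joint Dirichlet region would be tighter but has no similarly
  simple closed form.
* **Joints** (for mutual information) are raw relative frequencies; no
  smoothing, since no division by small row counts occurs.
* **Missing data** are dropped pairwise: a sample missing either member
  of the pair under estimation is ignored for that pair only, keeping
  every estimate bivariate.
* **Mediator sets** are handled by a derived joint variable whose symbols
  are tuples of member symbols; its alphabet is the set of *observed*
  tuples. A configurable cap (default 64 observed symbols) refuses joint
  mediators whose rows would be too thin to test at n ≈ 2000.

## Significance decisions

The plug-in capacity of an estimated tensor is positively biased —
smoothing alone produces capacities of order 1/n — so "capacity > 0"
cannot be read off the estimate.

* **Direct edges: permutation test.** The observed capacity is compared
  with capacities re-estimated after permuting the second variable's
  column B times (default 200), breaking the pairing while preserving
  both marginals; `p = (1 + #{null ≥ observed}) / (1 + B)`. This null is
  exact, so the false-edge rate equals the nominal level up to
  permutation granularity (≈ 0.0497 at α = 0.05, B = 200). Both
  orientations of a pair are tested against the same permuted pairings,
  and an edge requires significance in at least one orientation.
* **Composed paths: Dirichlet bootstrap.** A composed tensor has no
  direct counts to permute. Each replicate redraws every constituent
  row from `Dirichlet(counts + 1/2)`, composes the replicates, and the
  path is called "capacity larger than zero" when the empirical 5%
  quantile of replicate capacities clears an epsilon floor of 1e-3 bits
  (the scale that smoothing noise alone reaches at n ≈ 2000).
* No multiple-testing correction is applied across pairs by default; an
  optional Bonferroni switch exists.

## The three discovery steps

1. **Capacity graph.** Permutation-test all pairs; single-symbol
   (degenerate) variables can never gain an edge.
2. **Bivariate pruning.** One synchronous pass against the step-1
   snapshot: edge X–Z is pruned when for some common neighbor Y the
   composed {X}{Y}{Z} tensor lies inside the direct tensor's band *and*
   the reversed traversal {Z}{Y}{X} does too. Demanding both directions
   guards against asymmetric estimation noise; the synchronous pass makes
   the result order-independent (an iterate-to-fixed-point mode exists
   behind a flag). Equality holding under the true distribution requires
   Z ⊥ X | Y, so only genuinely mediated edges are pruned as n grows.
3. **Multivariate pruning.** For each surviving edge with ≥ 2 indirect
   paths (simple paths of 2–4 edges through surviving edges; the length
   cap covers the longest path the benchmark analysis needs and is
   configurable), each path is bootstrap-tested. If ≥ 2 paths carry
   capacity, their interiors form the mediator set S and the edge is
   pruned iff the composed {X}{S}{Z} tensor matches the direct one in
   both orientations. If exactly one path carries capacity the step-2
   verdict is kept, after conservatively re-checking that single path
   (this re-check also removes step-1 false positives that happen to
   have one real connecting path, since their endpoints are separated by
   that path's interior).

Indirect paths are enumerated over *surviving* edges. Enumerating over
pruned edges as well would flood step 3 with candidates built from
already-explained associations; the narrower rule also reproduces, on the
true 12-node benchmark skeleton, exactly one multivariate candidate pair
(see below).

All per-pair and per-path seeds are derived deterministically from the
run seed, so identical data and configuration give identical skeletons
and reports.

## The synthetic generator

`capskel.synthetic` builds discrete Bayesian networks (DAG + CPTs),
samples them ancestrally, and — networks here being at most 12 binary
nodes — computes exact population marginals, pair joints and tensors by
full joint enumeration. These population objects are the oracles for the
composition/DPI/fork identities and for the population-oracle pipeline
(`discover_skeleton_oracle`), which replaces estimates with exact tensors
and the band verdict with exact equality and must recover every fixture's
skeleton with zero errors.

Fixtures (binary, default link noise 0.1 — comfortably detectable at
n = 2000 yet clearly noisy):

* `chain`, `fork` — three nodes, binary symmetric links;
* `collider` — X → Y ← Z with `p(y=1|x,z)` = noise / 0.5 / 1 − noise for
  0/1/2 active causes, so both edges carry capacity while X ⊥ Z;
* `diamond` — X → U → Z, X → V → Z with *no* direct X–Z mechanism: the
  X–Z association is carried by two paths, neither single-mediator
  composition reproduces the end-to-end tensor (population cell
  differences > 0.01), and only the multivariate step with S = {U, V}
  can explain the edge away;
* `lucas_like` — 12 binary nodes whose skeleton matches the public LUCAS
  ("LUng CAncer Simple") benchmark: Anxiety/PeerPressure → Smoking →
  YellowFingers and (with Genetics) → LungCancer; Genetics →
  AttentionDisorder; Allergy/LungCancer → Coughing;
  LungCancer/Coughing → Fatigue; AttentionDisorder/Fatigue →
  CarAccident; BornEvenDay isolated. The benchmark's generating CPTs are
  not public, so the tables are this package's own; only the *skeleton*
  emulates the benchmark. Every true edge of every fixture has population
  capacity ≥ 0.05 bits (faithfulness guard, asserted in the tests).

On the true `lucas_like` skeleton exactly one edge — (LungCancer,
Fatigue) — is joined by two or more indirect paths of ≤ 4 edges: the
2-edge Coughing path and the 4-edge
Genetics–AttentionDisorder–CarAccident path. In finite-sample runs the
long path's bootstrap test is usually not significant, so the edge is
kept on the strength of the single-path re-check against the Coughing
mediator — the direct tensor does not match that composition, and the
edge survives.

What sampling from these fixtures does *not* show: robustness to hidden
confounders, selection, non-stationarity, measurement error, or
real-world effect-size distributions. Passing benchmarks demonstrates
correctness of the machinery under the model's own assumptions, not
field performance.

## Numerical choices

* Blahut–Arimoto: uniform initialization (deterministic); `0·log 0 = 0`;
  capacities clamped at 0 against round-off. The standalone routine uses
  a 1e-9-bit bound-gap tolerance. Inside the pipeline's permutation and
  bootstrap batches the tolerance is 1e-6 bits: the capacity lower bound
  is accurate to ~1e-10 bits by the time the certificate gap reaches
  1e-6, while closing the gap itself to 1e-9 costs >10^4 iterations per
  near-null channel for no change in any decision.
* Composition renormalizes rows after the matrix product to absorb
  accumulated round-off in long products.
* Ties/degenerate inputs: a variable observed with one symbol yields
  capacity 0 by construction; an input symbol with zero complete
  observations is an error rather than a silent guess.
* Permutation p-values use the add-one convention, so the smallest
  attainable p is 1/(B+1).

## Simulation sizes used by the checks

Chosen to bound Monte-Carlo error meaningfully while keeping runs brisk:
capacity closed-form grid over six flip probabilities; 1000 random chains
for the DPI sweep; 100 random forks for symmetry; 500 repetitions at
n = 2000 for calibration; 100 seeds per triad fixture, 50 diamond seeds
and 20 LUCAS-like seeds at n = 2000 for recovery rates.

## Known limitations

* A well-calibrated α = 0.05 edge test implies ~5% false edges per truly
  independent pair. False edges incident to a vertex with no other
  neighbors (an isolated variable such as the BornEvenDay analogue) have
  no common neighbor and no connecting path, so no pruning step can
  remove them; exact whole-skeleton recovery on a 12-node network with
  ~29 independent pairs therefore fails in a substantial fraction of
  runs even though per-edge behaviour is exactly as designed. Lowering α
  or enabling Bonferroni trades those false edges against power.
* Several genuinely indirect pairs of the 12-node benchmark (e.g. the
  Smoking–CarAccident analogue) have *no* single-vertex separator — every
  single-mediator composition differs from the direct tensor at the
  population level because conditioning on one mediator opens a collider
  elsewhere. Whether bivariate pruning removes them at n = 2000 depends
  on effect sizes relative to band widths; with this package's CPTs they
  regularly survive to step 3, which then removes them via mediator
  sets. The textbook picture in which bivariate pruning leaves exactly
  one multivariate candidate is a property of a particular generating
  distribution, not of the graph.
* Cellwise (not joint) confidence bands; no continuous variables or
  binning; no edge orientation; no time-series/transfer-entropy variant.
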