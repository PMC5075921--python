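# Methods

This note documents the modeling choices behind `fuzzysig`: the executable
model class, the scoring of prior knowledge, the objective, the search
strategy, the synthetic-data generators the tests rely on, and the
numerical conventions. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Prior knowledge network

Edges come from literature endorsements. Publications are split into
low-throughput and high-throughput by the number of unique reactions they
endorse; the default cutoff of 111 reactions is the 90th-percentile value
of a large pathway-database snapshot and is exposed as a config default,
with `ht_threshold_from_counts` recomputing it from any endorsement table.
A reaction endorsed by a single study class is scored from a fixed table
(low-throughput: 0, 0.8, 0.9, 0.95, 0.95 for 0–4+ endorsements;
high-throughput: 0, 0.25, 0.5, 0.75, 0.85); mixed support scores the
low-throughput base plus 0.05 per high-throughput endorsement, capped at
0.95. The asymmetry encodes the lower false-positive rate of
low-throughput experiments.

**Compression.** Proteins that are neither stimulated, inhibited nor
measured ("undesignated") are not identifiable and are removed before
inference. An undesignated node with indegree 1 or outdegree 1 is a
pass-through (a linear cascade, a convergence onto a dispatcher, or a
divergence out of a cascade): each in/out pair of tandem edges is merged
into one edge with the *minimum* of the two confidences — the bottleneck
of the path — and the *product* of the two signs, so two inhibitions
compose to an activation (standard signed-path semantics; the composition
rule is this package's choice). Undesignated nodes with no incoming or no
outgoing edges are non-controllable/non-observable and are dropped
outright. Nodes are visited in sorted order and the rules iterate to a
fixed point, which makes the procedure deterministic and idempotent;
parallel duplicates arising from merges keep the larger confidence, and
self-loops created by a merge are dropped as unidentifiable. Undesignated
crossroads nodes (indegree > 1 and outdegree > 1) are kept: merging them
would multiply edges and change the gate semantics. Incoming edges of
stimulated nodes are removed — a stimulated node is an experimental input.

## Fuzzy logic model

The transfer function is the simple Hill form `f(x) = x^p / (x^p + h^p)`.
It maps [0, 1] into [0, 1), is strictly increasing, and has its midpoint
exactly at the sensitivity parameter (`f(h) = 1/2`) for every `h` in
(0, 1) — including the whole default grid `h ∈ {0.2, …, 0.8}`, which a
variance-constrained normalized Hill variant would not support (it is
undefined once `h^p ≥ 1/2`). `p` defaults to 2 (sigmoidal but not
step-like) and `h` is a single global parameter optimized over the
discrete grid as one gene; per-edge sensitivities are deliberately not
implemented — they would explode the parameter count that the small
datasets this method targets cannot constrain.

Gates are DNF with the restriction that each regulator appears in exactly
one AND clause, i.e. a gate shape is a set partition of the regulators
(Bell(k) shapes for indegree k). This covers the biologically typical
"regulator acts through one specific complex" cases while keeping the
search space finite. AND/OR are min/max; inhibition enters as `1 − f(x)`.
In Boolean mode the transfer is the identity, not a thresholded Hill:
with the simple Hill `f(1) < 1`, so bypassing the transfer is what makes
the fuzzy model an exact Boolean network on binary states.

**Simulation.** Updates are synchronous (the asynchronous alternative is
combinatorially explosive and is out of scope). Steady-state search starts
all non-clamped nodes at 0, holds stimulus clamps and inhibited nodes
(clamped to 0, the usual convention for kinase inhibitors) fixed, and
stops when the max absolute change of successive states drops below
ε = 1e-6 or after 5·m iterations; non-convergence (feedback loops
oscillate under synchronous updates) is reported via a flag and the last
state is used, not an exception. Time-series simulation runs 3× the number
of experimental time points, starting measured nodes at their first
experimental value and everything else at 0. Parentless non-clamped nodes
hold their state. A compiled (numba) kernel mirrors the reference
implementation step for step; the test suite asserts their agreement, and
the package falls back to the reference path if no compiler is available.

## Objective

* **Steady state:** mean squared error over all (condition, measured node)
  cells.
* **Time series:** dynamic time warping per measured node, summed over
  nodes and series. Local cost is the squared difference; paths are pinned
  at both ends and advance one or both indices per step (continuity and
  monotonicity); the minimum total cost is normalized by the alignment
  length S so losses are comparable across path lengths. Ties are broken
  toward shorter paths, then toward diagonal steps. The experimental
  series is aligned against the full 3·n_y-point simulation — one window
  whose size equals the simulated length; a `window_stride` option slides
  a shorter window and keeps the minimum for users who want a true sliding
  search. Both the normalization and the pinned endpoints are documented
  config constants rather than empirical claims.
* **Prior regularizer:** `γ · Σ_ij |b_ij − w_ij|` over ordered node pairs,
  the quantitative extension of the qualitative edge-set prior: including
  a confidence-w edge costs 1−w, excluding it costs w, a non-prior edge
  costs 1, and binary confidences recover the qualitative disagreement
  count exactly.
* **Indegree regularizer:** `λ · Σ_j max(0, indeg_j − d_max_j)` — a hinge,
  penalizing only the excess over the knowledge-derived cap. γ and λ are
  equal by default (equal confidence in both kinds of prior knowledge) but
  are exposed separately.

For steady-state fits the per-node error report lists LSE (sum of squared
errors over conditions), MSE (LSE divided by the number of conditions) and
their sums, each labeled, since summary conventions differ between
studies.

## Search

The unknowns (B, C, R, h) form a constrained integer program. A chromosome
holds an include bit, a sign bit and a clause gene per candidate edge
(ordered pairs, excluding self-loops and stimulated targets) plus one h
index. Decoding reduces clause genes modulo the realized indegree and
renumbers labels canonically, so label permutations decode to the same
gate and every decoded model is valid by construction. The GA is
generational: tournament selection (size 3), uniform crossover (rate 0.8),
per-gene mutation (rate 1/length), elitism 2, defaults population 100 ×
200 generations × 50 restarts seeded `seed, seed+1, …`. Initial
populations are random with include-bit probability 0.2 (sparse, like real
signaling networks); the prior enters only through the objective, never
through initialization, so recovery improvements with richer priors are
attributable to the regularizer. Fitness ties are broken by lower prior
penalty, then fewer edges, then lexicographic chromosome, making results a
pure function of inputs and seed. Prior-edge signs float by default
(`pin_prior_signs` fixes them). `exhaustive_fit` enumerates the identical
space exactly and is the optimality oracle for small problems; it refuses
spaces beyond ~2×10⁶ models.

## Synthetic data

The generators emulate the study conditions the method is evaluated under:

* `toy9` — the bundled 9-node, 10-edge benchmark with one negative
  feedback loop (c → h → j ⊣ c) and one AND gate ((c AND d) → f). Its full
  edge list beyond those structural facts is this package's own documented
  choice; all bundled structure-recovery properties are defined on `toy9`.
* `make_truth_network` — random connected signed networks with requested
  feedback loops and AND gates, deterministic per seed.
* `boolean_trajectories` — 5 synchronous Boolean trajectories of 10 states
  from random initial states, subsampled to 6–7 points (initial state
  always kept) to mimic sparse experimental sampling.
* `make_steady_state_panel` — fuzzy steady-state responses per condition,
  optionally with truncated Gaussian noise (an artifact choice; the
  bundled trajectory studies are noise-free).
* `perturb_prior` — priors containing round(ratio·|truth|) true edges plus
  round(noise·|prior|) false edges, all confidences Uniform(0, 1), default
  indegree cap 2.

What passing tests on these fixtures shows — and does not show: the
pipeline recovers structure when data are generated by its own model class
and noise is limited to edge-level prior corruption. Real
phosphoproteomic data add measurement noise, unmodeled biology
(post-translational timescales, unmeasured regulators) and normalization
artifacts that these fixtures do not emulate; readers with MIDAS-style or
time-series CSVs can run the identical pipeline on them.

The structure-recovery experiment in the test suite uses a reduced search
profile (population 24, 16 generations, 5 restarts, 20 repeats per grid
cell), chosen once as the package's scaled-down study condition; the
GA-vs-oracle battery uses 3-node steady-state problems where exhaustive
enumeration is exact.

## Evaluation utilities

Structural distance counts directed edge additions plus deletions,
ignoring signs and gates. The significance test refits the model with
degree-constrained random networks as priors (same node and edge counts,
every node incident to an edge, stimulated nodes source-only with at least
one outgoing edge, confidences resampled from the original scores;
rejection sampling with a 10,000-attempt cap) and reports the z-score of
the true fit's data loss against the random-prior losses plus an empirical
p-value. Cell-fate prediction binarizes measured states at 0.5
(configurable), attaches fate nodes by OR-of-inputs gates, draws
Bernoulli(0.5) states for unmeasured proteins, and runs the Boolean
dynamics to an attractor with cycle detection; a fate counts as on at a
fixed point iff its bit is set and, on a cycle, iff it is set in at least
half the cycle's states (a "strict" fixed-point-only mode is available —
attractor handling on cycles is a package convention, not an empirical
claim).

## Known limitations

* Synchronous-update semantics only; oscillation periods are artifacts of
  the update scheme, and only attractor membership should be interpreted.
* A single global Hill midpoint; strongly heterogeneous transfer
  steepnesses across reactions are outside the model class.
* Compression order can, in rare topologies, affect which surviving direct
  edges exist (never their bottleneck confidences along preserved
  designated-to-designated routes); the deterministic sorted-node order
  makes results reproducible.
* The GA offers no optimality certificate beyond the small-problem oracle
  comparisons; multi-restart with the documented defaults is a heuristic.
* Logistic normalization of raw measurements is not reconstructed: inputs
  must already be in [0, 1] (`minmax_normalize` is a convenience only).
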