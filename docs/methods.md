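# Methods

## Model and statistic

A pathway is a directed multigraph. Nodes are non-empty sets of protein
identifiers (identity: the sorted, `;`-joined member list, so rows naming the
same set share a node). Edges carry a type with multiplier `T = +1`
(catalysis) or `T = −1` (inhibition); bidirectional relations are two opposed
edges; self-loops are single-edge cycles; parallel edges of differing type
are kept, identical ones collapsed.

Per protein, `E(x)` is the mean log-ratio (paired mode) or
`log_b(mean case) − log_b(mean control)` (unpaired mode, base `b = 2` by
default). A node's expression is the sum of its members' `E` values after
collapsing *exactly equal* values within that node to one contribution:
identical values inside one protein set almost always reflect one duplicated
measurement (redundant identifiers, protein variants sharing peptides), not
independent signals. Equal values in different nodes are unrelated and kept.
Proteins missing from the data contribute nothing and are counted in a
per-pathway coverage diagnostic (`n_measured / n_proteins`); the null-effect
choice keeps uncovered pathways at score 0 rather than excluding them.

A path `n₀ … n_L` (simple path or simple cycle; in a cycle the closing node
is counted again) scores

    s = E(n₀) + T₁·(E(n₁) + T₂·(E(n₂) + … + T_L·E(n_L))),

and the pathway statistic is `s* = max over paths |s|`, with the achieving
path reported.

### Dynamic programme

For every edge `e = (r → p)` the table stores the maximum and minimum signed
score over paths *starting with* `e`. The continuation past `p` is either
nothing (the path ends at `p`, contributing `E(p)`) or the best/worst
continuation through one of `p`'s outgoing edges; with `T(e) = −1` the roles
of best and worst swap. Values are memoized per edge together with
argmax/argmin pointers, so the table is linear in the edge count and the best
path is reconstructed by following pointers until a stop. The recursion is
seeded at leaf edges (no upstream edge reaches the reactant set) and then at
any still-unvisited edges in sorted `edge_id` order until the edge set is
exhausted, which reaches closed cycles. The exposed per-edge scores are
clamped (`max_score ≥ 0 ≥ min_score`): a negative best (or positive worst)
continuation is never forced on a parent.

On acyclic graphs this programme is *exact*: the test suite asserts bitwise
equality of the statistic with brute-force enumeration of all simple paths on
1000 random DAGs, and agreement of the reported path. On cyclic graphs edges
already on the recursion stack are not re-entered and memoized values depend
on the seeding order, so cycle scores are a deterministic heuristic, flagged
`cycle-heuristic` in the result; the brute-force scorer (`brute_force_score`,
with an enumeration-size guard) is the reference on small cyclic graphs.
Ties (equal `|s|`) are broken toward the positive branch and the
lexicographically smallest starting `edge_id`; the enumerator breaks ties by
lexicographic edge-id sequence. With continuous data ties have probability
zero; the rules exist to make results reproducible.

## Rotation null

Under the null, sample vectors are spherically symmetric within the residual
space of the nuisance design, so the data are multiplied by a random
orthogonal matrix there: project onto an orthonormal basis of the nuisance
complement, rotate, transform back, re-add the fitted nuisance component. One
rotation matrix is shared by all genes (preserving co-expression) and one
rotation stream is shared by all pathways of a dataset (preserving
cross-pathway correlation of the statistics, as shared shuffles do for
permutation tests). Rotations are the Q of the QR decomposition of a standard
normal matrix with the R-diagonal signs fixed — without the sign fix Q is not
Haar distributed. Default nuisance: none for paired log-ratios (the tested
mean *is* the interest term, so raw rows are rotated), the intercept for
unpaired designs. Unpaired rotation can produce non-positive group means
whose log is undefined; this raises rather than silently shifting — users
with single-channel data should supply log-scale values or use paired ratios.

The p-value is `(1 + #{sᵢ ≥ s*})/(R + 1)` with `R = 1000` rotations by
default (add-one avoids p = 0 and is the standard randomization-test form; a
flag restores the plain proportion). Storey–Tibshirani q-values use
`π̂₀` estimated on the λ-grid 0.05…0.95 by an inverse-variance-weighted
quadratic fit evaluated at λ = 0.95 — the same three effective degrees of
freedom as the classical df = 3 smoothing spline, but deterministic and
endpoint-stable; below 50 tests the fixed λ = 0.5 estimate is used. `π̂₀` is
clipped to `[1/m, 1]`.

## Simulator and fixtures

Each gene is `x_ij = d_i·(μ + g_i) + e_ij` with `d_i ∈ {−1, 0, +1}` fixed by
the fixture, `g_i ~ N(0, σ²_g)` drawn once per gene (shared across replicate
samples), `e_ij ~ N(0, 1)` fresh per gene and sample. Values are paired
log-ratios, so `E` is the row mean — the natural reading for zero-centred
null data, where the unpaired log-of-mean summary is undefined. Defaults
(μ = 0, σ²_g = 0, n = 10) are the null condition of the type-I experiments;
power and recovery runs set μ on a grid with σ²_g = 0, n = 10 unless the
experiment varies them.

The five fixtures are stored as data (pathway TSV + node table), not code:

* `catalytic_string` — 5 nodes, all catalytic, all `d = +1`; true path = the
  whole string.
* `inhibitory_string` — 5 nodes, all inhibitory, `d = (+1, −1, +1, −1, +1)`:
  each node contributes `+μ` after sign propagation; true path = the string.
* `mixed_string` — 5 nodes, edges alternating catalysis/inhibition with `d`
  matching the cumulative signs `(+1, +1, −1, −1, +1)`.
* `branched_crossroads` — 8 nodes, 8 edges (one inhibitory), with exactly one
  coherent 3-node route `BC3→BC4→BC7` switched on among decoy branches.
* `long_alternate_route` — 14 nodes: a 4-node 'on' route `LA01…LA04` from
  source to sink plus a 10-node background bridge joining the same
  endpoints. One bridge edge is inhibitory, so a bridge-spanning path picks
  up a sign flip on the shared sink and cannot compete with the true path by
  noise alone — chosen a priori from the variance budget: a purely catalytic
  bridge path differs from the true path by `N(2μ, ≈1.2)` at n = 10 and
  would fail recovery a few percent of the time at μ = 1, swamping the
  designed behaviour of the other fixtures.

True paths start at sources and end at sinks by design: the maximal path
ends exactly where extending by a background neighbour stops paying, and at
graph boundaries there is nothing to extend into, so recovery measures the
scorer rather than boundary noise. Fixture truth is compared on *node sets*
(the reported focus), not edge sequences. What the simulator does **not**
emulate: heavy-tailed or count-based measurement error, missing proteins,
correlated background genes, node sets with more than one member, and
cyclic topologies — passing benchmarks here demonstrate correctness of the
machinery under the stated Gaussian model, not robustness to those realities.

## Variants

Four degraded statistics share the rotation machinery as internal baselines:
score divided by best-path node count (`length_normalized`); all multipliers
forced to `+1` (`unsigned`); the absolute whole-pathway sum over edges of
`E(reactant) + T·E(product)` (`whole_pathway_sum`); and the absolute mean of
`E` over member proteins (`set_based`). The harness treats statistics as
plug-ins `f(graph, summary) → float`, so external p-value tables from other
tools can be compared downstream without reimplementing those tools here.

## Benchmark harness and problem sizes

Experiments are defined by a grid (fixtures × μ × σ²_g × n × replicates) and
are bit-for-bit reproducible from (grid, seed); every cell records its
Monte-Carlo standard error. Rejection uses `p < α`. The shipped test suite
runs: recovery at μ = 1 with 400 replicates/fixture and at μ = 2 with
100/fixture; type-I with 1000 null datasets per fixture at R = 200
rotations; p-value uniformity over 1000 null datasets; and power curves
with 300 replicates at R = 100 on 3-point grids — sizes chosen so the whole
suite completes in a few minutes on one core while keeping standard errors
a small fraction of the tested margins. The benchmark CLI defaults to 1000
replicates/cell with a `--fast` cap of 100 for smoke runs.

## Numerical and degenerate-input choices

* Zero-edge pathways score 0 with an empty path and a `no-edges` flag (GMT
  sets fall in this class; only the set-based variant is meaningful there).
* Exact float equality between the dynamic programme and the enumerator is
  achievable because both fold the nested sum from the path's final node in
  the same association order.
* `dim = 1` rotations are ±1 with equal probability; orthogonality holds to
  1e-10 by construction (asserted in tests).
* Expression identifiers are treated as opaque strings; an analysis with no
  overlap between data and pathway identifiers aborts with examples of both
  styles rather than returning all-null results.
* `--threads` is accepted for interface compatibility but execution is
  sequential; results are therefore trivially thread-count invariant.

## Known limitations

* Cyclic pathway scores are heuristic (entry-order dependent by
  construction; fixed seeding order makes them deterministic).
* The unpaired summary requires positive group means; data containing
  negatives must be pre-shifted or supplied as paired ratios.
* π̂₀ estimation on uniform p-values has inherent sampling noise (sd ≈ 0.06
  at m = 1000); single-draw bounds on it are brittle by nature.
* The SBML importer is deliberately minimal: species-to-protein collapsing
  follows names only, modifiers map to edges by SBO term, and everything
  else (stoichiometry, compartments, kinetics) is ignored with a log entry.
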