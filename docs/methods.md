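# Methods

## Model

Given a log2 expression matrix X ∈ R^{m×n} (m genes, n samples), an
undirected gene interaction network G, and a subtype label per sample,
the package extracts sparse rank-one components

    max_{‖u‖₂=‖v‖₂=1}  uᵀ X v    subject to a sparsity constraint on u,

with three constraint families:

1. **L0**: ‖u‖₀ ≤ s. The projection of z = Xv keeps the s entries of
   largest magnitude; this projection is exact, so the alternating
   objective is non-decreasing and the iteration converges monotonically.
2. **Edge-group**: supp(u) must be covered by at most k network edges.
   An edge e_h = (i, j) is scored w_h = √(z_i² + z_j²) at the current
   direction z.
3. **Dynamic edge-group (supervised)**: for subtype p every gene carries
   a frozen nonnegative relevance weight t_pi = |Welch t| of that gene
   in subtype p's meta samples versus all other subtypes' meta samples
   (unpooled variances, sample (n−1) denominators), and the edge score
   becomes w_ph = √(t_pi z_i² + t_pj z_j²). Component p is solved on
   subtype p's reweighted network; with unit gene weights this reduces
   algebraically to family 2.

Genes are mean-centred inside the solver (`center=True`). On log2
microarray data the shared baseline (≈6 log2 units) otherwise dominates
every loading direction and the objective cannot discriminate between
selections; centring is the usual PCA convention and can be switched
off.

The Welch magnitude |t| is used rather than t or t² because
down-regulated markers are as informative as up-regulated ones; the t²
transform (same ranking, stronger contrast) is available via
`t_transform="square"`. The edge score uses the square root (a Euclidean
norm of the weighted endpoints); the no-root variant
(`edge_norm="sumsq"`) is a monotone relabelling that changes nothing for
unit gene weights but interacts with non-unit t.

## Meta-sample selection

Subtype cohorts contain atypical samples that distort per-gene
statistics. Before weighting, each subtype is reduced to its h most
stably central samples: K-means over all samples (K = number of
subtypes, full gene space, k-means++ with 10 restarts, tol 1e-6),
clusters matched to subtypes by Hungarian assignment on the contingency
table, and the h samples nearest (Euclidean) the matched centre marked;
after `repeats` independent clusterings (default 10, seeds seed+r) the
samples marked in at least `stability_threshold` of the repeats
(default 1.0 — every time) are kept. If no sample survives the
threshold, the h most frequently marked samples are taken, ties broken
by smaller mean distance and then sample id, so the selection is never
empty and always deterministic. Defaults for h: the estimator uses half
the smallest subtype (at least 2) — enough samples for a stable Welch
denominator while still discarding the outlying half. Distances are
computed on unstandardised log2 values; a standardisation flag is
deliberately absent from the default path because the inputs share one
measurement scale.

## Solver

Selecting the k-edge group that maximises the retained ‖z‖ is NP-hard
(edge groups overlap), so the projection is randomised greedy: rank all
edges by weight, keep the top ⌊(1+ω)k⌋ as candidates I, sample k of
them uniformly without replacement (J_k), and set u to z restricted to
J_k's endpoints, normalised. ω shrinks by ρ once per outer (u, v)
iteration, ω ← max(0, ω − ρ), reaching 0 in finitely many steps;
convergence (relative objective change < tol, default 1e-6) is only
tested once ω = 0, and the *final* iterate is returned — by then the
projection is the pure greedy rule, so the returned support is a fixed
point of the deterministic algorithm. Returning the best-objective
iterate instead is tempting but subtly wrong here: because edge groups
overlap, swapping a redundant within-module edge for any background
edge adds vertices and strictly increases the retained norm, so the
maximum over a randomised trajectory systematically favours
contaminated supports.

Non-convergence at `max_iter` (default 200) returns the last iterate
with a warning flag, never an exception. A zero direction z (possible
after deflation) yields a zero component with a warning. Ties in edge
and gene rankings break lexicographically (edge id, then gene id) for
bit-reproducibility; ⌊(1+ω)k⌋ uses the floor so the candidate budget is
never exceeded, and both the candidate set and the sample are capped at
the number of available edges.

**Initialisation.** Unsupervised modes start each restart from a random
unit v (seeded), optionally the leading right singular vector for
restart 0 (`svd_init`). The supervised model defaults to a
subtype-indicator warm start (v₀ ∝ 1{sample ∈ subtype p}) for every
restart of component p (`init="subtype"`; `init="random"` restores
fully random starts). The reason is structural: the objective uᵀXv does
not see the subtype — only the constraint search does — so with random
starts the best-of-restarts rule lets component p capture whichever
subtype's module happens to carry the most variance. The indicator
start points the search into subtype p's basin, which is exactly the
attribution the supervised model promises; restarts then differ through
the randomised projection stream.

**Restarts and seeding.** All randomness flows from one root seed
through named substreams (`numpy` SeedSequence spawning, one child per
(component, restart)), so the same root seed reproduces a fit
bit-for-bit and restart streams are prefix-stable (the first restart of
a 1-restart run and a 20-restart run coincide).

**Multiple components.** After each component, Hotelling deflation
X ← X − (uᵀXv)·u vᵀ removes the extracted rank-one structure. Genes may
reappear in later components (no exclusion rule); in the supervised
mode component p uses subtype p's network, in subtype first-appearance
order, so the number of components is capped by the number of subtypes.

## Evaluation

* Clustering accuracy: K-means (K = number of subtypes) on the
  selected-gene submatrix, scored under the optimal one-to-one
  cluster↔subtype assignment (Hungarian on the contingency table).
* Per-gene significance: two-sided Welch t test (scipy), target subtype
  vs rest, all samples; constant genes get p = 1 by convention.
* Classification: stratified 5-fold CV of KNN (k=5), RBF SVM (C=1), L2
  logistic regression, and a 100-tree random forest on the
  selected-gene submatrix; macro-averaged precision/recall/F1 plus
  accuracy, averaged over five seeded CV runs. Macro averaging is used
  because subtype classes are imbalanced in general.

## Synthetic benchmark

The generator emulates a log2 microarray cohort: baseline 6.0 with
Gaussian noise (sd 1.0), P disjoint planted modules (one per subtype,
default 20 genes each) up-shifted by `effect` (default +5 log2 units)
in exactly their subtype's samples, each module wired as a random
spanning tree plus 10 extra within-module chords (29 edges per module,
equal across subtypes by construction), drowned in 2000 uniformly
random background edges, with an optional fraction of decoy probes
parked below the log2-intensity floor of 4. Everything is a
deterministic function of the seed.

What it does *not* emulate: batch effects, probe cross-hybridisation,
heavy-tailed or correlated noise, overlapping modules,
partially-connected modules, or label noise. Tests passing on this
generator therefore demonstrate the mechanics of the method — correct
weighting, projection, attribution, calibration — not performance on
real cohorts, where effect sizes are smaller and module boundaries
blurrier.

The test and acceptance runs use desk-scale problem sizes chosen to
exercise every code path while keeping the suite quick: the benchmark
instance is 500 genes × 100 samples (4 subtypes × 25) with ~2100 edges,
recovery is measured over 20 seeds, and the oracle comparisons use
instances small enough for exact enumeration (≤12 edges, k ≤ 3, where
the global optimum is the maximum leading singular value over all
vertex-restricted submatrices).

## Hand-checkable worked instance

`small_worked_instance()` ships a fixed 6-gene × 8-sample × 7-edge
instance (two subtypes of four samples). For gene A the subtype-one
values are 8.0, 8.2, 7.8, 8.1 (mean 8.025) and the subtype-two values
4.0, 4.2, 3.8, 4.1 (mean 4.025); both groups have sample variance
0.0875/3, so t_A = 4 / √(2·(0.0875/3)/4) = 33.1232…. Gene B's +2 shift
with deviations ±0.05, ±0.15 gives variance 0.05/3 and
t_B = 2 / √(2·(0.05/3)/4) = 21.9089…. Gene F is constant and gets
weight 0 with a logged warning. The unit tests assert these numbers.

## Known limitations

* The randomised search improves on greedy but carries no optimality
  guarantee; the alternation is a local method and the non-convex
  problem admits many fixed points.
* Gene weights are frozen from the meta samples for the whole solve;
  they do not adapt as u evolves (only the z-dependent part of the edge
  weight is dynamic).
* The edge budget k is a user choice; the package does not select it.
* Identifiers are opaque strings: no probe→symbol mapping, no handling
  of many-to-one probe sets.
* The supervised warm start assumes the labels are trustworthy; with
  heavily mislabelled cohorts `init="random"` plus more restarts may be
  preferable, at the cost of attribution stability.
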