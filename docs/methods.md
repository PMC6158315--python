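# Methods

This note records the statistical model, the algorithmic variants, and
the design decisions behind `coexnet`, in the spirit of a methods
appendix: what is computed, under which conventions, and what the
synthetic benchmarks do and do not demonstrate.

## Correlation

All association is Pearson's product-moment correlation, computed over
*pairwise-complete* observations: for a variable pair, only strains
where both values are present enter the sums. A correlation is
**undefined** — never an edge, never counted in a degree — when fewer
than `min_obs` complete pairs exist (default 5; three points or fewer
make the estimate degenerate, and five is a conservative floor for a
panel where a trait may cover only half the expression strains) or when
either side has (numerically) zero variance. Computed values are clipped
to [−1, 1] to absorb floating-point overshoot.

The vectorised implementation uses the moment identity on masked sums
(`n`, `Σx`, `Σy`, `Σx²`, `Σy²`, `Σxy` accumulated over the shared
mask), which is algebraically exact for pairwise deletion; tests compare
it against a naive two-pass loop at 1e−10.

For transcriptome-scale inputs the full transcript × transcript matrix
is never materialised: `seed_network` computes seed-versus-all rows,
collects the above-threshold correlates, and only then computes the
all-pairs block on that union.

## Network construction

`threshold_network` keeps an edge (i, j), i ≠ j, iff r is defined and
r ≥ τ (signed mode, the default) or |r| ≥ τ (absolute mode). Edge weight
is r itself; all matrix nodes are retained, so isolated nodes exist and
are reported. Thresholds are nested by construction: raising τ can only
remove edges, down to the empty edge set at τ = 1 and up to the complete
(n² − n)/2 edge count at τ → 0 on all-positive matrices.

Signed mode with τ = 0.6 is the package default: positive co-expression
is the biologically interpretable relation for this analysis, and 0.6
sits at the low end of the scale-free-stable range on the data this
pipeline is designed around. Absolute mode is provided for analyses that
treat strong negative correlation as equally informative.

## Threshold selection by scale freedom

The degree distribution assigns each *distinct positive* degree k its
empirical probability among nodes of degree ≥ 1. Zero-degree nodes are
excluded from numerator and denominator — their log-degree is undefined
and a thresholded correlation network can contain arbitrarily many of
them — so the listed probabilities always sum to 1.

The fit is ordinary least squares of log₁₀ p on log₁₀ k over the raw
points: no logarithmic binning, no maximum-likelihood exponent
estimation. This mirrors how such log-log plots are drawn and judged by
eye, which is the judgment the selection rule encodes; a Clauset-style
bootstrap test is a deliberate non-goal. With constant p the slope is 0
and r² is reported as 0. The base-10 choice only shifts the intercept.

`select_threshold` returns the *smallest* scanned τ with r² ≥ 0.8 and at
least 5 distinct degrees: the largest network still inside the power-law
regime. The r² floor is a tunable default, not a claim that 0.8
reproduces any particular visual judgment.

## Centrality panel

All five measures run on the unweighted topology (an edge either
survived the threshold or it did not); correlation magnitude is kept as
edge weight for reporting only. Scores are computed on the full network
including trait nodes; ranked report tables can then filter to
transcripts, so traits shape the scores without appearing in gene
rankings.

* **Degree** — neighbour count.
* **Betweenness** — Brandes' dependency accumulation over BFS DAGs,
  *unnormalised*, each unordered pair counted once (leaves score exactly
  0). Unnormalised counts are the more legible quantity on a single
  fixed network.
* **Eigenvector** — principal eigenvector of the adjacency matrix by
  power iteration, started from a uniform positive vector and run on
  A + I. The shift leaves eigenvectors untouched but makes the spectrum
  positive, so iteration also converges on bipartite-like structures
  (e.g. stars) where plain iteration on A oscillates between ±λ₁.
  Scores are scaled so the maximum is 1; nodes outside the component
  carrying the principal eigenvalue decay to ≈ 0. Tolerance 1e−10 on the
  sup-norm change, at most 10000 sweeps, `ConvergenceError` with the
  last residual otherwise.
* **Closeness** — c(v) = |R(v)| / [(n − 1) · d̄(v)], where R(v) is the
  set of nodes reachable from v and d̄(v) their mean hop distance. On a
  connected graph this is classical (n − 1)-normalised closeness; on a
  disconnected graph the reachable-fraction damping keeps scores on one
  comparable [0, 1] scale and gives isolated nodes 0. Closeness has
  several formula variants in circulation for disconnected graphs; this
  choice is a documented decision, not a canonical fact.
* **PageRank** — fixed point of p = (1 − d)/n + d·(A D⁻¹)p on the
  undirected graph, damping d = 0.85 (the conventional default),
  isolated nodes redistributing their mass uniformly (dangling rule).
  Scores sum to 1 within 1e−9; L1 tolerance 1e−12.

Every measure is validated against independent oracles in the test
suite: exhaustive shortest-path enumeration and networkx for
betweenness, dense eigendecomposition for eigenvector, Floyd–Warshall
distances for closeness, an exact linear solve and networkx for
PageRank.

## Distances, levels, degrees of separation

Distances are unweighted hop counts by breadth-first search with sorted
neighbour iteration (all outputs deterministic). Unreachable nodes carry
an infinite sentinel, serialized as `Inf` in reports.

The per-seed level table is **cumulative**: row k counts distinct
non-seed nodes with shortest-path distance ≤ k, extending to the seed's
eccentricity where it saturates at (component size − 1). The seed itself
is excluded by convention; the ±1 choice matters when comparing against
externally published tables.

`mean_shortest_path` defaults to the mean over all mutually reachable
unordered pairs (`reachable_pairs`), the natural scope for a graph known
to be disconnected; `largest_component` restricts both endpoints to the
largest component. Degrees of separation = path length − 1: direct
neighbours are 0 degrees apart, and a fractional mean path maps to a
fractional mean separation.

## Layouts

Both layout algorithms are stress-style formulations chosen as the
minimal reading of "distance on the canvas reflects correlation"; the
objectives, schedules, and defaults below are implementation decisions.

**Force-directed.** Nodes start at seeded random positions in the unit
square and gradient-descend Σ_edges (‖p_u − p_v‖ − L(w))² with
L(w) = 1 − w, fixed step size (default 0.05), stopping after
`iterations` sweeps or when an iteration improves the objective by less
than 1e−9. A non-finite objective raises a divergence error suggesting a
smaller step.

**Constrained grid.** Nodes are assigned injectively to cells of an
R × C grid (default ⌈√n⌉ × ⌈√n⌉). Dissimilarity is d = 1 − r for
defined/connected pairs and a cap d_max = 1.5 for undefined or
unconnected pairs — larger than any connected pair's, which is what
pushes unconnected nodes to the periphery. The objective sums
(cell distance / grid diagonal − d/d_max)² over all near pairs
(d < d_max) plus a seeded per-node sample of far pairs (default 5),
keeping the cost far below O(n²) per sweep on large graphs.
Optimisation: the most-connected node is placed centrally, remaining
nodes greedily at their best free cell in decreasing connectivity order,
then a simulated-annealing phase proposes random swaps and relocations
with geometric cooling from t₀ = 0.02 down to a floor of 1e−6, below
which only improving moves are accepted. The best assignment seen is
returned and its objective recomputed from scratch, so the reported
value is exact for the reported layout.

Both layouts are bit-reproducible given inputs, parameters, and seed.

## Synthetic data generator

The generator emulates a recombinant-inbred panel: `n_strains`
expression strains of which a fraction (default 31/69) is also
phenotyped, with a latent factor model planting co-expression:

    x_ts = λ_t f_{m(t),s} + ε_ts,   ε ~ N(0, σ²),  f ~ N(0, 1)
    trait_j = Σ_m β_jm f_m + ν,     ν ~ N(0, 0.5²)

Defaults: 69 strains, 15000 transcripts, four modules of 150 transcripts
(λ = 2, σ = 1, hence within-module r = λ²/(λ²+σ²) = 0.8), four traits
named PROL, SURV, NEUR, ASTR with SURV/NEUR sharing a module (the
most-similar pair) and ASTR driven by its own module (the distinct
trait). The closed form r_ij = λ_iλ_j/√((λ_i²+σ²)(λ_j²+σ²)) is the
ground-truth oracle: tests check empirical correlations converge to it
(mean absolute deviation < 0.02 at 2000 strains) and that thresholding
at the expected within-module r minus 0.1 recovers planted module edges
with precision and recall ≥ 0.9.

An optional planted hub loads λ on *every* module. Its expected
correlation with any module transcript is
λ²/√((Gλ²+σ²)(λ²+σ²)) ≈ 0.496 for G = 3, λ = 2, σ = 1 — below the 0.7
module-recovery threshold — so hub-centrality checks threshold at 0.45,
derived from that closed form.

Reference graph generators provide the scale-free contrast:
preferential attachment (clique seed of m + 1 nodes, each newcomer
attaching to m distinct degree-proportional targets) versus
Erdős–Rényi G(n, p) at matched density.

**What the generator does not emulate:** microarray measurement error
structure, probe effects and normalisation artifacts, heavy-tailed or
non-Gaussian expression, linkage between modules, genotype data, or
heritability. Passing recovery tests therefore demonstrates the
*pipeline's* correctness on data satisfying its model assumptions, not
robustness to real microarray pathology — upstream preprocessing is
explicitly out of scope.

## Determinism and numerical conventions

* All randomness flows through `numpy.random.default_rng` seeds held in
  the relevant config (generator spec, layout calls, pipeline config);
  reruns are byte-identical.
* Ranking ties are always broken lexically by node id.
* Edge lists are written with node_a < node_b and six-decimal weights;
  long-format tables sort lexically — identical analyses diff clean.
* Variables with sum-of-squares below 1e−14·n are treated as constant.

## Problem sizes

The test-suite and acceptance-script benchmarks run at deliberately
modest scale, chosen so every quantity has an exact or closed-form
oracle: oracle-equivalence sweeps use 200 random graphs of ≤ 12 nodes;
module-recovery fixtures use 60 strains × 620 transcripts (3 × 40 module
transcripts + 500 background); scale-free contrasts use 2000-node
graphs; the end-to-end pipeline fixture uses 69 strains (31 phenotyped)
× 620 transcripts. The implementation itself handles transcriptome-scale
inputs via the seed-restricted correlation route.

## Known limitations

* Hop-count distances only; edge weights never enter path lengths.
* No p-values, multiple-testing control, or partial correlations —
  networks are thresholded on raw r by design.
* The closeness variant and the unnormalised betweenness convention are
  package decisions; compare against other tools' defaults with care.
* OLS on raw log-log points is a deliberately simple scale-freedom
  criterion; it is not a hypothesis test.
* Grid-layout quality degrades gracefully but is not guaranteed optimal;
  the annealing budget trades quality for time.
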