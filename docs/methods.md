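# Methods

## Network construction

Each subject enters as a symmetric ROI × ROI Pearson correlation matrix
(unit diagonal enforced on load; asymmetry above 1e-8 is an error, below it
the matrix is averaged with its transpose; a diagonal off unity by less
than 1e-3 is normalized with a logged notice).

Construction is maximum-spanning-tree + sparsity thresholding:

1. Kruskal MST over edge weights = correlations. Ties are broken by
   sorting candidate edges on `(-weight, smaller index, larger index)`,
   which makes every construction bit-reproducible. The tie-break (and the
   direct Kruskal implementation that enforces it) is a deliberate choice;
   a library MST without an ordering contract would not reproduce across
   runs on tied inputs.
2. Remaining node pairs are appended in the same deterministic order until
   the target count for the density is reached, then weights are dropped.

The **target edge count** for density *d* on *n* nodes is
`round_half_away_from_zero(d · n(n−1)/2)`, floored at the MST size *n−1*
and capped at the complete-graph count. The rounding rule is a declared
convention — proportional thresholding needs one and no single standard
exists. Ordering is by **signed** correlation, not absolute value; at high
densities negative-correlation edges can enter, and a warning is logged
when they do.

The default density grid is 0.02–0.50 inclusive in steps of 0.01
(49 networks per subject). Because the per-subject edge order is fixed,
stacks are nested: the network at density *d* is a subgraph of every
network at higher density, and all are connected by MST containment.

## Curvatures

**Augmented Forman–Ricci curvature.** The graph is treated as a
2-dimensional CW complex whose 2-cells are the triangles (3-cliques);
longer cycles are ignored. For the unweighted pipeline path the curvature
of edge *e = (i, j)* is `4 − deg(i) − deg(j) + 3·tri(e)` — an integer. The
general weighted form is implemented for completeness: direct terms sum
`w_e/w_f` over triangles containing *e* and `w_v/w_e` over its endpoints;
each *parallel* edge ê (sharing a vertex or a triangle with *e* but not
both) contributes `|Σ_f √(w_e w_ê)/w_f − Σ_v w_v/√(w_e w_ê)|` as a
penalty. In a simple graph two edges in a common triangle always share a
vertex, so the parallel set reduces to vertex-sharing edges without a
common triangle; at unit weights the expression collapses to the
combinatorial formula (verified by test on random graphs).

**Ollivier–Ricci curvature.** `O(e) = 1 − W1(m_i, m_j)/d(i, j)` with
`m_i` uniform over the neighbors of *i* and zero mass on *i* itself
(idleness 0; an optional idleness parameter is exposed but off by
default). Ground distances are hop counts on the **full graph** (BFS per
support node), since the graph metric — not the neighborhood subgraph —
defines the transport cost. W1 is solved exactly as a transportation LP
with the HiGHS simplex solver; optima are rounded to 12 decimals to
stabilize cross-platform floats. Single-support marginals short-circuit to
the closed form. For adjacent endpoints the supports lie within hop
distance 3 of each other, giving the bound −2 ≤ O(e) ≤ 1, asserted in
tests. The test suite cross-checks the LP against brute-force enumeration
of all integer-scaled transport plans on every connected graph with ≤ 5
nodes.

**Node curvature** is the sum of the curvatures of the incident edges
(hand-shake identity: node values sum to twice the edge total).

## Global measures

Eight standard measures per network: exact clique number (in-package
Tomita-style branch-and-bound with greedy-coloring bound and a wall-clock
budget — exceeding the budget raises rather than approximating), average
clustering coefficient, global efficiency, average normalized betweenness,
average local efficiency, average shortest path length, Louvain modularity
(resolution 1, seed 0 by default, the only seeded measure; reported Q is
recomputed from the returned partition), and degree assortativity, which
is flagged undefined (None) on regular graphs rather than coerced to 0.
Betweenness is normalized per node before averaging so values are
comparable across densities.

## Group statistics

- Per-measure, per-density two-tailed two-sample *t*-tests (pooled
  variance by default; Welch by flag). A zero-variance comparison returns
  t = 0, p = 1 when means agree and raises otherwise.
- Node-level comparison uses the trapezoidal AUC of node curvature over
  the density grid as the subject-level summary, one *t*-test per ROI.
- BH-FDR at α = 0.05. FDR families: densities within a measure (global),
  ROIs within a curvature method (node level), terms within an RSN
  (enrichment), ROI × subscore pairs within a behavioral test
  (correlations). The family choices are conventions of this package and
  are documented here because reasonable alternatives exist (e.g. pooling
  measures into one family).

## Term enrichment

The null resamples significant-set-sized ROI subsets from the **full**
atlas (not per-RSN), partitions each draw by RSN and counts term
occurrences identically to the observed set; 1,000 draws by default.
z = (observed − null mean)/null sd, converted to a one-sided upper-tail
normal p (enrichment is directional; a two-sided option exists). Terms
with a degenerate null (sd = 0) are flagged and excluded from the FDR
family with a warning.

## Phenotype correlations

Spearman rank correlation (mid-ranks for ties, two-sided t-approximation
p) between each significant ROI's curvature AUC and each behavioral
subscore, pooled across both groups by default; a group-restricted mode
exists because pooled correlations mix individual- and group-level
variation. The AUC (not a single-density curvature) is the ROI-level
quantity, consistent with the node-level group statistic.

## Synthetic cohorts

The generator emulates only what the statistics assume: group-structured
correlation differences. Per group, a block-constant correlation matrix
(blocks = pseudo-RSNs; within-block 0.35, between-block 0.10 by default —
values typical of parcel-level resting-state correlations). The old group
shifts correlations among the effect ROIs within their block by
`u_s · effect_size` (default +0.3), where `u_s ~ Uniform(0.5, 1.5)` per
old subject (young subjects: `u_s = 0`), creating both a group difference
and within-group variation. Matrices that lose positive definiteness are
repaired by clipping eigenvalues at 1e-6 and re-normalizing to unit
diagonal. Subject FC matrices are sample Pearson correlations of T = 300
i.i.d. multivariate-normal draws. Phenotype subscores are
`pheno_slope · u_s + Normal(0, 0.5)` with independent noise per subscore;
the term table gives every ROI `terms_per_roi` random terms and plants the
enriched terms on all effect ROIs.

What the generator does **not** model: temporal autocorrelation and
hemodynamics, head motion, negative-correlation structure, heterogeneous
within-block correlations, site/scanner effects. Passing tests therefore
demonstrate correctness of the pipeline and its calibration under the
stated generative model, not performance on real scans.

Default cohort: 60 ROIs in 3 blocks, 20 + 20 subjects, T = 300 — chosen as
the desk-scale condition at which exact-LP ORC remains tractable while the
planted effect is comfortably detectable. Pilot runs at this condition
(recorded in the acceptance suite) gave FRC node-level sensitivity 1.0 and
false-positive rate 0.004 against the frozen thresholds of 0.8 and 0.05.
Calibration tests run the null at reduced scale (24 ROIs, 10+10 subjects,
T = 80, a 10-density grid, 200 replicates) with FRC, the fast curvature;
the acceptance script's ORC recovery runs at 30 ROIs, 10+10 subjects,
10 densities. These problem sizes are the package's own defaults for
routine verification; all stages accept arbitrary sizes.

## Numerical conventions

- Transport optima and ORC values rounded to 12 decimals.
- Tables written with 12-significant-digit floats and `#` provenance
  headers (package version, config hash, seeds).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); a fixed seed reproduces every table
  byte-for-byte.

## Known limitations

- Exact-LP ORC costs ~2 ms per edge; cohort-scale ORC across a 49-density
  grid on hundreds of ROIs calls for coarser grids, smaller cohorts or
  parallelism. No approximate (Sinkhorn) transport is provided by design.
- The exact clique number can be exponential on dense networks; the time
  budget turns pathological instances into explicit errors.
- No weighted-network variants of the measures, no covariate adjustment in
  the statistics, and no neuroimaging-format readers: the package starts
  from correlation matrices.
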