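# Methods

This note records the statistical model behind `rsnhubs`, the conventions
and tunable parameters that matter, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## 1. From time series to difference networks

**FC construction.** Connectivity between two regions is the Pearson
correlation of their time courses, Fisher-z transformed
(`z = atanh(r)`). Correlations are clipped to `|r| <= 1 - 1e-7` before
`atanh` so that degenerate (collinear) inputs stay finite; the
perturbation to realistic values is below 1e-7. The diagonal is fixed at
0 and never treated as an edge; the edge universe is the upper triangle.
Per-run matrices are averaged element-wise per animal; whatever runs are
supplied are averaged (run-level QC is assumed to have happened upstream).

**Group contrast.** Each edge is tested with the classic pooled-variance
two-sample t (task minus control), df = n_a + n_b - 2. Pooled rather
than Welch was chosen because the designs this targets have matched,
similar-sized groups; Welch is available via `group_difference(...,
welch=True)`. Edges with zero pooled variance get t = 0, p = 1 and are
flagged rather than raising.

**Thresholding conventions.** t-score thresholds are inclusive
(`|t| >= tau`), p-value thresholds strict (`p < alpha`). Difference graphs
default to both tails — increases and decreases both count as
connections — with binary or |t| weights. Weighted shortest-path lengths
use `length = 1/weight`; clustering-type quantities and the
eigenvector/HITS spectra always use the binarized topology (the weighted
variants of those are not well standardized, and binarized is what the
hub analyses require).

## 2. Graph metrics

* **Global efficiency** `E = (1/n) sum_i [sum_{j!=i} d_ij^-1 / (n-1)]`;
  unreachable pairs contribute 0, so E is defined on disconnected graphs.
* **Modularity** uses Newman's leading-eigenvector recursive bisection on
  the (generalized) modularity matrix with a deterministic
  Kernighan–Lin-style fine-tuning pass (each node moved at most once per
  bisection, best configuration kept). Q is then evaluated with the
  standard `sum_u [e_uu - a_u^2]` form on the returned partition. The
  procedure is deterministic for a fixed input; on block fixtures with
  n <= 8 it matches exhaustive partition enumeration.
* **Transitivity** `T = sum 2 t_i / sum k_i (k_i - 1)` on the binarized
  graph; 0 when no node has two neighbors.
* **Closeness** is computed within each node's connected component,
  `(n_c - 1)/sum d`, and 0 for isolated nodes — the usual toolbox
  convention, since the textbook formula is undefined across components.
* **Betweenness** uses the ordered-pair normalization `1/((n-1)(n-2))`,
  identical to the standard normalized undirected definition.
* **HITS hub scores.** On an undirected graph the hub/authority fixed
  point is the Perron eigenvector of the adjacency. The literal
  alternating iteration (h <- A a, a <- A h) converges into the top
  eigenspace of A^2, which is degenerate on bipartite graphs (on a
  3-path it fixes the uninformative uniform vector). The implementation
  therefore power-iterates on A + I — the same eigenvectors with a
  strictly dominant top eigenvalue per component — with tolerance 1e-10
  and a 1000-iteration cap.
* **Giant component** ties break toward the component containing the
  smallest node index; an edgeless graph has giant size 1.
* **Metric-vs-threshold curves** run over t = 2.0..3.8 (step 0.2) with
  trapezoid AUC. When a thresholded graph is empty a metric takes its
  degenerate value (efficiency 0, modularity 0, transitivity 0, giant
  component 1) and the grid point is flagged, so AUC is always defined.
* **Small-world indices** binarize each animal's FC at z = 0.01..0.07
  (step 0.01); the top threshold must leave no isolated node. C is the
  mean nodal clustering coefficient (Watts–Strogatz), deliberately
  distinct from transitivity; L is the characteristic path length over
  reachable pairs. The random reference is analytic Erdős–Rényi with
  matched n and mean degree: `C_rand = <k>/n`, `L_rand = ln n / ln <k>`;
  lambda = L/L_rand, gamma = C/C_rand, sigma = gamma/lambda.

## 3. Collective-influence hub ranking

`CI_l(i) = (k_i - 1) sum_{j in dB(i,l)} (k_j - 1)` with the frontier
`dB(i,l)` the set of nodes at graph distance exactly l; default l = 2
(larger radii give nearly identical rankings on these network sizes, at
higher cost). CI removal is *adaptive*: after each removal the CI values
are recomputed on the remaining graph. Ties break to the smallest node
index; when every CI is 0 (fragments of degree <= 1) the highest
remaining degree goes first, then smallest index. Centrality/HITS
comparison rankings are *static* — computed once on the intact graph —
matching standard practice for such comparisons; an adaptive variant
would be a different estimator, not a baseline.

Removal proceeds until a single node remains; `gc_ratio[k]` is the giant
size after the (k+1)-th removal over the intact giant size, so the curve
ends at `1/gc0` ("one node remaining" convention), and the sole survivor
closes the removal order so per-threshold ranks are a full permutation.
Collapse AUC is the trapezoid area of gc_ratio against the fraction of
nodes removed; method comparisons report `auc / auc_CI` (CI row exactly 1).

**Mean CI rank.** The difference network is binarized at p < 0.05, 0.01
and 0.005 (both tails), each graph restricted to non-isolated nodes. A
node isolated or absent at a threshold gets rank (present count) + 1 —
maximally uninfluential there, since it cannot shrink that graph's giant
component. Mean ranks are sorted ascending; the top 10 are tiered high
(1–3), middle (4–7), low (8–10). Behavior filtering then tests every
incident edge of a top node that is significant in the difference network
(p < 0.05 uncorrected) for Pearson correlation with the probe-test score
across the task-group animals (two-tailed p < 0.05), sorted by |r|.

## 4. Null models

**Degree/strength-preserving randomization.** Topology is rewired by
10 × |E| attempted double-edge swaps, each accepted only if the graph
stays simple — the binarized degree sequence is conserved exactly.
Weights are then reassigned stochastically: repeatedly pick a random
unfilled edge, rank its endpoints' remaining strength deficit among all
unfilled edges, and assign the unassigned weight of the same rank. The
weight multiset is conserved exactly and node strengths approximately
(strength correlation with the original typically > 0.8). A fully
deterministic greedy (largest weight onto largest deficit) was rejected:
on graphs where rewiring is a no-op — notably the *complete* weighted
difference graph used for AUC nulls — it would collapse the null to a
single point. Every draw is deterministic under its seed.

**Metric-AUC null.** The observed AUC comes from thresholding |t| over
the t grid; null AUCs from the same curve on randomizations of the full
weighted difference graph. Both one-sided add-one empirical p values are
reported.

**Permutation FWE for the common network.** The observed cascade is:
per-task edgewise t thresholded at p < 0.05 (uncorrected, both tails) →
intersection of the two tasks' edge sets (sign agreement recorded but not
required) → Pearson correlation of each common edge with behavior across
the pooled task-group animals of both cohorts, kept at two-tailed
p < 0.05. Each permutation independently reshuffles group labels within
each task, preserving group sizes; behavior scores travel with their
animals (controls also carry probe scores). The FWE p is the add-one
upper-tail proportion of null surviving-edge counts. The behavior pool is
the permuted task-group animals, mirroring the observed case. The
headline overlap fraction uses the union of the two edge sets as the
denominator; all raw counts are reported because the natural denominator
is ambiguous.

**FWE discreteness.** The surviving-edge count is a small integer. At a
pure null with 40 regions and alpha 0.05 at each stage its mean is
~0.1, so the count is 0 in ~90% of datasets and the permutation p is 1
there; p <= 0.05 effectively requires a count of 2+. The estimator is
exchangeable and therefore *valid* (type-I rate ~0.008 <= 0.05 measured
over 500 null cohorts) but strongly conservative — "fraction of null
datasets with p <= 0.05" lands near 0.005, not near 0.05. Calibration
bands that presume a continuous statistic will read as failures for this
reason, not because the test is broken. With realistic signal (several
common edges) the discreteness relaxes and the test behaves as expected.

## 5. Synthetic cohorts: what they emulate, and what not

The generator draws regional time series from zero-mean multivariate
normals. The control covariance is block-diagonal compound symmetry
(`base_modules` blocks, within-block correlation 0.3, unit variances) —
a coarse stand-in for modular resting-state covariance. The task
covariance adds `delta` to each planted edge, with eigenvalue clipping at
1e-8 as a PSD safety net (the default worlds never need it). Behavior is
`beta * (mean planted-edge Fisher-z FC of that animal) + N(0, noise_sd)`
— crucially the *realized* FC, so finite-sample FC noise propagates into
behavior exactly as the analysis assumes. All animals (controls included)
receive behavior scores. Defaults: 40 regions, 10 animals per group per
task, two tasks, 3 runs of 2000 timepoints, seed-deterministic output
(byte-identical for identical config + seed).

Deliberately *not* modeled: hemodynamic convolution, autocorrelated or
1/f noise, scanner artifacts, sedation effects, inter-animal covariance
heterogeneity, run-level QC exclusions. A green planted-recovery test
therefore establishes that the pipeline recovers structure of the planted
kind at the planted strength under iid-Gaussian sampling noise — not that
it is robust to physiological confounds.

**Effect-size calibration.** Covariance-level deltas are calibration
knobs, not literature quantities. The Fisher-z sampling SD of one run of
T timepoints is ~`1/sqrt(T-3)`, so a target edgewise Cohen's d maps to
`delta = tanh(d / sqrt(T-3))` (cross-module edges; within-module edges
sit on a 0.3 baseline, shifting d by ~10%). Recovery simulations use
T = 200, one run, d ~ 1.5 — chosen once for runtime, since d (not T)
determines test power. Because behavior couples to the *mean* of K
planted edges, any single edge's behavior correlation is ceiling-limited
at ~`1/sqrt(K)`; power analyses of the common-network cascade must
account for this dilution (see the decisions shipped with the test
suite: with K = 3, per-edge ceiling ~0.58 against the ~0.44 needed at
n = 20, the cascade detects the planted network in ~78% of seeds).

**Planted graphs.** `generate_planted_graph` builds `n_modules` dense
blocks (edge probability `intra_p`) plus `bridge_nodes` connector nodes,
each linked to exactly one random node per block; bridges occupy the
final indices and carry `bridge*` labels. These are the fixtures for the
percolation-method comparison: bridges are low-degree but high-CI, so
adaptive CI dismantles these graphs faster than any static centrality
(CI AUC <= degree AUC on 100/100 seeded instances).

## 6. Known limitations

* Spectral modularity is a heuristic; it matches exhaustive enumeration
  on small block fixtures but carries no global optimality guarantee.
* Strength preservation in the randomized null is approximate by design
  (exact joint degree+strength conservation is infeasible in general);
  the exact contracts are the degree sequence and the weight multiset.
* The permutation FWE p is conservative at very sparse signal (see §4).
* Adaptive CI recomputation is O(n · E) per removal — fine for
  230-region networks, not intended for graphs with 10^5+ nodes.
* The CLI reads cohorts in the layout written by `rsnhubs simulate`
  (per-animal FC CSVs + cohort TSV); arbitrary external layouts should go
  through the library functions.
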