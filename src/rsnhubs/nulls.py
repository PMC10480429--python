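"""Null models and permutation inference.

Two null families back the pipeline's claims:

* degree/strength-preserving randomizations of the weighted difference
  network, giving empirical nulls for metric-curve AUCs (integration and
  segregation beyond what degree structure alone explains);
* group-label permutations of the per-animal FC matrices, giving a
  family-wise-error-controlled null for the count of behavior-correlated
  common-network connections.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import metrics as _metrics
from .containers import (
    CohortDataset,
    CommonNetworkResult,
    DiffNetwork,
    EdgeBehaviorCorrelation,
    NullDistribution,
    ThresholdedGraph,
    edge_index,
)


def randomize_preserving_degree_strength(g: ThresholdedGraph, seed: int) -> ThresholdedGraph:
    """Rewire a weighted graph preserving degrees exactly and strengths approximately.

    Topology is randomized by attempted double-edge swaps (10 x |E|
    attempts, each accepted only if the result stays simple), which
    preserves the binarized degree sequence exactly.  Weights are then
    reassigned to the rewired edges by strength-rank matching: repeatedly
    pick a random free edge, rank its endpoints' remaining strength deficit
    among the free edges, and give it the free weight of matching rank.
    The weight multiset is preserved exactly; node strengths approximately.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i, j, _ in g.edge_list()]
    weights = np.array([w for _, _, w in g.edge_list()])
    n_e = len(edges)
    if n_e < 2:
        warnings.warn("graph too small to swap; returning an unrewired copy")
        return ThresholdedGraph(adjacency=g.adjacency.copy(), node_labels=list(g.node_labels))

    edge_set = set(edges)
    edge_arr = list(edges)
    for _ in range(10 * n_e):
        e1, e2 = rng.integers(n_e), rng.integers(n_e)
        if e1 == e2:
            continue
        a, b = edge_arr[e1]
        c, d = edge_arr[e2]
        # propose (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edge_arr[e1])
        edge_set.discard(edge_arr[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edge_arr[e1] = new1
        edge_arr[e2] = new2

    # strength-rank-matched weight reassignment
    target = g.strengths.astype(float)
    deficit = target.copy()
    ew = np.array(edge_arr)  # n_e x 2
    w_sorted = np.sort(weights)[::-1]
    w_alive = np.ones(n_e, dtype=bool)
    e_alive = np.ones(n_e, dtype=bool)
    adj = np.zeros_like(g.adjacency)
    for _ in range(n_e):
        free = np.flatnonzero(e_alive)
        pick = free[rng.integers(len(free))]
        scores = deficit[ew[free, 0]] + deficit[ew[free, 1]]
        my_score = deficit[ew[pick, 0]] + deficit[ew[pick, 1]]
        rank = int((scores > my_score).sum())  # 0 = largest deficit
        w_idx = np.flatnonzero(w_alive)[rank]
        w = w_sorted[w_idx]
        u, v = ew[pick]
        adj[u, v] = adj[v, u] = w
        deficit[u] -= w
        deficit[v] -= w
        e_alive[pick] = False
        w_alive[w_idx] = False
    return ThresholdedGraph(adjacency=adj, node_labels=list(g.node_labels))


def metric_auc_null_test(
    diff: DiffNetwork,
    metric: str,
    n_null: int = 5000,
    t_range: np.ndarray | None = None,
    seed: int = 0,
    weighting: str = "abs_t",
) -> NullDistribution:
    """Empirical null for a metric-curve AUC from degree/strength-preserving nulls.

    The observed AUC comes from thresholding |t| over the grid; null AUCs
    come from the same curve on randomizations of the full weighted
    both-tail difference graph.  Both one-sided add-one p values are
    available on the returned distribution (``p_upper``, ``p_lower``).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    taus = _metrics.default_t_grid() if t_range is None else np.asarray(t_range, dtype=float)
    observed = _metrics.metric_curve(diff, metric, taus, weighting=weighting).auc
    w = np.abs(diff.t).copy()
    np.fill_diagonal(w, 0.0)
    base = ThresholdedGraph(adjacency=w, node_labels=list(diff.region_labels))
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_null)
    nulls = np.empty(n_null)
    for k in range(n_null):
        g_r = randomize_preserving_degree_strength(base, int(sub_seeds[k]))
        nulls[k] = _metrics.curve_from_weights(g_r.adjacency, metric, taus, weighting=weighting).auc
    return NullDistribution(
        statistic=f"{metric}_auc", observed=observed, null_samples=nulls, seed=seed
    )


def common_network_overlap(
    diff_task1: DiffNetwork,
    diff_task2: DiffNetwork,
    alpha: float = 0.05,
) -> CommonNetworkResult:
    """Edges significant (p < alpha, both tails) in both task contrasts.

    Overlap is by unordered edge identity; the per-task t signs are
    recorded but sign agreement is not required.  The headline fraction is
    n_common / n_union; raw counts are all reported.
    """
    if diff_task1.region_labels != diff_task2.region_labels:
        raise ValueError("difference networks must share the same region set")
    n = diff_task1.n_regions
    iu, ju = edge_index(n)
    m1 = diff_task1.p[iu, ju] < alpha
    m2 = diff_task2.p[iu, ju] < alpha
    both = m1 & m2
    common = [(int(iu[k]), int(ju[k])) for k in np.flatnonzero(both)]
    signs = {
        e: (int(np.sign(diff_task1.t[e])), int(np.sign(diff_task2.t[e])))
        for e in common
    }
    return CommonNetworkResult(
        common_edges=common,
        signs=signs,
        n_task1=int(m1.sum()),
        n_task2=int(m2.sum()),
        n_union=int((m1 | m2).sum()),
    )


def _group_stats(x: np.ndarray, sel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-permutation group sums and sums of squares: sel (P x n) @ x (n x E)."""
    return sel @ x, sel @ (x**2)


def _pooled_t_perm(x: np.ndarray, sel: np.ndarray, n1: int) -> np.ndarray:
    """Two-tailed pooled-t p values, vectorized over permutations.

    ``x`` is (n_animals, n_edges); ``sel`` is (n_perm, n_animals) with n1
    ones per row marking the task group.
    """
    n = x.shape[0]
    n2 = n - n1
    df = n - 2
    s1, ss1 = _group_stats(x, sel)
    st, sst = x.sum(axis=0), (x**2).sum(axis=0)
    s2, ss2 = st - s1, sst - ss1
    ssa = ss1 - s1**2 / n1
    ssb = ss2 - s2**2 / n2
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (s1 / n1 - s2 / n2) / se
    t = np.where(se == 0, 0.0, t)
    return 2.0 * stats.t.sf(np.abs(t), df)


def _behavior_r_perm(
    x1: np.ndarray, b1: np.ndarray, sel1: np.ndarray,
    x2: np.ndarray, b2: np.ndarray, sel2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r (and two-tailed p) of each edge with behavior, pooled over
    the task-group animals selected in both cohorts, per permutation."""
    n_pool = int(sel1[0].sum() + sel2[0].sum())
    sb = sel1 @ b1 + sel2 @ b2
    sbb = sel1 @ b1**2 + sel2 @ b2**2
    sx = sel1 @ x1 + sel2 @ x2
    sxx = sel1 @ x1**2 + sel2 @ x2**2
    sxb = sel1 @ (b1[:, None] * x1) + sel2 @ (b2[:, None] * x2)
    cov = sxb - sx * sb[:, None] / n_pool
    varx = sxx - sx**2 / n_pool
    varb = (sbb - sb**2 / n_pool)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(varx * varb)
    r = np.where(np.isfinite(r), r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n_pool - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    tstat = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), tstat)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return r, p


def _selection_matrix(groups: np.ndarray) -> np.ndarray:
    """1 x n identity selection row for the true task-group labels."""
    return (groups == "task").astype(float)[None, :]


def common_fwe_permutation(
    cohort_task1: CohortDataset,
    cohort_task2: CohortDataset,
    behavior_index: str = "n_shock",
    alpha_net: float = 0.05,
    alpha_beh: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> CommonNetworkResult:
    """Behavior-correlated common network with a permutation FWE null.

    Observed pipeline: per task, edgewise pooled two-sample t (task vs
    control) thresholded at p < alpha_net (uncorrected, both tails); the
    two edge sets are intersected; each common edge's z strength is
    Pearson-correlated with the behavior score across the pooled task-group
    animals of both cohorts and kept at two-tailed p < alpha_beh.  Each of
    ``n_perm`` permutations independently reshuffles group labels within
    each task (group sizes preserved; behavior scores travel with their
    animals) and recomputes the surviving-edge count.  FWE p is the add-one
    upper-tail proportion of null counts >= the observed count.
    """
    if cohort_task1.region_labels != cohort_task2.region_labels:
        raise ValueError("cohorts must share the same region set")
    for c in (cohort_task1, cohort_task2):
        if c.meta[behavior_index].isna().any():
            raise ValueError("every animal needs a behavior score")
        if not {"task", "control"} <= set(c.meta["group"]):
            raise ValueError("each task cohort needs both a task and a control group")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; FWE p will be coarse")

    x1 = cohort_task1.edge_matrix()
    x2 = cohort_task2.edge_matrix()
    b1 = cohort_task1.behavior(behavior_index)
    b2 = cohort_task2.behavior(behavior_index)
    g1 = cohort_task1.meta["group"].to_numpy()
    g2 = cohort_task2.meta["group"].to_numpy()
    n1_task = int((g1 == "task").sum())
    n2_task = int((g2 == "task").sum())

    def survivors(sel1: np.ndarray, sel2: np.ndarray) -> np.ndarray:
        p_net1 = _pooled_t_perm(x1, sel1, n1_task)
        p_net2 = _pooled_t_perm(x2, sel2, n2_task)
        common = (p_net1 < alpha_net) & (p_net2 < alpha_net)
        _, p_beh = _behavior_r_perm(x1, b1, sel1, x2, b2, sel2)
        return common & (p_beh < alpha_beh)

    sel1_obs = _selection_matrix(g1)
    sel2_obs = _selection_matrix(g2)
    obs_mask = survivors(sel1_obs, sel2_obs)[0]
    observed_count = int(obs_mask.sum())

    rng = np.random.default_rng(seed)

    def random_selection(n: int, k: int, size: int) -> np.ndarray:
        sel = np.zeros((size, n))
        for row in sel:
            row[rng.choice(n, size=k, replace=False)] = 1.0
        return sel

    sel1 = random_selection(len(g1), n1_task, n_perm)
    sel2 = random_selection(len(g2), n2_task, n_perm)
    null_counts = survivors(sel1, sel2).sum(axis=1)
    fwe_p = float(((null_counts >= observed_count).sum() + 1) / (n_perm + 1))

    # assemble the observed result with per-edge detail
    n_regions = cohort_task1.n_regions
    iu, ju = edge_index(n_regions)
    p_net1 = _pooled_t_perm(x1, sel1_obs, n1_task)[0]
    p_net2 = _pooled_t_perm(x2, sel2_obs, n2_task)[0]
    m1 = p_net1 < alpha_net
    m2 = p_net2 < alpha_net
    common_idx = np.flatnonzero(m1 & m2)
    common_edges = [(int(iu[k]), int(ju[k])) for k in common_idx]
    # per-task mean-difference signs on the common edges
    mean1 = x1[g1 == "task"].mean(axis=0) - x1[g1 == "control"].mean(axis=0)
    mean2 = x2[g2 == "task"].mean(axis=0) - x2[g2 == "control"].mean(axis=0)
    signs = {
        (int(iu[k]), int(ju[k])): (int(np.sign(mean1[k])), int(np.sign(mean2[k])))
        for k in common_idx
    }
    r_obs, p_obs = _behavior_r_perm(x1, b1, sel1_obs, x2, b2, sel2_obs)
    n_pool = n1_task + n2_task
    surviving = [
        EdgeBehaviorCorrelation(
            edge=(int(iu[k]), int(ju[k])),
            behavior_index=behavior_index,
            r=float(r_obs[0, k]),
            p=float(p_obs[0, k]),
            n=n_pool,
        )
        for k in np.flatnonzero(obs_mask)
    ]
    surviving.sort(key=lambda e: (-abs(e.r), e.edge))
    return CommonNetworkResult(
        common_edges=common_edges,
        signs=signs,
        n_task1=int(m1.sum()),
        n_task2=int(m2.sum()),
        n_union=int((m1 | m2).sum()),
        surviving=surviving,
        observed_count=observed_count,
        null_counts=np.asarray(null_counts),
        fwe_p=fwe_p,
    )
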