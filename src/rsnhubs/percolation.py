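"""Integrator-hub detection by collective-influence (CI) percolation.

CI_l(i) = (k_i - 1) * sum over nodes j exactly l steps from i of (k_j - 1):
a node is influential when it is well connected and sits near other
well-connected nodes.  Removing the current-maximum-CI node and recomputing
(adaptive removal) dismantles a network's giant component near-optimally;
comparing the collapse trajectory against static centrality/HITS removal
orders quantifies how much better CI finds integrator nodes.

Hub tiering follows the mean CI removal rank across several p-value
thresholds of a group-difference network; candidate hubs are then filtered
by whether their connections correlate with probe-test behavior.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd

from . import fc as _fc
from . import metrics as _metrics
from .containers import (
    CohortDataset,
    DiffNetwork,
    HubRanking,
    RemovalCurve,
    ThresholdedGraph,
)

STATIC_METHODS = ("degree", "closeness", "betweenness", "eigenvector", "HITS")


def _adjacency_sets(g: ThresholdedGraph) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(g.n_nodes)]
    for i, j, _ in g.edge_list():
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _ci_of(adj: list[set[int]], deg: np.ndarray, node: int, l: int) -> float:
    """CI of one node on the current (possibly pruned) adjacency."""
    if deg[node] <= 1:
        return 0.0
    # BFS to depth l; frontier at exactly distance l
    seen = {node}
    frontier = adj[node]
    for _ in range(l - 1):
        nxt = set()
        for u in frontier:
            nxt |= adj[u]
        seen |= frontier
        frontier = nxt - seen
        if not frontier:
            return 0.0
    frontier = frontier - seen
    if not frontier:
        return 0.0
    return float((deg[node] - 1) * sum(deg[j] - 1 for j in frontier))


def collective_influence(g: ThresholdedGraph, node: int, l: int = 2) -> float:
    """CI_l of a node on the binarized topology."""
    if not (0 <= node < g.n_nodes):
        raise ValueError(f"node {node} not in graph")
    if l < 1:
        raise ValueError("ball radius l must be >= 1")
    adj = _adjacency_sets(g)
    deg = np.array([len(a) for a in adj])
    return _ci_of(adj, deg, node, l)


def _giant_size(adj: list[set[int]], alive: np.ndarray) -> int:
    """Largest connected component among alive nodes (singletons count)."""
    n = len(adj)
    unvisited = set(np.flatnonzero(alive))
    best = 0
    while unvisited:
        start = unvisited.pop()
        size = 1
        dq = deque([start])
        while dq:
            u = dq.popleft()
            for v in adj[u]:
                if v in unvisited:
                    unvisited.discard(v)
                    size += 1
                    dq.append(v)
        best = max(best, size)
    return best


def ci_removal_sequence(g: ThresholdedGraph, l: int = 2) -> RemovalCurve:
    """Adaptive CI dismantling: remove the max-CI node, recompute, repeat.

    Ties break to the smallest node index; when every CI is zero the node
    with the highest remaining degree (then smallest index) goes next.
    Removal stops with one node left; that survivor closes
    ``removal_order``.  ``gc_ratio`` records giant size / intact giant size
    after each actual removal.
    """
    n = g.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    adj = _adjacency_sets(g)
    deg = np.array([len(a) for a in adj], dtype=float)
    alive = np.ones(n, dtype=bool)
    gc0 = _giant_size(adj, alive)
    order: list[int] = []
    ratios: list[float] = []
    for _ in range(n - 1):
        ci = np.full(n, -np.inf)
        for v in np.flatnonzero(alive):
            ci[v] = _ci_of(adj, deg, int(v), l)
        best = int(np.argmax(ci))  # argmax takes the smallest index on ties
        if ci[best] == 0.0:
            # degree fallback among alive nodes
            d = np.where(alive, deg, -np.inf)
            best = int(np.argmax(d))
        # remove
        alive[best] = False
        for u in adj[best]:
            adj[u].discard(best)
            deg[u] -= 1
        adj[best] = set()
        deg[best] = 0
        order.append(best)
        ratios.append(_giant_size(adj, alive) / gc0)
    order.append(int(np.flatnonzero(alive)[0]))
    return RemovalCurve(
        method="CI", removal_order=order, gc_ratio=np.array(ratios), n_nodes=n, gc0=gc0
    )


def static_removal_sequence(g: ThresholdedGraph, method: str) -> RemovalCurve:
    """Remove nodes in descending order of a centrality computed once.

    Scores come from the intact graph (degree, closeness, betweenness,
    eigenvector or HITS); ties break to the smallest node index.
    """
    if method not in STATIC_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {STATIC_METHODS}")
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    if method == "HITS":
        scores = _metrics.hits_scores(g)
    else:
        scores = _metrics.centrality(g, method)
    idx = np.arange(g.n_nodes)
    order_full = idx[np.lexsort((idx, -scores))]
    adj = _adjacency_sets(g)
    deg = np.array([len(a) for a in adj])
    alive = np.ones(g.n_nodes, dtype=bool)
    gc0 = _giant_size(adj, alive)
    ratios = []
    for v in order_full[:-1]:
        alive[v] = False
        for u in adj[v]:
            adj[u].discard(v)
        adj[v] = set()
        ratios.append(_giant_size(adj, alive) / gc0)
    return RemovalCurve(
        method=method,
        removal_order=[int(v) for v in order_full],
        gc_ratio=np.array(ratios),
        n_nodes=g.n_nodes,
        gc0=gc0,
    )


def compare_hub_methods(
    g: ThresholdedGraph,
    methods: tuple[str, ...] = ("CI",) + STATIC_METHODS,
    l: int = 2,
) -> pd.DataFrame:
    """AUC of the collapse curve per method, normalized by CI's AUC.

    Lower AUC = faster giant-component collapse = better integrator-hub
    detection.  The CI row has normalized_auc exactly 1.
    """
    if "CI" not in methods:
        raise ValueError("methods must include 'CI' (the normalization reference)")
    curves = {}
    for m in methods:
        curves[m] = ci_removal_sequence(g, l) if m == "CI" else static_removal_sequence(g, m)
    auc_ci = curves["CI"].auc
    rows = []
    for m in methods:
        a = curves[m].auc
        rows.append({"method": m, "auc": a, "normalized_auc": 1.0 if m == "CI" else a / auc_ci})
    return pd.DataFrame(rows)


def mean_ci_rank(
    diff: DiffNetwork,
    p_thresholds: tuple[float, ...] = (0.05, 0.01, 0.005),
    l: int = 2,
) -> HubRanking:
    """Mean CI removal rank across several p-value thresholds.

    Per threshold the both-tail difference network is binarized at p < alpha
    and restricted to non-isolated nodes; rank is the position (1-based) in
    the adaptive CI removal sequence.  Nodes absent (isolated) at a
    threshold get rank (present count) + 1 — maximally uninfluential there.
    Output is sorted by ascending mean rank; positions 1-3 of the top 10 are
    tier 'high', 4-7 'middle', 8-10 'low'.
    """
    n = diff.n_regions
    ranks = np.zeros((len(p_thresholds), n))
    any_edges = False
    for k, alpha in enumerate(p_thresholds):
        g_full = _fc.threshold_graph(diff, mode="p_value", value=alpha, tail="both", weighting="binary")
        present = np.flatnonzero(g_full.degrees > 0)
        if present.size == 0:
            ranks[k, :] = 1.0  # no node present: every rank is 0 + 1
            continue
        any_edges = True
        sub = ThresholdedGraph(
            adjacency=g_full.adjacency[np.ix_(present, present)],
            node_labels=[g_full.node_labels[i] for i in present],
        )
        curve = ci_removal_sequence(sub, l)
        n_present = present.size
        ranks[k, :] = n_present + 1
        for pos, local in enumerate(curve.removal_order):
            ranks[k, present[local]] = pos + 1
    if not any_edges:
        raise ValueError("all thresholded graphs are empty")
    mean_rank = ranks.mean(axis=0)
    idx = np.arange(n)
    order = idx[np.lexsort((idx, mean_rank))]
    tiers: dict[int, str] = {}
    for pos, node in enumerate(order[:10]):
        tiers[int(node)] = "high" if pos < 3 else ("middle" if pos < 7 else "low")
    return HubRanking(
        node_labels=list(diff.region_labels),
        thresholds=list(p_thresholds),
        ranks=ranks,
        mean_rank=mean_rank,
        order=order,
        tiers=tiers,
    )


def select_behavior_correlated_ci_nodes(
    ranking: HubRanking,
    cohort: CohortDataset,
    behavior_index: str,
    diff: DiffNetwork,
    top_k: int = 10,
    alpha_net: float = 0.05,
    alpha_beh: float = 0.05,
) -> pd.DataFrame:
    """Behavior-correlated connections of the top-ranked CI nodes.

    For each of the ``top_k`` best mean-CI-rank nodes, every incident edge
    significant in the difference network (p < alpha_net, uncorrected) is
    tested for Pearson correlation with the behavior score across the
    cohort's task-group animals; rows with two-tailed p < alpha_beh are
    returned sorted by |r| descending.
    """
    if ranking.node_labels != diff.region_labels:
        raise ValueError("ranking and difference network label mismatch")
    top = [int(v) for v in ranking.order[:top_k]]
    edges = []
    seen = set()
    for node in top:
        for j in np.flatnonzero(diff.p[node] < alpha_net):
            if j == node:
                continue
            e = (min(node, int(j)), max(node, int(j)))
            if e not in seen:
                seen.add(e)
                edges.append(e)
    rows = []
    if edges:
        corrs = _fc.behavior_correlation(cohort, behavior_index, edges, group="task", diff=diff)
        top_set = set(top)
        for c in corrs:
            if c.p < alpha_beh:
                i, j = c.edge
                hub = i if i in top_set else j
                partner = j if hub == i else i
                rows.append(
                    {
                        "node": hub,
                        "label": ranking.node_labels[hub],
                        "partner": partner,
                        "partner_label": ranking.node_labels[partner],
                        "r": c.r,
                        "p": c.p,
                        "cohen_d": c.cohen_d,
                        "mean_ci_rank": ranking.mean_rank[hub],
                        "tier": ranking.tier_of(hub),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "node", "label", "partner", "partner_label",
            "r", "p", "cohen_d", "mean_ci_rank", "tier",
        ],
    )
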