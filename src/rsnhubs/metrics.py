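"""Graph-theoretic integration and segregation metrics.

Global efficiency, Newman leading-eigenvector modularity, transitivity,
four classical centralities, HITS hub scores, giant-component size, module
composition, metric-versus-threshold curves with trapezoid AUC, and
small-world indices against an Erdős–Rényi analytic reference.

Integration metrics (efficiency, giant component) rise with long-range
connectedness; segregation metrics (modularity, transitivity) rise with
clustering into modules.  Weighted shortest paths use length = 1/weight;
clustering-type metrics and the eigenvector/HITS spectra run on the
binarized topology.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import numpy as np

from .containers import (
    DiffNetwork,
    FCMatrix,
    MetricCurve,
    SmallWorldResult,
    ThresholdedGraph,
)


def to_networkx(g: ThresholdedGraph, *, binarize: bool = False, as_length: bool = False) -> nx.Graph:
    """Convert to a networkx graph; optionally carry 1/weight as 'length'."""
    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    for i, j, w in g.edge_list():
        attrs = {"weight": 1.0 if binarize else w}
        if as_length and not binarize:
            attrs["length"] = 1.0 / w
        G.add_edge(i, j, **attrs)
    return G


def global_efficiency(g: ThresholdedGraph, weighted: bool = False) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0.

    E = (1/n) sum_i [ sum_{j != i} 1/d_ij / (n-1) ].  In weighted mode edge
    length is 1/weight, so strong edges are short.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    if weighted:
        G = to_networkx(g, as_length=True)
        dists = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    else:
        G = to_networkx(g, binarize=True)
        dists = dict(nx.all_pairs_shortest_path_length(G))
    total = 0.0
    for i in range(n):
        di = dists.get(i, {})
        total += sum(1.0 / d for j, d in di.items() if j != i and d > 0)
    return total / (n * (n - 1))


# ---------------------------------------------------------------------------
# Newman spectral modularity


def modularity_value(g: ThresholdedGraph, partition: list[set[int]]) -> float:
    """Q = sum_u [e_uu - (sum_v e_uv)^2] for a given node partition."""
    a = g.adjacency
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an empty graph")
    member = np.empty(g.n_nodes, dtype=int)
    for u, nodes in enumerate(partition):
        for v in nodes:
            member[v] = u
    q = 0.0
    for u in range(len(partition)):
        in_u = member == u
        e_uu = a[np.ix_(in_u, in_u)].sum() / two_m
        a_u = a[in_u, :].sum() / two_m  # = sum_v e_uv
        q += e_uu - a_u**2
    return float(q)


def _leading_split(b_sub: np.ndarray) -> np.ndarray | None:
    """One bisection of the (generalized) modularity matrix; None if indivisible."""
    vals, vecs = np.linalg.eigh(b_sub)
    lead = vals[-1]
    if lead <= 1e-10:
        return None
    u = vecs[:, -1]
    s = np.where(u >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        return None
    # Kernighan–Lin style fine-tuning: move each node once, in best-gain
    # order, keeping the best configuration seen.  Deterministic.
    best_s = s.copy()
    best_q = s @ b_sub @ s
    moved = np.zeros(len(s), dtype=bool)
    cur = s.copy()
    cur_q = best_q
    for _ in range(len(s)):
        gains = np.full(len(s), -np.inf)
        for i in np.flatnonzero(~moved):
            delta = -4.0 * cur[i] * (b_sub[i] @ cur) + 4.0 * b_sub[i, i]
            gains[i] = delta
        i = int(np.argmax(gains))
        if not np.isfinite(gains[i]):
            break
        cur[i] = -cur[i]
        moved[i] = True
        cur_q = cur_q + gains[i]
        if cur_q > best_q and not np.all(cur == cur[0]):
            best_q = cur_q
            best_s = cur.copy()
    if best_q <= 1e-10 or np.all(best_s == best_s[0]):
        return None
    return best_s


def modularity_spectral(g: ThresholdedGraph) -> tuple[float, list[set[int]]]:
    """Leading-eigenvector community detection with KL refinement.

    Recursively bisects the modularity matrix B = A - k k^T / 2m (generalized
    on subgraphs) until no split increases Q; returns Q of the final
    partition.  Deterministic for a fixed input.
    """
    a = g.adjacency
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an empty graph")
    k = a.sum(axis=1)
    b_full = a - np.outer(k, k) / two_m

    final: list[np.ndarray] = []
    stack = [np.arange(g.n_nodes)]
    while stack:
        nodes = stack.pop()
        if len(nodes) < 2:
            final.append(nodes)
            continue
        b_sub = b_full[np.ix_(nodes, nodes)].copy()
        # generalized modularity matrix: absorb row sums into the diagonal
        np.fill_diagonal(b_sub, np.diag(b_sub) - b_sub.sum(axis=1))
        s = _leading_split(b_sub)
        if s is None:
            final.append(nodes)
        else:
            stack.append(nodes[s > 0])
            stack.append(nodes[s < 0])
    partition = [set(int(v) for v in grp) for grp in final if len(grp)]
    # stable module order: by smallest member
    partition.sort(key=min)
    return modularity_value(g, partition), partition


def transitivity(g: ThresholdedGraph) -> float:
    """Global triangle density: sum 2 t_i over sum k_i (k_i - 1), binarized.

    Returns 0 when no node has degree >= 2 (no connected triples).
    """
    a = g.binarized()
    k = a.sum(axis=1)
    denom = (k * (k - 1)).sum()
    if denom == 0:
        return 0.0
    # t_i = (A^3)_ii / 2 triangles around node i
    tri2 = np.trace(a @ a @ a)  # = sum_i 2 t_i ... each triangle counted 6 times overall
    return float(tri2 / denom)


def centrality(g: ThresholdedGraph, method: str) -> np.ndarray:
    """Classical per-node centralities on the binarized topology.

    degree: k_i; closeness: (n_c - 1)/sum d within each node's component
    (0 for isolated nodes); betweenness: shortest-path load, normalized by
    (n-1)(n-2) over ordered pairs; eigenvector: principal eigenvector of the
    binarized adjacency, nonnegative, unit max-norm.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    G = to_networkx(g, binarize=True)
    if method == "degree":
        return g.degrees.astype(float)
    if method == "closeness":
        c = nx.closeness_centrality(G, wf_improved=False)
        return np.array([c[i] for i in range(g.n_nodes)])
    if method == "betweenness":
        c = nx.betweenness_centrality(G, normalized=True)
        return np.array([c[i] for i in range(g.n_nodes)])
    if method == "eigenvector":
        if g.n_edges == 0:
            raise ValueError("eigenvector centrality undefined on an edgeless graph")
        a = g.binarized()
        vals, vecs = np.linalg.eigh(a)
        v = vecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        return v / v.max()
    raise ValueError(f"unknown centrality method {method!r}")


def hits_scores(g: ThresholdedGraph, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Hub scores from the HITS mutual-reinforcement iteration.

    On an undirected graph hub and authority scores coincide with the
    Perron (principal) eigenvector of the binarized adjacency.  The raw
    h <- A a, a <- A h recursion stalls on bipartite graphs (its limit
    lives in the degenerate eigenspace of A^2), so the power iteration
    runs on A + I, which has the same eigenvectors with a strictly
    dominant top eigenvalue on every connected component.
    """
    if g.n_edges == 0:
        raise ValueError("HITS requires at least one edge")
    a_mat = g.binarized() + np.eye(g.n_nodes)
    n = g.n_nodes
    h = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        h_new = a_mat @ h
        h_new /= np.linalg.norm(h_new)
        resid = np.abs(h_new - h).max()
        h = h_new
        if resid < tol:
            return h
    raise RuntimeError(f"HITS failed to converge; residual {resid:.3e}")


def giant_component(g: ThresholdedGraph) -> tuple[int, frozenset[int]]:
    """Largest connected component; ties go to the component whose minimum
    node index is smallest.  An edgeless graph has giant size 1."""
    G = to_networkx(g, binarize=True)
    comps = list(nx.connected_components(G))
    if not comps:
        return 0, frozenset()
    best = max(comps, key=lambda c: (len(c), -min(c)))
    return len(best), frozenset(best)


def module_composition(g: ThresholdedGraph, partition: list[set[int]]) -> tuple[int, float]:
    """Module count and the fraction of edges inside modules (sum_u e_uu)."""
    covered = set().union(*partition) if partition else set()
    if covered != set(range(g.n_nodes)):
        raise ValueError("partition must cover all nodes")
    member = np.empty(g.n_nodes, dtype=int)
    for u, nodes in enumerate(partition):
        for v in nodes:
            member[v] = u
    edges = g.edge_list()
    if edges:
        intra = sum(1 for i, j, _ in edges if member[i] == member[j]) / len(edges)
    else:
        intra = 0.0
    n_modules = sum(1 for nodes in partition if nodes)
    return n_modules, intra


# ---------------------------------------------------------------------------
# metric-versus-threshold curves

#: value used when a metric is undefined on an (empty) thresholded graph
DEGENERATE_VALUE = {
    "giant_component": 1.0,
    "global_efficiency": 0.0,
    "modularity": 0.0,
    "transitivity": 0.0,
}


def _eval_metric(g: ThresholdedGraph, metric: str, weighted: bool) -> tuple[float, bool]:
    if g.n_edges == 0 and metric in DEGENERATE_VALUE:
        return DEGENERATE_VALUE[metric], True
    if metric == "giant_component":
        return float(giant_component(g)[0]), False
    if metric == "global_efficiency":
        return global_efficiency(g, weighted=weighted), False
    if metric == "modularity":
        return modularity_spectral(g)[0], False
    if metric == "transitivity":
        return transitivity(g), False
    raise ValueError(f"unknown metric {metric!r}")


def default_t_grid() -> np.ndarray:
    """The standard t-score threshold grid, 2.0 to 3.8 in steps of 0.2."""
    return np.round(np.arange(2.0, 3.8 + 1e-9, 0.2), 10)


def metric_curve(
    diff: DiffNetwork,
    metric: str,
    t_range: np.ndarray | None = None,
    weighting: str = "binary",
) -> MetricCurve:
    """Evaluate a metric on |t|-thresholded graphs over a t grid; AUC by trapezoid."""
    taus = default_t_grid() if t_range is None else np.asarray(t_range, dtype=float)
    if len(taus) < 2 or np.any(np.diff(taus) <= 0):
        raise ValueError("t_range must be increasing with at least 2 points")
    return curve_from_weights(np.abs(diff.t), metric, taus, weighting)


def curve_from_weights(
    weight_matrix: np.ndarray,
    metric: str,
    taus: np.ndarray,
    weighting: str = "binary",
) -> MetricCurve:
    """Metric curve for an arbitrary symmetric nonnegative weight matrix,
    thresholded inclusively (weight >= tau) at each grid point."""
    w = np.abs(np.asarray(weight_matrix, dtype=float))
    np.fill_diagonal(w, 0.0)
    labels = [str(i) for i in range(w.shape[0])]
    values, flags = [], []
    for tau in taus:
        keep = w >= tau
        adj = keep.astype(float) if weighting == "binary" else np.where(keep, w, 0.0)
        g = ThresholdedGraph(adjacency=adj, node_labels=labels)
        v, fl = _eval_metric(g, metric, weighted=(weighting != "binary"))
        values.append(v)
        flags.append(fl)
    return MetricCurve(metric=metric, thresholds=taus, values=np.array(values), flagged=np.array(flags))


# ---------------------------------------------------------------------------
# small-world indices


def default_z_grid() -> np.ndarray:
    return np.round(np.arange(0.01, 0.07 + 1e-9, 0.01), 10)


def small_world(fc: FCMatrix, z_thresholds: np.ndarray | None = None) -> SmallWorldResult:
    """Small-world lambda/gamma/sigma over a Fisher-z threshold grid.

    Per threshold the FC matrix is binarized at z >= tau; C is the mean
    nodal clustering coefficient (Watts–Strogatz) and L the characteristic
    path length.  The random reference is the analytic Erdős–Rényi
    approximation with matched size and mean degree: C_rand = <k>/n,
    L_rand = ln(n)/ln(<k>).  lambda = L/L_rand, gamma = C/C_rand,
    sigma = gamma/lambda.

    The maximum threshold must leave no node isolated, mirroring the
    convention that the grid top is the sparsest fully-connected level.
    """
    taus = default_z_grid() if z_thresholds is None else np.asarray(z_thresholds, dtype=float)
    z = fc.z
    n = fc.n_regions
    top = taus.max()
    deg_top = ((z >= top) & ~np.eye(n, dtype=bool)).sum(axis=1)
    if (deg_top == 0).any():
        bad = int(np.argmax(deg_top == 0))
        raise ValueError(
            f"graph has an isolated node (region {fc.region_labels[bad]}) at the "
            f"maximum threshold z = {top}"
        )
    lams, gams, sigs = [], [], []
    for tau in taus:
        adj = ((z >= tau) & ~np.eye(n, dtype=bool)).astype(float)
        G = nx.from_numpy_array(adj)
        c = nx.average_clustering(G)
        # characteristic path length over reachable pairs
        total, cnt = 0.0, 0
        for _, dists in nx.all_pairs_shortest_path_length(G):
            for j, d in dists.items():
                if d > 0:
                    total += d
                    cnt += 1
        L = total / cnt if cnt else np.inf
        k_mean = adj.sum() / n
        c_rand = k_mean / n
        l_rand = np.log(n) / np.log(k_mean)
        lam = L / l_rand
        gam = c / c_rand
        lams.append(lam)
        gams.append(gam)
        sigs.append(gam / lam)
    return SmallWorldResult(
        thresholds=taus, lam=np.array(lams), gamma=np.array(gams), sigma=np.array(sigs)
    )
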