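"""Shared fixtures: hand-built graphs and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from rsnhubs import SyntheticCohortConfig, ThresholdedGraph, generate_cohort
from rsnhubs.fc import group_difference


def graph_from_edges(n: int, edges: list[tuple[int, int]], weights=None) -> ThresholdedGraph:
    adj = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        adj[i, j] = adj[j, i] = w
    return ThresholdedGraph(adjacency=adj, node_labels=[f"n{i}" for i in range(n)])


def complete_graph(n: int) -> ThresholdedGraph:
    adj = np.ones((n, n)) - np.eye(n)
    return ThresholdedGraph(adjacency=adj, node_labels=[f"n{i}" for i in range(n)])


@pytest.fixture
def two_k5_bridge() -> ThresholdedGraph:
    """Two K5 cliques (nodes 0-4 and 5-9) joined through connector node 10.

    The connector attaches to node 0 and node 5.  By hand: CI_2(10) = 24,
    clique-interior CI_2 = 3, attachment-node CI_2 = 16; removing node 10
    drops the giant component from 11 to 5.
    """
    edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
    edges += [(10, 0), (10, 5)]
    return graph_from_edges(11, edges)


@pytest.fixture
def star5() -> ThresholdedGraph:
    """Star: center 0 with 4 leaves."""
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def path3() -> ThresholdedGraph:
    return graph_from_edges(3, [(0, 1), (1, 2)])


def random_graph(n: int, p: float, rng: np.random.Generator) -> ThresholdedGraph:
    mask = np.triu(rng.random((n, n)) < p, k=1)
    adj = (mask | mask.T).astype(float)
    return ThresholdedGraph(adjacency=adj, node_labels=[f"n{i}" for i in range(n)])


@pytest.fixture(scope="session")
def null_cohort():
    """Small null cohort (no planted structure) shared across tests."""
    cfg = SyntheticCohortConfig(
        n_regions=20, n_per_group=8, n_runs=1, n_timepoints=150,
        behavior_beta=0.0, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_diff(null_cohort):
    sub = null_cohort.subset(task="1day")
    t = [sub.fc[i] for i in np.flatnonzero((sub.meta["group"] == "task").to_numpy())]
    c = [sub.fc[i] for i in np.flatnonzero((sub.meta["group"] == "control").to_numpy())]
    return group_difference(t, c)
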