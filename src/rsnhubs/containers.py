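"""Core data containers shared across the pipeline stages.

The pipeline moves from regional time series to Fisher-z functional
connectivity (FC) matrices, to edgewise group-difference networks, to
thresholded graphs on which hub statistics are computed.  Each stage has a
small dataclass here; operations live in the stage modules
(:mod:`rsnhubs.fc`, :mod:`rsnhubs.metrics`, :mod:`rsnhubs.percolation`,
:mod:`rsnhubs.nulls`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically unusable
    (zero-variance region, constant behavior vector, ...)."""


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) edge universe for an n-region network."""
    return np.triu_indices(n_regions, k=1)


@dataclass
class ROITimeSeries:
    """One animal/run table of regional signals (rows = timepoints)."""

    values: np.ndarray  # T x R
    region_labels: list[str]
    animal_id: str = ""
    run_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series values must be a T x R matrix")
        if self.values.shape[1] != len(self.region_labels):
            raise ValueError("column count does not match region labels")
        if self.values.shape[0] < 10:
            raise ValueError(
                f"need at least 10 timepoints, got {self.values.shape[0]}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing/non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Fisher-z functional-connectivity matrix for one animal.

    ``z[i, j]`` is atanh of the Pearson correlation between the time courses
    of regions i and j; the diagonal is fixed at 0 and the matrix is
    symmetric.
    """

    z: np.ndarray
    region_labels: list[str]
    animal_id: str = ""
    runs_averaged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        r = self.z.shape[0]
        if self.z.shape != (r, r):
            raise ValueError("z must be square")
        if len(self.region_labels) != r:
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("z must be symmetric")
        if not np.allclose(np.diag(self.z), 0.0):
            raise ValueError("diagonal of z must be 0")
        if not np.isfinite(self.z).all():
            raise ValueError("z contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    def edge_values(self) -> np.ndarray:
        """Vector of upper-triangle edge values (i < j order)."""
        iu, ju = edge_index(self.n_regions)
        return self.z[iu, ju]


@dataclass
class CohortDataset:
    """Per-animal averaged FC matrices plus group/task labels and behavior.

    ``meta`` has one row per animal with columns ``animal_id``, ``task``,
    ``group`` ('task' or 'control'), ``n_shock`` and ``t_enter`` (probe-test
    behavior: shock count and latency to first shock-zone entry, seconds).
    ``fc`` is aligned with the rows of ``meta``.
    """

    fc: list[FCMatrix]
    meta: pd.DataFrame
    region_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.fc) != len(self.meta):
            raise ValueError("fc list and meta table must align")
        for m in self.fc:
            if m.region_labels != self.region_labels:
                raise ValueError("all FC matrices must share region labels")
        if self.meta["animal_id"].duplicated().any():
            raise ValueError("each animal may appear only once")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def edge_matrix(self) -> np.ndarray:
        """(n_animals, n_edges) matrix of upper-triangle edge z values."""
        return np.array([m.edge_values() for m in self.fc])

    def subset(self, *, task: str | None = None, group: str | None = None) -> "CohortDataset":
        mask = pd.Series(True, index=self.meta.index)
        if task is not None:
            mask &= self.meta["task"] == task
        if group is not None:
            mask &= self.meta["group"] == group
        idx = np.flatnonzero(mask.to_numpy())
        return CohortDataset(
            fc=[self.fc[i] for i in idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            region_labels=self.region_labels,
        )

    def behavior(self, index_name: str) -> np.ndarray:
        if index_name not in ("n_shock", "t_enter"):
            raise ValueError(f"unknown behavioral index {index_name!r}")
        return self.meta[index_name].to_numpy(dtype=float)


@dataclass
class DiffNetwork:
    """Edgewise two-sample t comparison between a task group and its control.

    ``t`` and ``p`` are symmetric R x R matrices; diagonal is t = 0, p = 1.
    ``flagged`` marks edges where the pooled variance vanished (t forced to 0).
    """

    t: np.ndarray
    p: np.ndarray
    n_a: int
    n_b: int
    region_labels: list[str]
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape or self.t.shape[0] != self.t.shape[1]:
            raise ValueError("t and p must be square and congruent")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("p values must lie in [0, 1]")
        if self.flagged is None:
            self.flagged = np.zeros_like(self.t, dtype=bool)

    @property
    def df(self) -> int:
        return self.n_a + self.n_b - 2

    @property
    def n_regions(self) -> int:
        return self.t.shape[0]


@dataclass
class ThresholdedGraph:
    """Symmetric nonnegative adjacency (binary or |t| weighted), no self-loops."""

    adjacency: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if (a < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(np.diag(a)).max(initial=0.0) > 0:
            raise ValueError("self-loops are not allowed")
        if len(self.node_labels) != a.shape[0]:
            raise ValueError("label count does not match adjacency")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Binarized degree k_i."""
        return (self.adjacency > 0).sum(axis=1)

    @property
    def strengths(self) -> np.ndarray:
        """Weighted degree (node strength)."""
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int((self.adjacency > 0).sum() // 2)

    def binarized(self) -> np.ndarray:
        return (self.adjacency > 0).astype(float)

    def edge_list(self) -> list[tuple[int, int, float]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(iu, ju)]


@dataclass
class MetricCurve:
    """A graph metric traced over a threshold grid, with its trapezoid AUC."""

    metric: str
    thresholds: np.ndarray
    values: np.ndarray
    flagged: np.ndarray = field(default=None)  # thresholds where the degenerate convention applied

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.thresholds) != len(self.values):
            raise ValueError("thresholds and values must align")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.values), dtype=bool)

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.values, self.thresholds))


@dataclass
class SmallWorldResult:
    """Normalized path length (lambda), clustering (gamma) and sigma = gamma/lambda."""

    thresholds: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray

    @property
    def auc(self) -> dict[str, float]:
        return {
            "lambda": float(np.trapezoid(self.lam, self.thresholds)),
            "gamma": float(np.trapezoid(self.gamma, self.thresholds)),
            "sigma": float(np.trapezoid(self.sigma, self.thresholds)),
        }


@dataclass
class EdgeBehaviorCorrelation:
    """Pearson correlation between one edge's FC strength and a behavior score."""

    edge: tuple[int, int]
    behavior_index: str
    r: float
    p: float
    n: int
    cohen_d: float | None = None


@dataclass
class RemovalCurve:
    """Giant-component collapse trajectory under targeted node removal.

    Nodes are removed one by one until a single node remains; ``gc_ratio[k]``
    is the giant-component size after the (k+1)-th removal divided by the
    intact giant-component size.  ``removal_order`` lists all nodes, the last
    entry being the sole survivor (never actually removed).
    """

    method: str
    removal_order: list[int]
    gc_ratio: np.ndarray
    n_nodes: int
    gc0: int

    @property
    def auc(self) -> float:
        """Trapezoid area of gc_ratio versus fraction of nodes removed."""
        n = self.n_nodes
        x = np.arange(len(self.gc_ratio) + 1) / n
        y = np.concatenate([[1.0], self.gc_ratio])
        return float(np.trapezoid(y, x))


@dataclass
class HubRanking:
    """Per-threshold collective-influence removal ranks and their mean.

    ``ranks`` is a (n_thresholds, n_nodes) array; rank 1 = removed first.
    Nodes absent or isolated at a threshold get rank (present count) + 1.
    ``order`` sorts nodes by ascending mean rank; ``tiers`` labels the top 10
    (high = positions 1-3, middle = 4-7, low = 8-10, else unranked).
    """

    node_labels: list[str]
    thresholds: list[float]
    ranks: np.ndarray
    mean_rank: np.ndarray
    order: np.ndarray
    tiers: dict[int, str]

    def tier_of(self, node: int) -> str:
        return self.tiers.get(node, "unranked")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos, node in enumerate(self.order):
            row = {"node": int(node), "label": self.node_labels[node]}
            for k, thr in enumerate(self.thresholds):
                row[f"rank_p{str(thr).replace('0.', '')}"] = self.ranks[k, node]
            row["mean_rank"] = self.mean_rank[node]
            row["tier"] = self.tier_of(int(node))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class NullDistribution:
    """Observed statistic against an empirical null sample."""

    statistic: str
    observed: float
    null_samples: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.null_samples = np.asarray(self.null_samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.null_samples)

    @property
    def p_upper(self) -> float:
        """Add-one empirical p for an upper-tail statistic; never 0."""
        return ((self.null_samples >= self.observed).sum() + 1) / (self.n_samples + 1)

    @property
    def p_lower(self) -> float:
        return ((self.null_samples <= self.observed).sum() + 1) / (self.n_samples + 1)


@dataclass
class CommonNetworkResult:
    """Edges significant in both task contrasts, optionally behavior-filtered.

    ``common_edges`` are (i, j) upper-triangle pairs; ``signs`` records the
    per-task t signs (agreement not required).  When the permutation FWE step
    has run, ``surviving`` holds the behavior-correlated common edges and
    ``fwe_p`` the add-one permutation p for the surviving-edge count.
    """

    common_edges: list[tuple[int, int]]
    signs: dict[tuple[int, int], tuple[int, int]]
    n_task1: int
    n_task2: int
    n_union: int
    surviving: list[EdgeBehaviorCorrelation] | None = None
    observed_count: int | None = None
    null_counts: np.ndarray | None = None
    fwe_p: float | None = None

    @property
    def n_common(self) -> int:
        return len(self.common_edges)

    @property
    def overlap_fraction(self) -> float:
        """Headline overlap: common edges over the union of both edge sets."""
        return self.n_common / self.n_union if self.n_union else 0.0
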