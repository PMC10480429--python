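"""Functional-connectivity construction and edgewise statistics.

Builds Fisher-z FC matrices from regional time series, averages repeated
runs per animal, contrasts task and control groups edge by edge with a
two-sample t test, thresholds the resulting difference network, and
correlates edge strengths with probe-test behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CohortDataset,
    DegenerateInputError,
    DiffNetwork,
    EdgeBehaviorCorrelation,
    FCMatrix,
    ROITimeSeries,
    ThresholdedGraph,
    edge_index,
)

# Correlations are clipped just inside +-1 before atanh so degenerate
# (perfectly correlated) columns stay finite without materially perturbing
# realistic values.
R_CLIP = 1.0 - 1e-7


def compute_fc(ts: ROITimeSeries) -> FCMatrix:
    """Pearson-correlate every pair of regional time courses and Fisher-z them.

    Raises
    ------
    DegenerateInputError
        If any region has zero variance (its correlation is undefined).
    """
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead)
        raise DegenerateInputError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # kill asymmetric rounding noise
    return FCMatrix(
        z=z,
        region_labels=list(ts.region_labels),
        animal_id=ts.animal_id,
        runs_averaged=(ts.run_id,) if ts.run_id else (),
    )


def average_runs(fcs: list[FCMatrix]) -> FCMatrix:
    """Element-wise mean of one animal's per-run z matrices."""
    if not fcs:
        raise ValueError("need at least one FC matrix to average")
    labels = fcs[0].region_labels
    for m in fcs[1:]:
        if m.region_labels != labels:
            raise ValueError("region labels differ between runs")
    z = np.mean([m.z for m in fcs], axis=0)
    runs = tuple(r for m in fcs for r in m.runs_averaged)
    return FCMatrix(z=z, region_labels=list(labels), animal_id=fcs[0].animal_id, runs_averaged=runs)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized classic (pooled-variance) two-sample t of a minus b.

    ``a`` and ``b`` are (n_animals, n_edges).  Edges with zero pooled
    variance get t = 0, p = 1 and are flagged.
    """
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    diff = a.mean(axis=0) - b.mean(axis=0)
    ssa = ((a - a.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    flagged = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flagged, 0.0, diff / np.where(flagged, 1.0, se))
    p = np.where(flagged, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p, flagged


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    flagged = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flagged, 0.0, (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(np.where(flagged, 1.0, se2)))
        df = np.where(flagged, 1.0, se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1))))
    p = np.where(flagged, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p, flagged


def group_difference(
    task_fcs: list[FCMatrix],
    control_fcs: list[FCMatrix],
    *,
    welch: bool = False,
) -> DiffNetwork:
    """Edgewise two-sample t test (task minus control) over animals.

    Pooled-variance Student t by default; Welch behind the ``welch`` switch.
    """
    if len(task_fcs) < 2 or len(control_fcs) < 2:
        raise ValueError("each group needs at least 2 animals")
    labels = task_fcs[0].region_labels
    n = len(labels)
    a = np.array([m.edge_values() for m in task_fcs])
    b = np.array([m.edge_values() for m in control_fcs])
    t_e, p_e, fl_e = (_welch_t if welch else _pooled_t)(a, b)
    iu, ju = edge_index(n)
    t = np.zeros((n, n))
    p = np.ones((n, n))
    fl = np.zeros((n, n), dtype=bool)
    t[iu, ju] = t_e
    t[ju, iu] = t_e
    p[iu, ju] = p_e
    p[ju, iu] = p_e
    fl[iu, ju] = fl_e
    fl[ju, iu] = fl_e
    return DiffNetwork(
        t=t, p=p, n_a=len(task_fcs), n_b=len(control_fcs), region_labels=list(labels), flagged=fl
    )


def threshold_graph(
    diff: DiffNetwork,
    mode: str = "t_score",
    value: float = 2.0,
    tail: str = "both",
    weighting: str = "binary",
) -> ThresholdedGraph:
    """Keep edges surviving a t-score or p-value threshold.

    t-score thresholds are inclusive (|t| >= value); p thresholds are strict
    (p < value).  ``tail`` restricts to positive-t or negative-t edges;
    weights are 1 (binary) or |t| (abs_t).
    """
    if mode not in ("t_score", "p_value"):
        raise ValueError(f"unknown mode {mode!r}")
    if tail not in ("both", "positive", "negative"):
        raise ValueError(f"unknown tail {tail!r}")
    if weighting not in ("binary", "abs_t"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if mode == "t_score" and not value > 0:
        raise ValueError("t-score threshold must be positive")
    if mode == "p_value" and not (0 < value < 1):
        raise ValueError("p threshold must lie in (0, 1)")

    if mode == "t_score":
        keep = np.abs(diff.t) >= value
    else:
        keep = diff.p < value
    if tail == "positive":
        keep &= diff.t > 0
    elif tail == "negative":
        keep &= diff.t < 0
    np.fill_diagonal(keep, False)
    if weighting == "binary":
        adj = keep.astype(float)
    else:
        adj = np.where(keep, np.abs(diff.t), 0.0)
    return ThresholdedGraph(adjacency=adj, node_labels=list(diff.region_labels))


def fdr_bh(p_list, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask over a p-value list."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def pearson_p(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via the exact t transform, df = n - 2."""
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def behavior_correlation(
    cohort: CohortDataset,
    behavior_index: str,
    edges: list[tuple[int, int]],
    *,
    group: str | None = "task",
    diff: DiffNetwork | None = None,
) -> list[EdgeBehaviorCorrelation]:
    """Pearson-correlate each edge's z strength with a behavior score.

    Correlations run across the cohort's task-group animals by default
    (``group=None`` uses every animal).  Output is sorted by |r| descending,
    ties by (i, j) ascending.  When the corresponding difference network is
    supplied, Cohen's d of the underlying group contrast is attached.
    """
    if not edges:
        raise ValueError("edges must be nonempty")
    sub = cohort if group is None else cohort.subset(group=group)
    n = len(sub.fc)
    if n < 4:
        raise ValueError(f"need at least 4 animals with FC and behavior, got {n}")
    b = sub.behavior(behavior_index)
    if np.ptp(b) == 0:
        raise DegenerateInputError("behavior vector is constant")
    z = np.array([m.z for m in sub.fc])  # n x R x R
    out = []
    for i, j in edges:
        x = z[:, i, j]
        if np.ptp(x) == 0:
            raise DegenerateInputError(f"edge ({i}, {j}) has constant FC values")
        r = float(np.corrcoef(x, b)[0, 1])
        d = None
        if diff is not None:
            # convert the edgewise pooled t back to Cohen's d
            d = float(diff.t[i, j] * np.sqrt(1.0 / diff.n_a + 1.0 / diff.n_b))
        out.append(
            EdgeBehaviorCorrelation(
                edge=(i, j), behavior_index=behavior_index,
                r=r, p=pearson_p(r, n), n=n, cohen_d=d,
            )
        )
    out.sort(key=lambda e: (-abs(e.r), e.edge))
    return out


# ---------------------------------------------------------------------------
# on-disk formats


def read_timeseries_tsv(path, animal_id: str = "", run_id: str = "", task: str = "") -> ROITimeSeries:
    """Read a TSV of timepoints x regions with region labels as header."""
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(
        values=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        animal_id=animal_id,
        run_id=run_id,
        task=task,
    )


def write_timeseries_tsv(ts: ROITimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(path, sep="\t", index=False)


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix CSV (region labels as header and index)."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix_csv(matrix: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path)
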