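"""Synthetic cohorts and planted graphs with known ground truth.

Every downstream stage of the pipeline (edgewise contrasts, behavior
correlation, percolation hub ranking, permutation FWE) is validated against
data whose causal structure is planted here:

* :func:`generate_cohort` draws two-task, two-group cohorts of regional
  time series from zero-mean multivariate normals.  The control covariance
  is block-structured (``base_modules`` compound-symmetry blocks, within-
  block correlation 0.3); the task covariance adds ``delta`` increments on
  the planted edges.  Behavior is linearly coupled to the *realized*
  Fisher-z FC of the planted edges plus Gaussian noise, so finite-sample FC
  noise propagates to behavior exactly as the analysis assumes.
* :func:`generate_planted_graph` builds modular graphs with designated
  bridge (connector) nodes whose removal disconnects the modules — the
  fixture family for comparing percolation hub-detection methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fc as _fc
from .containers import CohortDataset, FCMatrix, ROITimeSeries, ThresholdedGraph

TASKS = ("1day", "5day")


@dataclass
class SyntheticCohortConfig:
    """Stated world for a two-task, two-group cohort.

    ``planted_edges`` is a list of (i, j, delta) covariance increments added
    to the task groups of both tasks; ``hub_nodes`` marks regions designated
    as planted integrator hubs (used by :meth:`with_planted_hub` to build a
    star of planted edges).  ``behavior_beta`` couples the mean planted-edge
    Fisher-z FC to the behavior score, with residual
    ``behavior_noise_sd``.
    """

    n_regions: int = 40
    n_per_group: int = 10
    n_runs: int = 3
    n_timepoints: int = 2000
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    hub_nodes: list[int] = field(default_factory=list)
    behavior_beta: float = 0.0
    behavior_noise_sd: float = 1.0
    base_modules: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_regions > 230:
            raise ValueError("n_regions must be in [2, 230]")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be at least 10")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")
        seen = set()
        for i, j, _ in self.planted_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions) or i == j:
                raise ValueError(f"invalid planted edge ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted edge {key}")
            seen.add(key)
        for h in self.hub_nodes:
            if not 0 <= h < self.n_regions:
                raise ValueError(f"hub node {h} out of range")

    @classmethod
    def with_planted_hub(
        cls,
        hub: int,
        delta: float,
        spokes_per_module: int = 2,
        **kwargs,
    ) -> "SyntheticCohortConfig":
        """Config whose planted edges form a star from ``hub`` into every
        background module, making the hub a cross-module integrator in the
        task-vs-control difference network."""
        cfg = cls(hub_nodes=[hub], **kwargs)
        block = cfg.n_regions // cfg.base_modules
        edges = []
        for m in range(cfg.base_modules):
            lo = m * block
            hi = (m + 1) * block if m < cfg.base_modules - 1 else cfg.n_regions
            spokes = [v for v in range(lo, hi) if v != hub][:spokes_per_module]
            edges.extend((hub, v, delta) for v in spokes)
        cfg.planted_edges = edges
        cfg.__post_init__()
        return cfg


def _background_covariance(cfg: SyntheticCohortConfig) -> np.ndarray:
    """Block-diagonal compound symmetry: within-block correlation 0.3."""
    n = cfg.n_regions
    cov = np.eye(n)
    block = n // cfg.base_modules
    for m in range(cfg.base_modules):
        lo = m * block
        hi = (m + 1) * block if m < cfg.base_modules - 1 else n
        cov[lo:hi, lo:hi] = 0.3
    np.fill_diagonal(cov, 1.0)
    return cov


def _nearest_psd(cov: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() >= floor:
        return cov
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    return (out + out.T) / 2


def group_covariances(cfg: SyntheticCohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """(control, task) population covariances; task adds delta on planted edges."""
    base = _background_covariance(cfg)
    task = base.copy()
    for i, j, delta in cfg.planted_edges:
        task[i, j] += delta
        task[j, i] += delta
    base = _nearest_psd(base)
    task = _nearest_psd(task)
    for c in (base, task):
        if np.linalg.eigvalsh(c).min() < 0:
            raise RuntimeError("covariance construction failed to reach PSD")
    return base, task


def generate_cohort(
    config: SyntheticCohortConfig,
    return_timeseries: bool = False,
    tasks: tuple[str, ...] = TASKS,
) -> CohortDataset | tuple[CohortDataset, dict[str, list[ROITimeSeries]]]:
    """Draw a full two-task cohort with planted structure.

    Each animal contributes ``n_runs`` time-series draws from its group's
    covariance; per-run FC matrices are Fisher-z transformed and averaged.
    Behavior: b = behavior_beta * mean planted-edge z + N(0, noise_sd), for
    every animal (controls also run the probe test).  Identical config and
    seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    cov_ctl, cov_task = group_covariances(config)
    chol = {"control": np.linalg.cholesky(cov_ctl), "task": np.linalg.cholesky(cov_task)}
    labels = [f"R{i:03d}" for i in range(config.n_regions)]
    planted = [(min(i, j), max(i, j)) for i, j, _ in config.planted_edges]

    fcs: list[FCMatrix] = []
    rows = []
    series: dict[str, list[ROITimeSeries]] = {}
    for task in tasks:
        for group in ("task", "control"):
            L = chol[group]
            for a in range(config.n_per_group):
                animal = f"{task}_{group}_{a:02d}"
                run_fcs = []
                run_series = []
                for r in range(config.n_runs):
                    x = rng.standard_normal((config.n_timepoints, config.n_regions)) @ L.T
                    ts = ROITimeSeries(
                        values=x, region_labels=labels,
                        animal_id=animal, run_id=f"run{r}", task=task,
                    )
                    run_series.append(ts)
                    run_fcs.append(_fc.compute_fc(ts))
                m = _fc.average_runs(run_fcs)
                m.animal_id = animal
                if planted:
                    planted_z = float(np.mean([m.z[i, j] for i, j in planted]))
                else:
                    planted_z = 0.0
                noise = rng.normal(0.0, config.behavior_noise_sd)
                b = config.behavior_beta * planted_z + noise
                fcs.append(m)
                rows.append(
                    {
                        "animal_id": animal,
                        "task": task,
                        "group": group,
                        # both probe indices share the planted coupling; T_enter
                        # is shifted to a plausible latency scale (seconds)
                        "n_shock": b,
                        "t_enter": 30.0 + b,
                    }
                )
                if return_timeseries:
                    series[animal] = run_series
    cohort = CohortDataset(fc=fcs, meta=pd.DataFrame(rows), region_labels=labels)
    if return_timeseries:
        return cohort, series
    return cohort


@dataclass
class PlantedGraphConfig:
    """Modular graph with designated bridge (connector) nodes.

    ``n_modules`` dense blocks of ``module_size`` nodes with within-block
    edge probability ``intra_p``; each of ``bridge_nodes`` extra nodes links
    to exactly one (randomly chosen) node per block.  Bridge nodes occupy
    the final indices and are labeled ``bridge*``.
    """

    n_modules: int = 4
    module_size: int = 10
    intra_p: float = 0.6
    bridge_nodes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if not (0 < self.intra_p <= 1):
            raise ValueError("intra_p must lie in (0, 1]")
        if self.bridge_nodes < 0:
            raise ValueError("bridge_nodes must be >= 0")


def generate_planted_graph(config: PlantedGraphConfig) -> ThresholdedGraph:
    """Sample a modular graph whose bridge nodes are the only inter-module links."""
    rng = np.random.default_rng(config.seed)
    n_block = config.n_modules * config.module_size
    n = n_block + config.bridge_nodes
    adj = np.zeros((n, n))
    labels = []
    for m in range(config.n_modules):
        lo = m * config.module_size
        hi = lo + config.module_size
        labels.extend(f"m{m}_n{v - lo}" for v in range(lo, hi))
        mask = rng.random((config.module_size, config.module_size)) < config.intra_p
        mask = np.triu(mask, k=1)
        block = (mask | mask.T).astype(float)
        adj[lo:hi, lo:hi] = block
    for b in range(config.bridge_nodes):
        v = n_block + b
        labels.append(f"bridge{b}")
        for m in range(config.n_modules):
            anchor = m * config.module_size + int(rng.integers(config.module_size))
            adj[v, anchor] = adj[anchor, v] = 1.0
    return ThresholdedGraph(adjacency=adj, node_labels=labels)


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path,
    write_timeseries: bool = True,
) -> CohortDataset:
    """Materialize a synthetic cohort as TSV files plus a ground-truth manifest.

    Layout: ``{animal}_{run}.tsv`` time-series tables (rows = timepoints,
    columns = region labels), ``cohort.tsv`` with animal_id/task/group and
    both behavior scores, ``fc/{animal}.csv`` averaged FC matrices, and
    ``ground_truth.json`` (planted edges, hub nodes, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = generate_cohort(config, return_timeseries=write_timeseries)
    if write_timeseries:
        cohort, series = result
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for animal, runs in series.items():
            for ts in runs:
                _fc.write_timeseries_tsv(ts, ts_dir / f"{animal}_{ts.run_id}.tsv")
    else:
        cohort = result
    cohort.meta.to_csv(out / "cohort.tsv", sep="\t", index=False)
    fc_dir = out / "fc"
    fc_dir.mkdir(exist_ok=True)
    for m in cohort.fc:
        _fc.write_matrix_csv(m.z, m.region_labels, fc_dir / f"{m.animal_id}.csv")
    manifest = {
        "planted_edges": [[int(i), int(j), float(d)] for i, j, d in config.planted_edges],
        "hub_nodes": [int(h) for h in config.hub_nodes],
        "seed": int(config.seed),
        "n_regions": int(config.n_regions),
        "n_per_group": int(config.n_per_group),
        "n_runs": int(config.n_runs),
        "n_timepoints": int(config.n_timepoints),
        "behavior_beta": float(config.behavior_beta),
        "behavior_noise_sd": float(config.behavior_noise_sd),
        "base_modules": int(config.base_modules),
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return cohort


def read_cohort(in_dir: str | Path) -> CohortDataset:
    """Load a cohort written by :func:`write_cohort` (FC matrices + table)."""
    out = Path(in_dir)
    meta = pd.read_csv(out / "cohort.tsv", sep="\t")
    fcs = []
    labels = None
    for animal in meta["animal_id"]:
        z, lab = _fc.read_matrix_csv(out / "fc" / f"{animal}.csv")
        labels = labels or lab
        fcs.append(FCMatrix(z=z, region_labels=lab, animal_id=str(animal)))
    return CohortDataset(fc=fcs, meta=meta, region_labels=labels)
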