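"""Clone-structured synthetic segment counts with ground truth.

The generator mirrors the model's own assumptions: a random clonal tree
whose root is fully diploid, with each non-root clone altering up to
``max_new_segments`` previously untouched segments; cells drawn from
Dirichlet-uniform mixing proportions; log-normal library factors; and
Negative Binomial counts whose mean scales linearly with the clone's
integer copy number, independently for an RNA-like and an ATAC-like
modality. What it deliberately does not emulate: gene-level expression
programs, batch effects, cell-cycle signal or doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .segdata import SegmentedCounts, compute_library_factors

__all__ = [
    "CloneTree",
    "SimulationTruth",
    "SimulatedDataset",
    "sample_clone_tree",
    "sample_mixing_proportions",
    "sample_segment_rates",
    "simulate_counts",
    "simulate_dataset",
    "recovery_benchmark",
]

# Realistic per-segment (chromosome-arm scale) baselines for 10x-style
# assays: counts per copy in an average cell, and NB sizes. Segment
# counts are sums over the hundreds of features a segment contains, so
# their effective NB size is large (near-Poisson); RNA is kept as the
# more dispersed modality.
DEFAULT_MEAN_RATE = {"RNA": 60.0, "ATAC": 40.0}
DEFAULT_MEAN_SIZE = {"RNA": 50.0, "ATAC": 150.0}
RATE_LOG_SD = 0.5
SIZE_LOG_SD = 0.3


@dataclass
class CloneTree:
    """Clonal topology plus per-clone copy-number events.

    ``parents[k]`` is the parent clone of k (root has parent -1);
    ``events[k]`` maps altered segment index -> new copy number, relative
    to the parent profile. Clone 0 is the diploid-like ancestor.
    """

    parents: list[int]
    events: list[dict[int, int]]

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    def copy_number_matrix(self, n_segments: int, root_cn: int = 2) -> np.ndarray:
        """Propagate events down the tree into a clones x segments matrix."""
        K = self.n_clones
        cn = np.zeros((K, n_segments), dtype=int)
        done = [False] * K
        for k in range(K):
            self._fill(k, cn, done, root_cn)
        return cn

    def _fill(self, k: int, cn: np.ndarray, done: list[bool], root_cn: int):
        if done[k]:
            return
        if self.parents[k] < 0:
            cn[k, :] = root_cn
        else:
            p = self.parents[k]
            self._fill(p, cn, done, root_cn)
            cn[k, :] = cn[p, :]
        for seg, value in self.events[k].items():
            cn[k, seg] = value
        done[k] = True

    def root_path(self, k: int) -> list[int]:
        path = [k]
        while self.parents[path[-1]] >= 0:
            path.append(self.parents[path[-1]])
        return path


@dataclass
class SimulationTruth:
    tree: CloneTree
    cn_matrix: np.ndarray  # (K, I) integer copy numbers
    proportions: np.ndarray  # simplex over clones
    segment_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cn_matrix = np.asarray(self.cn_matrix, dtype=int)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("proportions must sum to 1")
        if self.cn_matrix.shape[0] != self.proportions.size:
            raise ValueError("one mixing proportion per clone required")
        if not self.segment_ids:
            self.segment_ids = [
                f"seg_{i:03d}" for i in range(self.cn_matrix.shape[1])
            ]

    @property
    def n_clones(self) -> int:
        return self.cn_matrix.shape[0]


@dataclass
class SimulatedDataset:
    """Counts for both modalities plus the generating truth."""

    truth: SimulationTruth
    rna: SegmentedCounts
    atac: SegmentedCounts
    labels_rna: np.ndarray
    labels_atac: np.ndarray
    theta: dict[str, np.ndarray]
    overdispersion: dict[str, np.ndarray]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_clone_tree(
    K: int,
    I: int,
    max_new_segments: int = 3,
    H: int = 4,
    seed=None,
) -> tuple[CloneTree, np.ndarray]:
    """Random clonal tree with 1..max_new_segments new CNAs per clone.

    Each new clone attaches to a uniformly chosen existing clone and
    alters segments never touched on its root path, drawing each new
    copy number uniformly from {1..H} minus the parent's value. The root
    clone is diploid everywhere.
    """
    if K < 2:
        raise ValueError("a clonal tree needs K >= 2 clones")
    if I < K - 1:
        raise ValueError(
            f"need at least K-1={K - 1} segments for {K} clones, got {I}"
        )
    rng = _as_rng(seed)
    parents = [-1]
    events: list[dict[int, int]] = [{}]
    altered_on_path: list[set[int]] = [set()]
    cn = CloneTree(parents, events)  # grown in place
    for k in range(1, K):
        parent = int(rng.integers(0, k))
        free = [i for i in range(I) if i not in altered_on_path[parent]]
        if not free:
            raise ValueError(
                f"clone {k}: no unaltered segments left on its lineage; "
                "increase I or decrease max_new_segments"
            )
        n_events = int(rng.integers(1, max_new_segments + 1))
        n_events = min(n_events, len(free))
        segs = rng.choice(len(free), size=n_events, replace=False)
        parent_profile = cn.copy_number_matrix(I)[parent]
        ev: dict[int, int] = {}
        for j in segs:
            seg = free[int(j)]
            choices = [h for h in range(1, H + 1) if h != parent_profile[seg]]
            ev[seg] = int(rng.choice(choices))
        parents.append(parent)
        events.append(ev)
        altered_on_path.append(altered_on_path[parent] | set(ev))
    matrix = cn.copy_number_matrix(I)
    return cn, matrix


def sample_mixing_proportions(K: int, seed=None) -> np.ndarray:
    """Mixing proportions from a uniform Dirichlet over K clones."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = _as_rng(seed)
    return rng.dirichlet(np.ones(K))


def sample_segment_rates(
    I: int,
    modality: str,
    mean_rate: float | None = None,
    mean_size: float | None = None,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment NB rates (counts per copy) and sizes, log-normal."""
    rng = _as_rng(seed)
    mean_rate = mean_rate if mean_rate is not None else DEFAULT_MEAN_RATE[modality]
    mean_size = mean_size if mean_size is not None else DEFAULT_MEAN_SIZE[modality]
    theta = np.exp(rng.normal(np.log(mean_rate), RATE_LOG_SD, size=I))
    size = np.exp(rng.normal(np.log(mean_size), SIZE_LOG_SD, size=I))
    return theta, size


def simulate_counts(
    truth: SimulationTruth,
    n_cells: int | dict[str, int],
    theta: dict[str, np.ndarray],
    overdispersion: dict[str, np.ndarray],
    library_sd: float = 0.2,
    paired: bool = False,
    seed=None,
) -> SimulatedDataset:
    """Draw NB counts for both modalities from the clone structure.

    Cell labels come from the truth's mixing proportions (in paired mode
    one draw per cell serves both modalities and barcodes match);
    library factors are log-normal(0, library_sd), mean-normalised; and
    x ~ NegBin(mean = rho * theta_i * c[k, i], size = r_i).
    """
    rng = _as_rng(seed)
    if isinstance(n_cells, int):
        n_cells = {"RNA": n_cells, "ATAC": n_cells}
    if paired and n_cells["RNA"] != n_cells["ATAC"]:
        raise ValueError("paired mode needs equal cell numbers")
    K, I = truth.cn_matrix.shape
    if min(n_cells.values()) < K:
        import warnings

        warnings.warn(
            "fewer cells than clones; some clones may be empty", stacklevel=2
        )
    labels = {}
    if paired:
        shared = rng.choice(K, size=n_cells["RNA"], p=truth.proportions)
        labels = {"RNA": shared, "ATAC": shared.copy()}
    else:
        for name in ("RNA", "ATAC"):
            labels[name] = rng.choice(K, size=n_cells[name], p=truth.proportions)

    datasets = {}
    for name in ("RNA", "ATAC"):
        n = n_cells[name]
        rho = np.exp(rng.normal(0.0, library_sd, size=n))
        rho /= rho.mean()
        c = truth.cn_matrix[labels[name], :].astype(float)  # (n, I)
        mu = rho[:, None] * theta[name][None, :] * c
        r = overdispersion[name][None, :]
        counts = rng.negative_binomial(r, r / (r + mu))
        barcodes = (
            [f"CELL_{j:05d}" for j in range(n)]
            if paired
            else [f"{name}_{j:05d}" for j in range(n)]
        )
        datasets[name] = SegmentedCounts(
            modality=name,
            counts=counts,
            barcodes=barcodes,
            segment_ids=list(truth.segment_ids),
            library_factors=compute_library_factors(counts, barcodes),
        )
    return SimulatedDataset(
        truth=truth,
        rna=datasets["RNA"],
        atac=datasets["ATAC"],
        labels_rna=labels["RNA"],
        labels_atac=labels["ATAC"],
        theta={k: np.asarray(v, dtype=float) for k, v in theta.items()},
        overdispersion={
            k: np.asarray(v, dtype=float) for k, v in overdispersion.items()
        },
    )


def simulate_dataset(
    K: int,
    I: int = 20,
    n_cells: int | dict[str, int] = 1500,
    max_new_segments: int = 3,
    H: int = 4,
    library_sd: float = 0.2,
    paired: bool = False,
    include_normal_fraction: float | None = None,
    seed=None,
) -> SimulatedDataset:
    """One-call generator: tree + proportions + rates + counts.

    ``include_normal_fraction``, if set, pins the diploid root clone's
    mixing proportion (mimicking a spiked-in normal-cell population) and
    draws the remaining proportions from the uniform Dirichlet.
    """
    rng = _as_rng(seed)
    tree, cn = sample_clone_tree(K, I, max_new_segments, H, rng)
    props = sample_mixing_proportions(K, rng)
    if include_normal_fraction is not None:
        rest = sample_mixing_proportions(K - 1, rng) * (
            1.0 - include_normal_fraction
        )
        props = np.concatenate([[include_normal_fraction], rest])
    truth = SimulationTruth(tree=tree, cn_matrix=cn, proportions=props)
    theta = {}
    overdisp = {}
    for name in ("RNA", "ATAC"):
        theta[name], overdisp[name] = sample_segment_rates(I, name, seed=rng)
    return simulate_counts(
        truth, n_cells, theta, overdisp, library_sd, paired, rng
    )


def recovery_benchmark(
    n_replicates: int = 10,
    K_values: Sequence[int] = tuple(range(2, 11)),
    n_cells: int = 1500,
    n_segments: int = 20,
    max_new_segments: int = 3,
    H: int = 4,
    fit_config=None,
    seed: int = 0,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """End-to-end recovery benchmark: simulate, fit, score ARI and MAE.

    For every true K and replicate, simulates a two-modality dataset,
    fits with model selection (lambda = 0.5 and BIC unless overridden in
    ``fit_config``) and evaluates clustering recovery (ARI on RNA cells,
    ATAC cells, and both pooled) and copy-number recovery (MAE over
    optimally matched clone/segment pairs). Returns the tidy per-dataset
    table and the summary medians.
    """
    from .evaluation import evaluate_fit  # local import to avoid a cycle
    from .inference import FitConfig, select_model
    from .model import default_prior

    rows = []
    replicate_seeds = np.random.SeedSequence(seed).spawn(
        len(K_values) * max(n_replicates, 1)
    )
    idx = 0
    for K_true in K_values:
        for rep in range(n_replicates):
            rng = np.random.default_rng(replicate_seeds[idx])
            idx += 1
            sim = simulate_dataset(
                K=K_true,
                I=n_segments,
                n_cells=n_cells,
                max_new_segments=max_new_segments,
                H=H,
                seed=rng,
            )
            cfg = fit_config or FitConfig()
            prior = default_prior(np.full(n_segments, 2), H=H)
            best, table = select_model(sim.rna, sim.atac, prior, cfg)
            report = evaluate_fit(sim, best)
            rows.append(
                {
                    "K_true": K_true,
                    "replicate": rep,
                    "K_inferred": best.K,
                    "ari": report.ari,
                    "ari_rna": report.ari_per_modality.get("RNA", np.nan),
                    "ari_atac": report.ari_per_modality.get("ATAC", np.nan),
                    "mae": report.mae,
                }
            )
            if progress:
                print(
                    f"K_true={K_true} rep={rep}: K_inferred={best.K} "
                    f"ARI={report.ari:.3f} MAE={report.mae:.3f}",
                    flush=True,
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "K_true", "replicate", "K_inferred",
            "ari", "ari_rna", "ari_atac", "mae",
        ],
    )
    if len(table):
        summary = {
            "median_ari": float(table["ari"].median()),
            "median_mae": float(table["mae"].median()),
        }
    else:
        summary = {"median_ari": float("nan"), "median_mae": float("nan")}
    return table, summary
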