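"""Recovery metrics: clustering ARI and copy-number MAE.

Cluster labels are arbitrary, so inferred clusters are first matched
one-to-one to true clones by minimising the summed mean absolute
copy-number difference (solved exactly with the Hungarian algorithm);
the MAE is then averaged over matched clone/segment pairs only, so a
mis-selected K is penalised once through the ARI rather than twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "EvaluationReport",
    "adjusted_rand_index",
    "match_clusters",
    "cna_mae",
    "evaluate_fit",
]


@dataclass
class EvaluationReport:
    ari: float
    mae: float
    matching: dict[int, int]  # inferred cluster -> true clone
    per_segment_error: np.ndarray
    ari_per_modality: dict[str, float] = field(default_factory=dict)
    unmatched_true: list[int] = field(default_factory=list)
    unmatched_inferred: list[int] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"ARI={self.ari:.3f}  MAE={self.mae:.3f}  "
            f"matched={len(self.matching)} cluster(s)"
        )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same cells."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(
            f"label vectors differ in length: {labels_a.shape} vs "
            f"{labels_b.shape}"
        )
    if labels_a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def match_clusters(
    true_cn: np.ndarray, inferred_cn: np.ndarray
) -> tuple[dict[int, int], list[int], list[int]]:
    """Optimal one-to-one map inferred cluster -> true clone.

    Cost of pairing inferred cluster k with true clone t is the mean
    absolute copy-number difference of their profiles; the assignment
    minimising the summed cost is found exactly. Extra clusters on
    either side are left unmatched and reported.
    """
    true_cn = np.asarray(true_cn, dtype=float)
    inferred_cn = np.asarray(inferred_cn, dtype=float)
    if true_cn.shape[1] != inferred_cn.shape[1]:
        raise ValueError("true and inferred profiles must share segments")
    cost = np.abs(
        inferred_cn[:, None, :] - true_cn[None, :, :]
    ).mean(axis=2)  # (K_inf, K_true)
    rows, cols = linear_sum_assignment(cost)
    matching = {int(k): int(t) for k, t in zip(rows, cols)}
    unmatched_inf = [k for k in range(inferred_cn.shape[0]) if k not in matching]
    matched_true = set(matching.values())
    unmatched_true = [
        t for t in range(true_cn.shape[0]) if t not in matched_true
    ]
    return matching, unmatched_true, unmatched_inf


def cna_mae(
    true_cn: np.ndarray,
    inferred_cn: np.ndarray,
    matching: dict[int, int],
) -> float:
    """Mean |true - inferred| copy number over matched clone/segment pairs."""
    if not matching:
        raise ValueError("empty matching")
    true_cn = np.asarray(true_cn, dtype=float)
    inferred_cn = np.asarray(inferred_cn, dtype=float)
    diffs = [
        np.abs(true_cn[t] - inferred_cn[k]) for k, t in matching.items()
    ]
    return float(np.mean(np.concatenate(diffs)))


def _per_segment_error(true_cn, inferred_cn, matching) -> np.ndarray:
    diffs = np.stack(
        [np.abs(true_cn[t] - inferred_cn[k]) for k, t in matching.items()]
    )
    return diffs.mean(axis=0)


def evaluate_fit(sim, result) -> EvaluationReport:
    """Score a fit against the simulation that generated its data.

    ARI is computed per modality on the fit's hard assignments (a single
    shared set in multiome mode) and pooled across modalities for the
    headline number; MAE compares MAP copy numbers to the true clone
    profiles after optimal matching.
    """
    true_labels = {"RNA": sim.labels_rna, "ATAC": sim.labels_atac}
    ari_pm: dict[str, float] = {}
    pooled_true: list[np.ndarray] = []
    pooled_hat: list[np.ndarray] = []
    for key, hard in result.assignments.items():
        if key == "cells":  # multiome: shared labels, identical per modality
            truth = sim.labels_rna
            ari_pm["RNA"] = ari_pm["ATAC"] = adjusted_rand_index(truth, hard)
        else:
            truth = true_labels[key]
            ari_pm[key] = adjusted_rand_index(truth, hard)
        pooled_true.append(np.asarray(truth))
        pooled_hat.append(np.asarray(hard))
    ari = adjusted_rand_index(
        np.concatenate(pooled_true), np.concatenate(pooled_hat)
    )
    matching, unm_true, unm_inf = match_clusters(
        sim.truth.cn_matrix, result.map_cn
    )
    mae = cna_mae(sim.truth.cn_matrix, result.map_cn, matching)
    return EvaluationReport(
        ari=ari,
        mae=mae,
        matching=matching,
        per_segment_error=_per_segment_error(
            sim.truth.cn_matrix, result.map_cn, matching
        ),
        ari_per_modality=ari_pm,
        unmatched_true=unm_true,
        unmatched_inferred=unm_inf,
    )
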