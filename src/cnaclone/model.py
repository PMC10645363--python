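"""Generative model for copy-number clones from segment counts.

Cells belong to one of K clones; clone k carries a latent copy-number
state over each segment i, encoded by the probability tensor
Phi[k, i, h] over the discrete states h = 1..H (no zero-copy state).
Counts for cell n in segment i follow a Negative Binomial whose mean is
linear in the copy number,

    mu[k, i, n] = rho_n * theta_i * sum_h Phi[k, i, h] * h,

with rho_n the observed per-cell library factor, theta_i a learnt
per-segment rate (counts per copy in an average cell) and a learnt
per-segment overdispersion r_i (NB size). Marginalising the clone
assignment z gives the per-modality mixture likelihood

    p(X) = prod_n sum_k pi_k prod_i NB(x_{n,i} | mu[k,i,n], r_i),

and the RNA and ATAC modalities, which share Phi, are combined with a
shrinkage weight lambda in [0, 1]:

    L = lambda * log p(X_RNA) + (1 - lambda) * log p(X_ATAC).

Each Phi[k, i, :] carries a Dirichlet prior skewed towards the expected
(prior) copy number of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .segdata import SegmentedCounts

__all__ = [
    "CNAPrior",
    "ModelParams",
    "default_prior",
    "nb_mean",
    "nb_logpmf",
    "component_scores",
    "modality_loglik",
    "joint_loglik",
    "multiome_loglik",
]

DEFAULT_PRIOR_ON = 0.6
DEFAULT_PRIOR_OFF = 0.1
MAX_DEFAULT_H = 6


@dataclass
class CNAPrior:
    """Dirichlet concentrations over copy states 1..H, one row per segment."""

    H: int
    alpha: np.ndarray  # (I, H)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 2 or self.alpha.shape[1] != self.H:
            raise ValueError("alpha must be (n_segments, H)")
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def n_segments(self) -> int:
        return self.alpha.shape[0]

    @property
    def expected_cn(self) -> np.ndarray:
        """Copy state with the largest prior concentration (1-based)."""
        return np.argmax(self.alpha, axis=1) + 1


def default_prior(
    expected_cn: Sequence[int] | np.ndarray, H: int | None = None
) -> CNAPrior:
    """Skewed Dirichlet prior: 0.6 on the expected state, 0.1 elsewhere.

    If ``H`` is omitted it defaults to max(expected_cn) + 2, capped at 6 —
    a small categorical is all current single-cell resolution justifies.
    """
    expected_cn = np.asarray(expected_cn, dtype=int)
    if expected_cn.ndim != 1 or expected_cn.size == 0:
        raise ValueError("expected_cn must be a non-empty 1-D sequence")
    if H is None:
        H = min(int(expected_cn.max()) + 2, MAX_DEFAULT_H)
    if np.any(expected_cn < 1) or np.any(expected_cn > H):
        bad = expected_cn[(expected_cn < 1) | (expected_cn > H)]
        raise ValueError(f"expected_cn values {bad.tolist()} outside 1..{H}")
    alpha = np.full((expected_cn.size, H), DEFAULT_PRIOR_OFF)
    alpha[np.arange(expected_cn.size), expected_cn - 1] = DEFAULT_PRIOR_ON
    return CNAPrior(H=H, alpha=alpha)


@dataclass
class ModelParams:
    """Fitted (or hand-set) parameters of the clone mixture.

    ``pi`` maps modality name to its mixing proportions; in shared-pi and
    multiome modes both entries reference the same vector. ``theta`` and
    ``overdispersion`` map modality name to per-segment positive arrays.
    """

    K: int
    Phi: np.ndarray  # (K, I, H)
    pi: dict[str, np.ndarray]
    theta: dict[str, np.ndarray]
    overdispersion: dict[str, np.ndarray]
    lam: float = 0.5

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.ndim != 3 or self.Phi.shape[0] != self.K:
            raise ValueError("Phi must have shape (K, I, H)")
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if np.any(self.Phi < 0) or not np.allclose(
            self.Phi.sum(axis=2), 1.0, atol=1e-6
        ):
            raise ValueError("every Phi[k, i, :] must be a probability vector")
        for name, p in self.pi.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (self.K,) or np.any(p < 0) or not np.isclose(
                p.sum(), 1.0, atol=1e-6
            ):
                raise ValueError(f"pi[{name!r}] must be a K-simplex point")
        I = self.Phi.shape[1]
        for name in self.theta:
            th = np.asarray(self.theta[name], dtype=float)
            r = np.asarray(self.overdispersion[name], dtype=float)
            if th.shape != (I,) or np.any(th <= 0):
                raise ValueError(f"theta[{name!r}] must be positive, length I")
            if r.shape != (I,) or np.any(r <= 0):
                raise ValueError(
                    f"overdispersion[{name!r}] must be positive, length I"
                )

    @property
    def H(self) -> int:
        return self.Phi.shape[2]

    @property
    def n_segments(self) -> int:
        return self.Phi.shape[1]

    def mean_copy_numbers(self) -> np.ndarray:
        """Expected copy number per clone and segment, Phi . (1..H)."""
        h = np.arange(1, self.H + 1)
        return self.Phi @ h

    def map_copy_numbers(self) -> np.ndarray:
        """Most probable integer copy state per clone and segment.

        Ties break towards the smaller state.
        """
        return np.argmax(self.Phi, axis=2) + 1


def nb_mean(rho: float, theta: float, phi_vec: np.ndarray) -> float:
    """NB mean rho * theta * sum_h phi_h * h for copy states h = 1..H."""
    phi_vec = np.asarray(phi_vec, dtype=float)
    if abs(phi_vec.sum() - 1.0) > 1e-6:
        raise ValueError("phi_vec must sum to 1")
    if rho <= 0 or theta <= 0:
        raise ValueError("rho and theta must be positive")
    h = np.arange(1, phi_vec.size + 1)
    return float(rho * theta * phi_vec @ h)


def nb_logpmf(x, mu, size):
    """Negative Binomial log-pmf in mean/size parameterisation.

    Equivalent to scipy's nbinom with n = size and p = size/(size + mu);
    written out with gammaln so it broadcasts over arbitrary shapes.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    size = np.asarray(size, dtype=float)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be non-negative integers")
    if np.any(mu <= 0) or np.any(size <= 0):
        raise ValueError("mu and size must be positive")
    log_denom = np.log(size + mu)
    return (
        gammaln(x + size)
        - gammaln(size)
        - gammaln(x + 1)
        + size * (np.log(size) - log_denom)
        + x * (np.log(mu) - log_denom)
    )


def component_scores(
    data: SegmentedCounts, params: ModelParams, modality: str
) -> np.ndarray:
    """Per-cell, per-clone log-likelihoods s[n, k] = sum_i log NB(x_{n,i}).

    The building block shared by the flat and multiome likelihoods and by
    the responsibility computation.
    """
    if modality not in params.theta:
        raise ValueError(f"no parameters for modality {modality!r}")
    if data.n_segments != params.n_segments:
        raise ValueError(
            f"data has {data.n_segments} segments, params expect "
            f"{params.n_segments}"
        )
    x = data.counts.astype(float)  # (N, I)
    rho = data.effective_library_factors()  # (N,)
    theta = np.asarray(params.theta[modality], dtype=float)  # (I,)
    r = np.asarray(params.overdispersion[modality], dtype=float)  # (I,)
    h = np.arange(1.0, params.H + 1.0)
    c = params.Phi @ h  # (K, I) mean copy number
    mu = rho[:, None, None] * theta[None, None, :] * c[None, :, :]  # (N,K,I)
    lp = nb_logpmf(x[:, None, :], mu, r[None, None, :])
    return lp.sum(axis=2)


def modality_loglik(
    data: SegmentedCounts, params: ModelParams, modality: str | None = None
) -> float:
    """Marginal mixture log-likelihood of one modality.

    sum_n log sum_k pi_k prod_i NB(x_{n,i} | mu[k,i,n], r_i).
    """
    if modality is None:
        modality = data.modality
    if modality != data.modality:
        raise ValueError(
            f"data modality {data.modality!r} does not match requested "
            f"{modality!r}"
        )
    s = component_scores(data, params, modality)
    log_pi = np.log(np.asarray(params.pi[modality], dtype=float))
    return float(logsumexp(log_pi[None, :] + s, axis=1).sum())


def joint_loglik(
    rna: SegmentedCounts | None,
    atac: SegmentedCounts | None,
    params: ModelParams,
) -> float:
    """Shrinkage combination lambda*L_RNA + (1-lambda)*L_ATAC.

    At the boundaries (lambda = 1 or 0) the absent modality may be None.
    """
    lam = params.lam
    if rna is None and lam > 0:
        raise ValueError("RNA data required when lambda > 0")
    if atac is None and lam < 1:
        raise ValueError("ATAC data required when lambda < 1")
    total = 0.0
    if lam > 0:
        total += lam * modality_loglik(rna, params, "RNA")
    if lam < 1:
        total += (1.0 - lam) * modality_loglik(atac, params, "ATAC")
    return float(total)


def multiome_loglik(
    rna: SegmentedCounts, atac: SegmentedCounts, params: ModelParams
) -> float:
    """Shared-assignment likelihood for paired (multiome) assays.

    Each physical cell has one clone assignment driving both its RNA and
    ATAC counts; lambda tempers the per-cell log-likelihood of each
    modality inside the mixture:

        sum_n log sum_k pi_k exp(lambda*s^R_{n,k} + (1-lambda)*s^A_{n,k}).
    """
    if rna.barcodes != atac.barcodes:
        raise ValueError("multiome likelihood requires paired barcodes")
    s_r = component_scores(rna, params, "RNA")
    s_a = component_scores(atac, params, "ATAC")
    log_pi = np.log(np.asarray(params.pi["RNA"], dtype=float))
    t = log_pi[None, :] + params.lam * s_r + (1.0 - params.lam) * s_a
    return float(logsumexp(t, axis=1).sum())
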