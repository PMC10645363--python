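"""Stochastic variational inference for the clone mixture.

The copy-state tensor Phi is optimised through a Gumbel-Softmax
relaxation: the per-(clone, segment) categorical over copy states is
parameterised by logits, and at every step a noisy simplex sample

    phi = softmax((logits + Gumbel noise) / temperature)

is pushed through the lambda-weighted mixture log-likelihood plus the
Dirichlet log-prior. The temperature anneals from 1.0 towards 0.1 so the
relaxation sharpens as optimisation proceeds. Mixing proportions, rates
and overdispersions are point-estimated (delta factors) on softmax/log
scales. Clone assignments z are never relaxed: the mixture is evaluated
with z marginalised by enumeration over K, and responsibilities are
recovered exactly by Bayes' rule at the fitted parameters.

All gradients are analytic (negative-binomial score functions chained
through the softmax Jacobians) and the whole update runs on dense numpy
arrays; one Adam step costs O(N * K * I).

Model selection over K uses BIC (default), AIC or ICL:

    BIC = v ln(n) - 2L,  AIC = 2v - 2L,  ICL = BIC + H(z),

with v the parameter count, n the total number of observed cells and
H(z) the entropy of the posterior assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .model import (
    CNAPrior,
    ModelParams,
    component_scores,
    joint_loglik,
    modality_loglik,
    multiome_loglik,
)
from .segdata import SegmentedCounts

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "select_model",
    "responsibilities",
    "map_copy_numbers",
    "count_parameters",
    "compute_scores",
    "save_fit",
]

MODES = ("flat", "flat_shared_pi", "multiome")
SCORES = ("BIC", "AIC", "ICL")


@dataclass
class FitConfig:
    """Knobs of the variational fit.

    lam weighs the RNA log-likelihood against ATAC (1 = RNA only);
    temperature_anneal defaults to the multiplicative decay that reaches
    ``temperature_min`` at the final step.
    """

    K_range: Sequence[int] = tuple(range(1, 9))
    lam: float = 0.5
    steps: int = 1000
    polish_steps: int = 200
    learning_rate: float = 0.05
    temperature: float = 1.0
    temperature_min: float = 0.1
    temperature_anneal: float | None = None
    seed: int = 0
    mode: str = "flat"
    score: str = "BIC"
    restarts: int = 3
    tol: float = 1e-5
    tol_window: int = 20

    def __post_init__(self) -> None:
        if not self.K_range:
            raise ValueError("K_range must be non-empty")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.score not in SCORES:
            raise ValueError(f"score must be one of {SCORES}")
        if self.steps < 1 or self.restarts < 1:
            raise ValueError("steps and restarts must be positive")

    def anneal_factor(self) -> float:
        if self.temperature_anneal is not None:
            return self.temperature_anneal
        span = max(self.steps - 1, 1)
        return (self.temperature_min / self.temperature) ** (1.0 / span)


@dataclass
class FitResult:
    """Outcome of one fit at fixed K."""

    params: ModelParams
    mode: str
    responsibilities: dict[str, np.ndarray]
    assignments: dict[str, np.ndarray]
    map_cn: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    scores: dict[str, float]
    elbo_trace: np.ndarray
    restart_elbos: list[float]
    converged_step: int | None
    empty_clusters: list[int]
    raw_params: dict = field(default_factory=dict, repr=False)
    barcodes: dict[str, list[str]] = field(default_factory=dict, repr=False)

    @property
    def K(self) -> int:
        return self.params.K


# ---------------------------------------------------------------------------
# objective + analytic gradients


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    return z - logsumexp(z, axis=axis, keepdims=True)


class _ModalityData:
    """Pre-extracted arrays for one modality."""

    def __init__(self, data: SegmentedCounts):
        self.name = data.modality
        self.x = data.counts.astype(float)  # (N, I)
        self.rho = data.effective_library_factors()  # (N,)
        self.n_cells = data.n_cells
        self.segment_ids = data.segment_ids
        self.lgx = gammaln(self.x + 1.0)  # fixed part of the NB log-pmf


def _nb_scores_and_grads(md: _ModalityData, theta, r, c):
    """NB mixture component scores with the pieces needed for gradients.

    Returns s (N, K) per-cell component log-likelihoods, plus closures'
    worth of intermediates: mu (N,K,I) and the 2-D overdispersion score
    part A (N, I).
    """
    mu = md.rho[:, None, None] * theta[None, None, :] * c[None, :, :]
    log_rmu = np.log(r[None, None, :] + mu)
    lp = (
        (gammaln(md.x + r[None, :]) - gammaln(r)[None, :] - md.lgx)[:, None, :]
        + r[None, None, :] * (np.log(r)[None, None, :] - log_rmu)
        + md.x[:, None, :] * (np.log(mu) - log_rmu)
    )
    s = lp.sum(axis=2)
    return s, mu, log_rmu


def _accumulate_modality_grads(
    md: _ModalityData, R, weight, theta, r, c, mu, log_rmu, grads, key
):
    """Add one modality's weighted likelihood gradients into ``grads``.

    R (N, K) are the responsibilities under which the marginal-likelihood
    gradient decomposes (softmax of the per-cell component scores).
    """
    x3 = md.x[:, None, :]
    ratio = (x3 + r[None, None, :]) / (r[None, None, :] + mu)
    # d loglik / d mu times mu (avoids 1/mu):  R * (x - mu * ratio)
    gmu_mu = R[:, :, None] * (x3 - mu * ratio)
    M1 = gmu_mu.sum(axis=0)  # (K, I)
    grads[f"log_theta:{key}"] += weight * M1.sum(axis=0)
    grads["_c"] += weight * M1 / c
    # overdispersion: 2-D part sums over k to 1 per cell
    A = (
        digamma(md.x + r[None, :])
        - digamma(r)[None, :]
        + (np.log(r) + 1.0)[None, :]
    )
    B = np.einsum("nk,nki->i", R, log_rmu + ratio)
    grads[f"log_r:{key}"] += weight * r * (A.sum(axis=0) - B)


def _objective(params, pack, prior, cfg, gumbel, tau, want_grads=True):
    """lambda-weighted log-likelihood + Dirichlet log-prior on Phi.

    ``gumbel`` is None for a noise-free evaluation at temperature 1.
    Returns (objective, grads or None, diagnostics dict).
    """
    K = params["phi"].shape[0]
    H = params["phi"].shape[2]
    h = np.arange(1.0, H + 1.0)
    if gumbel is None:
        u = params["phi"]
        tau = 1.0
    else:
        u = (params["phi"] + gumbel) / tau
    log_phi = _log_softmax(u, axis=2)
    phi = np.exp(log_phi)
    c = phi @ h  # (K, I)

    grads = None
    if want_grads:
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        grads["_c"] = np.zeros_like(c)

    obj = 0.0
    resp = {}
    modality_weights = pack["weights"]
    if pack["mode"] == "multiome":
        names = list(modality_weights)
        parts = {}
        for name in names:
            md = pack["data"][name]
            theta = np.exp(params[f"log_theta:{name}"])
            r = np.exp(params[f"log_r:{name}"])
            parts[name] = (_nb_scores_and_grads(md, theta, r, c), theta, r)
        log_pi = _log_softmax(params["pi"])
        t = log_pi[None, :]
        for name in names:
            (s, _, _), _, _ = parts[name]
            t = t + modality_weights[name] * s
        ll_n = logsumexp(t, axis=1)
        obj += ll_n.sum()
        R = np.exp(t - ll_n[:, None])
        resp["cells"] = R
        if want_grads:
            pi = np.exp(log_pi)
            grads["pi"] += R.sum(axis=0) - R.shape[0] * pi
            for name in names:
                (s, mu, log_rmu), theta, r = parts[name]
                _accumulate_modality_grads(
                    pack["data"][name], R, modality_weights[name],
                    theta, r, c, mu, log_rmu, grads, name,
                )
    else:
        for name, weight in modality_weights.items():
            if weight == 0.0:
                continue
            md = pack["data"][name]
            theta = np.exp(params[f"log_theta:{name}"])
            r = np.exp(params[f"log_r:{name}"])
            s, mu, log_rmu = _nb_scores_and_grads(md, theta, r, c)
            pi_key = "pi" if "pi" in params else f"pi:{name}"
            log_pi = _log_softmax(params[pi_key])
            t = log_pi[None, :] + s
            ll_n = logsumexp(t, axis=1)
            obj += weight * ll_n.sum()
            R = np.exp(t - ll_n[:, None])
            resp[name] = R
            if want_grads:
                pi = np.exp(log_pi)
                grads[pi_key] += weight * (R.sum(axis=0) - R.shape[0] * pi)
                _accumulate_modality_grads(
                    md, R, weight, theta, r, c, mu, log_rmu, grads, name
                )

    # Dirichlet prior on each Phi[k, i, :]
    am1 = prior.alpha[None, :, :] - 1.0  # (1, I, H)
    obj += float((am1 * log_phi).sum())

    # Entropy of the Gumbel-Softmax variational factor, -E_q[log q(phi)],
    # estimated at the current sample. Without it the alpha < 1 prior
    # density diverges at the simplex vertices and would dominate the
    # objective; the Concrete density's -(tau+1) log phi terms grow
    # faster, keeping the ELBO bounded. Density from the Concrete
    # distribution: log q(phi) = log (H-1)! + (H-1) log tau
    #   + sum_h [l_h - (tau+1) log phi_h] - H log sum_h exp(l_h) phi_h^-tau.
    ell = params["phi"]
    t_w = ell - tau * log_phi
    log_S = logsumexp(t_w, axis=2, keepdims=True)
    K_, I_, H_ = phi.shape
    neg_log_q = (
        -gammaln(H_)  # log (H-1)!
        - (H_ - 1) * np.log(tau)
        - float(ell.sum())
        + (tau + 1.0) * float(log_phi.sum())
        + H_ * float(log_S.sum())
    )
    obj += neg_log_q

    if want_grads:
        w = np.exp(t_w - log_S)
        # chain rule through the (tempered) softmax; for the prior and
        # entropy terms phi * dterm/dphi is closed form and bounded
        phi_g = (
            phi * (grads.pop("_c")[:, :, None] * h[None, None, :])
            + am1
            + (tau + 1.0)
            - H_ * tau * w
        )
        inner = phi_g.sum(axis=2, keepdims=True)
        grads["phi"] = (phi_g - phi * inner) / tau
        # direct dependence of -log q on the logits
        grads["phi"] += H_ * w - 1.0
    return float(obj), grads, resp


def _diagnose_nonfinite(params, pack) -> str:
    bad: set[str] = set()
    for name, md in pack["data"].items():
        theta = np.exp(params[f"log_theta:{name}"])
        r = np.exp(params[f"log_r:{name}"])
        for i, sid in enumerate(md.segment_ids):
            if not (
                np.isfinite(theta[i]) and np.isfinite(r[i])
                and theta[i] > 0 and r[i] > 0
            ):
                bad.add(sid)
    return ", ".join(sorted(bad)) if bad else "unknown segment"


# ---------------------------------------------------------------------------
# initialisation


def _initial_params(pack, prior: CNAPrior, K: int, rng) -> dict:
    """K-means initialisation of copy-state logits on per-cell copy estimates.

    Per-cell crude copy numbers x / (rho * theta0) from all modalities are
    stacked and clustered, each row weighted by its modality's weight in
    the joint objective (lambda for RNA, 1 - lambda for ATAC) so the
    initial centres reflect the same evidence balance the fit optimises;
    cluster centres seed the copy-state logits and cluster sizes the
    mixing logits. Jitter keeps restarts diverse.
    """
    H = prior.H
    expected = prior.expected_cn.astype(float)
    params: dict[str, np.ndarray] = {}
    chat_rows = []
    row_modality = []
    row_weight = []
    for name, md in pack["data"].items():
        per_copy = (md.x / md.rho[:, None]).mean(axis=0) / expected
        theta0 = np.maximum(per_copy, 1e-3)
        params[f"log_theta:{name}"] = np.log(theta0)
        chat = md.x / (md.rho[:, None] * theta0[None, :])
        chat_rows.append(np.clip(chat, 0.0, H + 2.0))
        row_modality.extend([name] * md.n_cells)
        row_weight.extend([pack["weights"][name]] * md.n_cells)
    chat_all = np.vstack(chat_rows)
    row_modality = np.asarray(row_modality)
    row_weight = np.asarray(row_weight) + 1e-12

    if K == 1:
        centers = np.average(
            chat_all, axis=0, weights=row_weight
        )[None, :]
        labels = np.zeros(chat_all.shape[0], dtype=int)
    else:
        km = KMeans(
            n_clusters=K,
            n_init=4,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(chat_all, sample_weight=row_weight)
        centers, labels = km.cluster_centers_, km.labels_
    # Copy number and rate are only identified jointly (mu = rho*theta*c),
    # so the crude estimates sit on an arbitrary scale whenever the true
    # mean copy of a segment differs from the prior one. Re-anchor each
    # segment: choose the integer state for the heaviest cluster that
    # lets every cluster centre sit closest to the 1..H grid (mildly
    # preferring the prior state), and absorb the rescaling into theta.
    mass = np.array(
        [row_weight[labels == k].sum() for k in range(K)]
    )
    mass = mass / mass.sum()
    prior_state = prior.expected_cn
    anchor = int(np.argmax(mass))
    hgrid = np.arange(1, H + 1)
    for i in range(centers.shape[1]):
        e = np.maximum(centers[:, i], 1e-3)
        best_s, best_cost = 1.0, np.inf
        for hstar in hgrid:
            s = hstar / e[anchor]
            snapped = np.clip(np.rint(e * s), 1, H)
            # deviation measured on the original copy scale, otherwise
            # scaling down would shrink the residuals spuriously
            cost = float(mass @ np.abs(e * s - snapped)) / s
            cost += 0.05 * abs(hstar - prior_state[i])
            if cost < best_cost:
                best_cost, best_s = cost, s
        centers[:, i] *= best_s
        for name in pack["data"]:
            params[f"log_theta:{name}"][i] -= np.log(best_s)
    centers = np.clip(centers, 1.0, float(H))
    hvals = np.arange(1.0, H + 1.0)
    logits = -2.0 * np.abs(hvals[None, None, :] - centers[:, :, None])
    logits += 0.5 * rng.normal(size=logits.shape)
    params["phi"] = logits

    # Method-of-moments start for the overdispersion, pooled within the
    # initial clusters so clone structure is not mistaken for noise:
    # Var(x) = mu + mu^2 / r  =>  r = mu^2 / (Var - mu).
    offset = 0
    for name, md in pack["data"].items():
        sub = labels[offset : offset + md.n_cells]
        offset += md.n_cells
        xr = md.x / md.rho[:, None]
        num = np.zeros(md.x.shape[1])
        den = np.zeros(md.x.shape[1])
        for k in range(K):
            sel = sub == k
            if sel.sum() < 3:
                continue
            m = xr[sel].mean(axis=0)
            var = xr[sel].var(axis=0)
            num += sel.sum() * m**2
            den += sel.sum() * np.maximum(var - m, 1e-9)
        r0 = np.clip(np.where(den > 0, num / den, 10.0), 0.5, 1000.0)
        params[f"log_r:{name}"] = np.log(r0)

    def _pi_logits(lbls):
        frac = np.bincount(lbls, minlength=K) + 0.5
        return np.log(frac / frac.sum())

    if pack["mode"] == "flat" and len(pack["data"]) == 2:
        for name in pack["data"]:
            params[f"pi:{name}"] = _pi_logits(labels[row_modality == name])
    else:
        params["pi"] = _pi_logits(labels)
    return params


# ---------------------------------------------------------------------------
# the fit itself


def _build_pack(rna, atac, cfg: FitConfig) -> dict:
    lam = cfg.lam
    if cfg.mode == "multiome":
        if rna is None or atac is None:
            raise ValueError("multiome mode requires both modalities")
        if rna.barcodes != atac.barcodes:
            raise ValueError(
                "multiome mode requires paired data with identical barcodes "
                "(run pair_multiome first)"
            )
    if cfg.mode == "flat_shared_pi" and (rna is None or atac is None):
        raise ValueError("flat_shared_pi mode requires both modalities")
    if rna is None and atac is None:
        raise ValueError("at least one modality is required")
    if rna is None and lam > 0:
        raise ValueError("lambda > 0 but no RNA data; set lam=0")
    if atac is None and lam < 1:
        raise ValueError("lambda < 1 but no ATAC data; set lam=1")
    data = {}
    weights = {}
    if rna is not None and lam > 0:
        data["RNA"] = _ModalityData(rna)
        weights["RNA"] = lam
    if atac is not None and lam < 1:
        data["ATAC"] = _ModalityData(atac)
        weights["ATAC"] = 1.0 - lam
    seg_ids = None
    for md in data.values():
        if seg_ids is None:
            seg_ids = md.segment_ids
        elif md.segment_ids != seg_ids:
            raise ValueError("modalities must share the segment list")
    return {"mode": cfg.mode, "data": data, "weights": weights}


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for key, g in grads.items():
        m, v = state[key]
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[key] = (m, v)
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[key] += lr * mhat / (np.sqrt(vhat) + eps)


def _run_restart(pack, prior, K, cfg: FitConfig, restart: int, init=None):
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(restart)])
    )
    if init is None:
        params = _initial_params(pack, prior, K, rng)
    else:
        params = {k: v.copy() for k, v in init.items()}
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    anneal = cfg.anneal_factor()
    tau = cfg.temperature
    trace = np.empty(cfg.steps)
    converged_at = None
    w = cfg.tol_window
    for t in range(cfg.steps):
        gumbel = rng.gumbel(size=params["phi"].shape)
        obj, grads, _ = _objective(params, pack, prior, cfg, gumbel, tau)
        if not np.isfinite(obj):
            raise RuntimeError(
                "non-finite ELBO during optimisation; offending segment(s): "
                + _diagnose_nonfinite(params, pack)
            )
        trace[t] = obj
        _adam_step(params, grads, state, cfg.learning_rate, t + 1)
        tau = max(cfg.temperature_min, tau * anneal)
        if t + 1 >= 2 * w and (t + 1) % 10 == 0:
            recent = trace[t + 1 - w : t + 1].mean()
            before = trace[t + 1 - 2 * w : t + 1 - w].mean()
            if abs(recent - before) <= cfg.tol * (abs(before) + 1e-12):
                converged_at = t + 1
                trace = trace[: t + 1]
                break
    # Deterministic polish: once the relaxation has annealed, ascend the
    # noise-free objective (the ELBO integrand at the variational mean)
    # to sharpen the slow-moving rate/overdispersion tail.
    polish = []
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    prev = -np.inf
    for t in range(cfg.polish_steps):
        obj, grads, _ = _objective(params, pack, prior, cfg, None, 1.0)
        if not np.isfinite(obj):
            raise RuntimeError(
                "non-finite ELBO during optimisation; offending segment(s): "
                + _diagnose_nonfinite(params, pack)
            )
        polish.append(obj)
        _adam_step(params, grads, state, cfg.learning_rate, t + 1)
        if abs(obj - prev) <= cfg.tol * (abs(obj) + 1e-12):
            break
        prev = obj
    trace = np.concatenate([trace, polish]) if polish else trace
    final_obj, _, _ = _objective(
        params, pack, prior, cfg, gumbel=None, tau=1.0, want_grads=False
    )
    return params, trace, final_obj, converged_at


def _finalise(params_raw, pack, prior, K, cfg: FitConfig) -> ModelParams:
    Phi = _softmax(params_raw["phi"], axis=2)
    names = list(pack["data"])
    if "pi" in params_raw:
        shared_pi = _softmax(params_raw["pi"])
        pi = {name: shared_pi for name in names}
    else:
        pi = {name: _softmax(params_raw[f"pi:{name}"]) for name in names}
    theta = {name: np.exp(params_raw[f"log_theta:{name}"]) for name in names}
    overdisp = {name: np.exp(params_raw[f"log_r:{name}"]) for name in names}
    return ModelParams(
        K=K, Phi=Phi, pi=pi, theta=theta, overdispersion=overdisp, lam=cfg.lam
    )


def _exact_responsibilities(rna, atac, params: ModelParams, mode: str):
    """Posterior p(z = k | x) by Bayes' rule at the given parameters."""
    if mode == "multiome":
        s_r = component_scores(rna, params, "RNA")
        s_a = component_scores(atac, params, "ATAC")
        t = (
            np.log(params.pi["RNA"])[None, :]
            + params.lam * s_r
            + (1 - params.lam) * s_a
        )
        return {"cells": np.exp(t - logsumexp(t, axis=1, keepdims=True))}
    out = {}
    for data in (rna, atac):
        if data is None:
            continue
        name = data.modality
        if name not in params.pi:
            continue
        s = component_scores(data, params, name)
        t = np.log(params.pi[name])[None, :] + s
        out[name] = np.exp(t - logsumexp(t, axis=1, keepdims=True))
    return out


def fit(
    rna: SegmentedCounts | None,
    atac: SegmentedCounts | None,
    prior: CNAPrior,
    K: int,
    config: FitConfig | None = None,
    warm_init: dict | None = None,
) -> FitResult:
    """Fit the K-clone model by SVI; best of ``config.restarts`` starts.

    ``warm_init`` optionally supplies one extra starting point in raw
    (unconstrained) parameter space, e.g. a smaller model with a cluster
    split, as used by :func:`select_model`. Deterministic given
    ``config.seed``. Returns MAP parameters, exact posterior
    responsibilities, the MAP integer copy-number matrix and BIC/AIC/ICL
    scores.
    """
    cfg = config or FitConfig()
    pack = _build_pack(rna, atac, cfg)
    n_obs = sum(md.n_cells for md in pack["data"].values())
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_obs:
        raise ValueError(f"K={K} exceeds the number of cells ({n_obs})")
    I = next(iter(pack["data"].values())).x.shape[1]
    if prior.n_segments != I:
        raise ValueError(
            f"prior covers {prior.n_segments} segments, data has {I}"
        )

    best = None
    restart_elbos = []
    starts: list[tuple[int, dict | None]] = [
        (r, None) for r in range(cfg.restarts)
    ]
    if warm_init is not None:
        starts.append((cfg.restarts, warm_init))
    for restart, init in starts:
        result = _run_restart(pack, prior, K, cfg, restart, init)
        restart_elbos.append(result[2])
        if best is None or result[2] > best[2]:
            best = result
    params_raw, trace, _, converged_at = best
    params = _finalise(params_raw, pack, prior, K, cfg)

    resp = _exact_responsibilities(rna, atac, params, cfg.mode)
    assignments = {k: np.argmax(v, axis=1) for k, v in resp.items()}
    barcode_map = {}
    for key in resp:
        if key == "cells":
            barcode_map[key] = list(rna.barcodes)
        else:
            barcode_map[key] = list((rna if key == "RNA" else atac).barcodes)
    if cfg.mode == "multiome":
        loglik = multiome_loglik(rna, atac, params)
    elif len(pack["data"]) == 2:
        loglik = joint_loglik(rna, atac, params)
    else:
        data = rna if "RNA" in pack["data"] else atac
        loglik = modality_loglik(data, params)
    v = count_parameters(K, I, prior.H, len(pack["data"]), cfg.mode)
    n_for_score = n_obs
    scores = compute_scores(loglik, v, n_for_score, resp)
    mass = sum(r.sum(axis=0) for r in resp.values())
    empty = [int(k) for k in np.flatnonzero(mass < 1.0)]
    return FitResult(
        params=params,
        mode=cfg.mode,
        responsibilities=resp,
        assignments=assignments,
        map_cn=params.map_copy_numbers(),
        loglik=loglik,
        n_params=v,
        n_obs=n_for_score,
        scores=scores,
        elbo_trace=trace,
        restart_elbos=restart_elbos,
        converged_step=converged_at,
        empty_clusters=empty,
        raw_params=params_raw,
        barcodes=barcode_map,
    )


def responsibilities(result: FitResult) -> dict[str, np.ndarray]:
    """Posterior assignment probabilities (rows sum to 1), per modality
    in flat mode or one shared set ("cells") in multiome mode."""
    return result.responsibilities


def map_copy_numbers(result: FitResult) -> np.ndarray:
    """MAP integer copy number per clone and segment (ties to smaller h)."""
    return result.map_cn


def count_parameters(
    K: int, I: int, H: int, modalities: int, mode: str = "flat"
) -> int:
    """Free-parameter count v used by the information criteria.

    Independent mixing weights (2(K-1) for flat with two modalities,
    K-1 otherwise) + K*I*(H-1) copy-state probabilities + one rate and
    one overdispersion per segment per modality.
    """
    if min(K, I, H, modalities) < 1:
        raise ValueError("all inputs must be positive")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    mixing = 2 * (K - 1) if (mode == "flat" and modalities == 2) else K - 1
    return mixing + K * I * (H - 1) + modalities * I + modalities * I


def assignment_entropy(responsibilities) -> float:
    """H(z) = -sum_n sum_k z_nk ln z_nk, with 0 ln 0 = 0."""
    if isinstance(responsibilities, dict):
        mats = list(responsibilities.values())
    else:
        mats = [np.asarray(responsibilities)]
    total = 0.0
    for R in mats:
        R = np.asarray(R, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(R > 0, R * np.log(R), 0.0)
        total -= term.sum()
    return float(total)


def compute_scores(loglik: float, v: int, n: int, responsibilities) -> dict:
    """BIC = v ln n - 2L, AIC = 2v - 2L, ICL = BIC + H(z)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ent = assignment_entropy(responsibilities)
    bic = v * np.log(n) - 2.0 * loglik
    aic = 2.0 * v - 2.0 * loglik
    return {"BIC": float(bic), "AIC": float(aic), "ICL": float(bic + ent),
            "entropy": ent}


def _split_largest_cluster(result: FitResult, rng) -> dict:
    """Warm start for K+1: duplicate the heaviest cluster with jitter.

    The duplicated copy-state logits get enough noise for the two halves
    to specialise, and the cluster's mixing weight is shared between the
    copies.
    """
    raw = {k: v.copy() for k, v in result.raw_params.items()}
    mass = sum(R.sum(axis=0) for R in result.responsibilities.values())
    j = int(np.argmax(mass))
    new_row = raw["phi"][j : j + 1] + rng.normal(0.0, 0.7, raw["phi"][j:j+1].shape)
    raw["phi"] = np.concatenate([raw["phi"], new_row], axis=0)
    for key in list(raw):
        if key == "pi" or key.startswith("pi:"):
            p = raw[key]
            p[j] -= np.log(2.0)
            raw[key] = np.concatenate([p, p[j : j + 1]])
    return raw


def select_model(
    rna: SegmentedCounts | None,
    atac: SegmentedCounts | None,
    prior: CNAPrior,
    config: FitConfig | None = None,
) -> tuple[FitResult, pd.DataFrame]:
    """Fit every K in ``config.K_range`` and keep the best-scoring model.

    K values are visited in increasing order and each fit seeds one
    extra restart of the next by splitting the heaviest cluster of the
    best current model, so the log-likelihood is near-monotone in K.
    Returns the winning fit (minimum of the configured score) and the
    full score table, one row per K.
    """
    cfg = config or FitConfig()
    rows = []
    fits: dict[int, FitResult] = {}
    prev: FitResult | None = None
    warm_rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), 2**20])
    )
    for K in sorted(set(int(k) for k in cfg.K_range)):
        warm = (
            _split_largest_cluster(prev, warm_rng)
            if prev is not None and prev.K == K - 1
            else None
        )
        try:
            res = fit(rna, atac, prior, K, cfg, warm_init=warm)
        except Exception as exc:
            raise RuntimeError(f"fit failed at K={K}: {exc}") from exc
        fits[K] = res
        prev = res
        rows.append(
            {
                "K": K,
                "loglik": res.loglik,
                "n_params": res.n_params,
                "BIC": res.scores["BIC"],
                "AIC": res.scores["AIC"],
                "ICL": res.scores["ICL"],
                "entropy": res.scores["entropy"],
                "empty_clusters": len(res.empty_clusters),
                "converged_step": res.converged_step,
            }
        )
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table[cfg.score].idxmin(), "K"])
    return fits[best_k], table


def save_fit(
    result: FitResult,
    outdir: str | Path,
    score_table: pd.DataFrame | None = None,
) -> None:
    """Write assignments, MAP copy numbers, scores and the Phi posterior.

    Layout: ``assignments.tsv`` (barcode, modality, cluster, max
    responsibility; multiome fits use the shared "cells" block),
    ``map_cn.tsv`` (cluster x segment_id), ``scores.tsv``, and
    ``phi_posterior.npz`` holding the (K, I, H) tensor under key
    ``phi`` and the MAP copy-number matrix under ``map_cn``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, R in result.responsibilities.items():
        hard = np.argmax(R, axis=1)
        bcs = result.barcodes.get(name, [str(n) for n in range(R.shape[0])])
        for n in range(R.shape[0]):
            rows.append(
                {
                    "barcode": bcs[n],
                    "modality": name,
                    "cluster": int(hard[n]),
                    "max_responsibility": float(R[n, hard[n]]),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        result.map_cn,
        index=[f"cluster_{k}" for k in range(result.K)],
    ).to_csv(outdir / "map_cn.tsv", sep="\t")
    if score_table is not None:
        score_table.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    np.savez(
        outdir / "phi_posterior.npz",
        phi=result.params.Phi,
        map_cn=result.map_cn,
    )
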