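"""Penalized maximum-likelihood estimation by multiplicative updates.

Θ and Ψ are alternately rescaled by ratios of the positive and negative
parts of the objective gradient, the standard multiplicative scheme for
nonnegatively constrained factorization problems.  Updates preserve
nonnegativity and zeros exactly, so complexes whose affinity column hits
zero are permanently pruned — this is what lets the exponential prior select
the effective number of complexes when K is set generously.

Because the objective is not convex, the fit is repeated from several random
initializations and the restart with the lowest final objective wins.

The expensive sums are evaluated only at observed edges and annotations
(sparse form), so one iteration costs O(K(N + C + E + R)) where E is the
edge count and R the association count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .model import (
    EPS,
    FitResult,
    FunctionalProfile,
    ModelParams,
    PPINetwork,
    _check_dims,
    objective,
)

__all__ = ["FitConfig", "update_theta", "update_psi", "fit"]

logger = logging.getLogger("gmftp")


@dataclass
class FitConfig:
    """Settings for one fit.

    Defaults follow the reference protocol: a deliberately generous number of
    latent complexes (K = 1000) pruned by the sparsity prior (λ = 4),
    100 random restarts, and iteration until the relative objective change
    drops below 1e-6 or 400 iterations are reached.
    """

    K: int = 1000
    lam: float = 4.0
    n_restarts: int = 100
    tol: float = 1e-6
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_restarts < 1 or self.max_iter < 1:
            raise ValueError("K, n_restarts and max_iter must be positive integers")
        if not (self.lam > 0 and self.tol > 0):
            raise ValueError("lam and tol must be positive")


def _edge_pred(Theta: np.ndarray, ai: np.ndarray, aj: np.ndarray) -> np.ndarray:
    """Linear predictor Σ_k θ_ik θ_jk at the listed (directed) edges."""
    return np.einsum("ek,ek->e", Theta[ai], Theta[aj])


def _assoc_pred(Theta: np.ndarray, Psi: np.ndarray,
                fi: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Linear predictor Σ_k θ_ik ψ_kc at the listed (protein, term) cells."""
    return np.einsum("ek,ke->e", Theta[fi], Psi[:, fc])


def update_theta(params: ModelParams, net: PPINetwork,
                 prof: FunctionalProfile) -> np.ndarray:
    """One multiplicative update of Θ with Ψ held fixed.

    Each θ_ik is rescaled by the ratio of the negative to the positive part
    of ∂(objective)/∂θ_ik:

        numerator_ik   = S_i Σ_c F_ic ψ_kc / σ(Σ_k θ_ik ψ_kc)
                         + Σ_j A_ij θ_jk / σ(Σ_k θ_ik θ_jk)
        denominator_ik = S_i Σ_c ψ_kc + Σ_{j≠i} θ_jk + λ

    Zero entries stay zero; the result is elementwise nonnegative.
    """
    _check_dims(params, net, prof)
    ai, aj = np.nonzero(net.A)  # both directions
    fi, fc = np.nonzero(prof.F * prof.S[:, None])
    return _update_theta_fast(params.Theta, params.Psi, params.lam,
                              net.n_proteins, prof.n_terms,
                              ai, aj, fi, fc, prof.S)


def _update_theta_fast(Theta, Psi, lam, N, C, ai, aj, fi, fc, S) -> np.ndarray:
    p_e = np.maximum(-np.expm1(-_edge_pred(Theta, ai, aj)), EPS)
    W = sp.csr_matrix((1.0 / p_e, (ai, aj)), shape=(N, N))
    net_num = W @ Theta

    q_f = np.maximum(-np.expm1(-_assoc_pred(Theta, Psi, fi, fc)), EPS)
    Wf = sp.csr_matrix((1.0 / q_f, (fi, fc)), shape=(N, C))
    fun_num = Wf @ Psi.T

    denom = (S[:, None] * Psi.sum(axis=1)[None, :]
             + (Theta.sum(axis=0)[None, :] - Theta) + lam)
    return Theta * (fun_num + net_num) / denom


def update_psi(params: ModelParams, prof: FunctionalProfile) -> np.ndarray:
    """One multiplicative update of Ψ with Θ held fixed.

        ψ_kc ← ψ_kc · (Σ_i S_i F_ic θ_ik / σ(Σ_k θ_ik ψ_kc))
                      / (Σ_i S_i θ_ik + λ)
    """
    if prof.F.shape[0] != params.n_proteins or prof.n_terms != params.n_terms:
        raise ValueError("profile dimensions do not match params")
    fi, fc = np.nonzero(prof.F * prof.S[:, None])
    return _update_psi_fast(params.Theta, params.Psi, params.lam,
                            prof.F.shape[0], prof.n_terms, fi, fc, prof.S)


def _update_psi_fast(Theta, Psi, lam, N, C, fi, fc, S) -> np.ndarray:
    q_f = np.maximum(-np.expm1(-_assoc_pred(Theta, Psi, fi, fc)), EPS)
    Wf = sp.csr_matrix((1.0 / q_f, (fi, fc)), shape=(N, C))
    num = (Wf.T @ Theta).T  # K×C
    denom = (S @ Theta)[:, None] + lam
    return Psi * num / denom


def fit(net: PPINetwork, prof: FunctionalProfile, cfg: FitConfig) -> FitResult:
    """Estimate Θ and Ψ from an observed network and annotation profile.

    For each restart, Θ and Ψ are initialized i.i.d. Uniform(0, 1) from a
    per-restart seed (``cfg.seed + restart index``), then updated alternately
    (full Θ update with current Ψ, then full Ψ update with the new Θ) until
    the relative change of the objective between consecutive iterations falls
    below ``cfg.tol`` or ``cfg.max_iter`` iterations are reached.  The restart
    with the lowest final objective is returned; restarts ending at an
    infinite objective are never selected.

    Deterministic given ``cfg.seed``.
    """
    if net.n_proteins < 3:
        raise ValueError("network must contain at least 3 proteins")
    if prof.F.shape[0] != net.n_proteins:
        raise ValueError("profile and network disagree on N")
    N, C, K = net.n_proteins, prof.n_terms, cfg.K

    ai, aj = np.nonzero(net.A)
    fi, fc = np.nonzero(prof.F * prof.S[:, None])
    S = prof.S.astype(float)

    best: FitResult | None = None
    for r in range(cfg.n_restarts):
        rng = np.random.default_rng(cfg.seed + r)
        Theta = rng.uniform(size=(N, K))
        Psi = rng.uniform(size=(K, C))

        params = ModelParams(Theta=Theta, Psi=Psi, lam=cfg.lam)
        trace = [objective(params, net, prof)]
        for _ in range(cfg.max_iter):
            Theta = _update_theta_fast(Theta, Psi, cfg.lam, N, C, ai, aj, fi, fc, S)
            Psi = _update_psi_fast(Theta, Psi, cfg.lam, N, C, fi, fc, S)
            params = ModelParams(Theta=Theta, Psi=Psi, lam=cfg.lam)
            obj = objective(params, net, prof)
            trace.append(obj)
            if np.isfinite(obj) and np.isfinite(trace[-2]):
                if abs(obj - trace[-2]) < cfg.tol * abs(trace[-2]):
                    break
        final = trace[-1]
        logger.debug("restart %d: objective %.6g after %d iterations",
                     r, final, len(trace) - 1)
        if best is None or (np.isfinite(final)
                            and final < best.objective_trace[-1]):
            best = FitResult(params_hat=params, objective_trace=trace,
                             T=len(trace) - 1, n_restarts=cfg.n_restarts,
                             best_restart_index=r, seed=cfg.seed)
    assert best is not None
    if not np.isfinite(best.objective_trace[-1]):
        logger.warning("all restarts ended with an infinite objective")
    logger.info("best restart %d/%d: objective %.6g, %d iterations",
                best.best_restart_index, cfg.n_restarts,
                best.objective_trace[-1], best.T)
    return best
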