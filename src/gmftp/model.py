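"""Core data types and probability model.

The model couples two observed binary data sets over the same ``N`` proteins:

* a symmetric protein–protein interaction (PPI) adjacency matrix
  ``A ∈ {0,1}^{N×N}``, and
* a protein–function annotation profile ``F ∈ {0,1}^{N×C}`` over ``C``
  functional terms, with a per-protein indicator ``S_i`` marking whether
  protein *i* has an observed annotation profile at all.

Both are explained by ``K`` latent complexes through two nonnegative factor
matrices: the protein–complex affinity matrix ``Θ`` (N×K) and the
complex–function preference matrix ``Ψ`` (K×C).  An edge between proteins
*i* and *j* occurs with probability ``σ(Σ_k θ_ik θ_jk)`` and an annotation
``F_ic`` with probability ``σ(Σ_k θ_ik ψ_kc)``, where ``σ(x) = 1 − exp(−x)``
maps a nonnegative "total affinity" to a valid Bernoulli probability.
Independent Exponential(λ) priors on every entry of Θ and Ψ promote sparsity,
so that fitting with a generous ``K`` lets superfluous complexes vanish.

This module holds the in-memory containers, the link function, the
elementwise probabilities, and the penalized negative log-likelihood that
the inference module minimizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS",
    "PPINetwork",
    "FunctionalProfile",
    "ModelParams",
    "FitResult",
    "sigma",
    "association_prob",
    "interaction_prob",
    "objective",
]

#: Numerical floor for 1 − exp(−x) wherever it appears inside a logarithm or
#: an update-rule denominator.  Implementation constant, not a model parameter.
EPS = 1e-10


@dataclass
class PPINetwork:
    """An unweighted, undirected, simple PPI network.

    Parameters
    ----------
    protein_ids
        Ordered list of the ``N`` unique protein identifiers.  Row/column
        ``i`` of ``A`` refers to ``protein_ids[i]``.
    A
        Dense ``N×N`` binary adjacency matrix; symmetric with zero diagonal.
    """

    protein_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        n = len(self.protein_ids)
        if len(set(self.protein_ids)) != n:
            raise ValueError("protein_ids contains duplicates")
        if self.A.shape != (n, n):
            raise ValueError(f"A has shape {self.A.shape}, expected ({n}, {n})")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary")
        if (self.A != self.A.T).any():
            raise ValueError("A must be symmetric")
        if np.diagonal(self.A).any():
            raise ValueError("A must have a zero diagonal (no self-loops)")
        self.A = self.A.astype(np.int8, copy=False)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_edges(self) -> int:
        """E, the number of undirected interactions."""
        return int(self.A.sum()) // 2

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (i, j) of the edges with i < j."""
        return np.nonzero(np.triu(self.A))


@dataclass
class FunctionalProfile:
    """Binary protein–function annotation profile.

    ``S_i = 0`` marks a protein whose annotation profile is unobserved; such
    rows of ``F`` are all-zero and contribute nothing to the likelihood, so
    unannotated proteins are clustered from topology alone.
    """

    term_ids: list[str]
    F: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F)
        self.S = np.asarray(self.S)
        c = len(self.term_ids)
        if len(set(self.term_ids)) != c:
            raise ValueError("term_ids contains duplicates")
        if self.F.ndim != 2 or self.F.shape[1] != c:
            raise ValueError(f"F has shape {self.F.shape}, expected (N, {c})")
        if self.S.shape != (self.F.shape[0],):
            raise ValueError("S must be a length-N vector")
        if not np.isin(self.F, (0, 1)).all():
            raise ValueError("F must be binary")
        if not np.isin(self.S, (0, 1)).all():
            raise ValueError("S must be binary")
        if self.F[self.S == 0].any():
            raise ValueError("rows of F with S_i = 0 must be all-zero")
        self.F = self.F.astype(np.int8, copy=False)
        self.S = self.S.astype(np.int8, copy=False)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    @property
    def n_associations(self) -> int:
        """R, the number of protein–function associations."""
        return int(self.F.sum())

    @classmethod
    def empty(cls, n_proteins: int) -> "FunctionalProfile":
        """The "PPI only" profile: S_i = 0 for all proteins, F a zero matrix."""
        return cls(term_ids=[], F=np.zeros((n_proteins, 0), dtype=np.int8),
                   S=np.zeros(n_proteins, dtype=np.int8))


@dataclass
class ModelParams:
    """Nonnegative factor matrices Θ (N×K), Ψ (K×C) and the prior rate λ."""

    Theta: np.ndarray
    Psi: np.ndarray
    lam: float = 4.0

    def __post_init__(self) -> None:
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        if self.Theta.ndim != 2 or self.Psi.ndim != 2:
            raise ValueError("Theta and Psi must be 2-D")
        if self.Theta.shape[1] != self.Psi.shape[0]:
            raise ValueError(
                f"Theta has K={self.Theta.shape[1]} but Psi has K={self.Psi.shape[0]}")
        if (self.Theta < 0).any() or (self.Psi < 0).any():
            raise ValueError("Theta and Psi must be nonnegative")
        if not np.isfinite(self.Theta).all() or not np.isfinite(self.Psi).all():
            raise ValueError("Theta and Psi must be finite")
        # lam = 0 is tolerated here (the prior terms simply vanish from the
        # objective); fitting itself requires a strictly positive rate.
        if not (self.lam >= 0 and math.isfinite(self.lam)):
            raise ValueError("lam must be a nonnegative finite real")

    @property
    def n_proteins(self) -> int:
        return self.Theta.shape[0]

    @property
    def n_complexes(self) -> int:
        return self.Theta.shape[1]

    @property
    def n_terms(self) -> int:
        return self.Psi.shape[1]


@dataclass
class FitResult:
    """Outcome of one penalized maximum-likelihood fit (best restart)."""

    params_hat: ModelParams
    objective_trace: list[float] = field(default_factory=list)
    T: int = 0
    n_restarts: int = 1
    best_restart_index: int = 0
    seed: int = 0


def sigma(x):
    """Link function σ(x) = 1 − exp(−x), mapping [0, ∞) onto [0, 1).

    Accepts a scalar or array of nonnegative finite values; monotone
    increasing with σ(0) = 0.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("sigma: argument must be finite")
    if (x < 0).any():
        raise ValueError("sigma: argument must be nonnegative")
    out = -np.expm1(-x)
    return float(out) if out.ndim == 0 else out


def association_prob(params: ModelParams, i: int, c: int) -> float:
    """P(F_ic = 1) = σ(Σ_k θ_ik ψ_kc)."""
    if not (0 <= i < params.n_proteins):
        raise IndexError(f"protein index {i} out of range")
    if not (0 <= c < params.n_terms):
        raise IndexError(f"term index {c} out of range")
    return float(sigma(params.Theta[i] @ params.Psi[:, c]))


def interaction_prob(params: ModelParams, i: int, j: int) -> float:
    """P(A_ij = 1) = σ(Σ_k θ_ik θ_jk), defined for i ≠ j only."""
    n = params.n_proteins
    if not (0 <= i < n) or not (0 <= j < n):
        raise IndexError(f"protein index out of range: ({i}, {j})")
    if i == j:
        raise ValueError("self-interactions are not modeled (i must differ from j)")
    return float(sigma(params.Theta[i] @ params.Theta[j]))


def _check_dims(params: ModelParams, net: PPINetwork, prof: FunctionalProfile) -> None:
    if params.n_proteins != net.n_proteins:
        raise ValueError(
            f"params has N={params.n_proteins} but network has N={net.n_proteins}")
    if prof.F.shape[0] != net.n_proteins:
        raise ValueError(
            f"profile has N={prof.F.shape[0]} but network has N={net.n_proteins}")
    if params.n_terms != prof.n_terms:
        raise ValueError(
            f"params has C={params.n_terms} but profile has C={prof.n_terms}")


def objective(params: ModelParams, net: PPINetwork, prof: FunctionalProfile) -> float:
    """Penalized negative log-likelihood of (A, F) under (Θ, Ψ, λ).

    Six terms: the Bernoulli log-likelihood of the observed annotations
    (masked by S_i), of the absent annotations, of the observed edges, of the
    absent edges (pair sums over i ≠ j only), and the Exponential(λ) priors
    on Θ and Ψ.  Additive constants are dropped.

    Returns ``+inf`` when an observed edge or annotation has a zero linear
    predictor (its log-probability is −∞); such parameter settings are never
    selected by the fitter.
    """
    _check_dims(params, net, prof)
    Theta, Psi, lam = params.Theta, params.Psi, params.lam

    ei, ej = net.edges()
    x_e = np.einsum("ek,ek->e", Theta[ei], Theta[ej])
    fi, fc = np.nonzero(prof.F * prof.S[:, None])
    x_f = np.einsum("ek,ke->e", Theta[fi], Psi[:, fc])
    if (x_e <= 0).any() or (x_f <= 0).any():
        return math.inf

    # positive observations: -Σ log σ(x) at edges and observed annotations
    obj = -np.log(np.maximum(-np.expm1(-x_e), EPS)).sum()
    obj -= np.log(np.maximum(-np.expm1(-x_f), EPS)).sum()

    # absent edges: (1/2) Σ_{i≠j} (1 − A_ij) x_ij = Σ_{i<j} x_ij − Σ_edges x_e
    col = Theta.sum(axis=0)
    all_pairs = 0.5 * (col @ col - (Theta * Theta).sum())
    obj += all_pairs - x_e.sum()

    # absent annotations: Σ_i S_i Σ_c (1 − F_ic) x_ic
    obj += (prof.S @ Theta) @ Psi.sum(axis=1) - x_f.sum()

    # Exponential priors
    obj += lam * (Theta.sum() + Psi.sum())
    return float(obj)
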