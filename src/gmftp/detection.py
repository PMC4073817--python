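"""Turn an estimated affinity matrix into overlapping protein complexes.

Pipeline: row-normalize the estimated Θ̂ so each protein's affinities become
membership fractions, binarize by a threshold τ, split each candidate
complex into the connected components it induces in the PPI network, and
discard components below a minimum size.  Because rows sum to one, a protein
can pass the threshold in at most ⌊1/τ⌋ complexes (5 at the default
τ = 0.2), which caps the overlap per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import FitResult, PPINetwork

__all__ = [
    "ComplexSet",
    "DetectConfig",
    "normalize_affinity",
    "threshold_membership",
    "split_components",
    "detect_complexes",
]


@dataclass
class ComplexSet:
    """An ordered collection of (possibly overlapping) protein-index sets."""

    complexes: list[frozenset[int]]
    n_proteins: int
    #: diagnostics: proteins whose normalized affinity row was all-zero
    unassigned: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        for c in self.complexes:
            if c and (min(c) < 0 or max(c) >= self.n_proteins):
                raise ValueError("complex member index out of range")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @property
    def membership(self) -> np.ndarray:
        """Binary N×K′ indicator matrix (K′ = number of complexes)."""
        m = np.zeros((self.n_proteins, len(self.complexes)), dtype=np.int8)
        for k, c in enumerate(self.complexes):
            m[list(c), k] = 1
        return m

    @property
    def coverage(self) -> int:
        """Number of proteins belonging to at least one complex."""
        return len(set().union(*self.complexes)) if self.complexes else 0


@dataclass
class DetectConfig:
    """Thresholds of the detection pipeline.

    tau
        Membership threshold on the normalized affinity row; default 0.2
        (so no protein joins more than 5 complexes).
    min_size
        Smallest complex reported; default 3.
    zero_floor
        Affinity rows whose entries are all below this are treated as
        all-zero before normalizing; default 1e-16.
    """

    tau: float = 0.2
    min_size: int = 3
    zero_floor: float = 1e-16

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        if self.min_size < 1:
            raise ValueError("min_size must be a positive integer")
        if self.zero_floor <= 0:
            raise ValueError("zero_floor must be positive")


def normalize_affinity(theta_hat: np.ndarray, zero_floor: float = 1e-16) -> np.ndarray:
    """Row-normalize Θ̂ so each row sums to 1 (or to 0 if numerically dead).

    Rows whose entries are all below ``zero_floor`` become all-zero: the
    protein is assigned to no complex.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    if (theta_hat < 0).any():
        raise ValueError("affinity matrix must be nonnegative")
    out = np.where(theta_hat < zero_floor, 0.0, theta_hat)
    sums = out.sum(axis=1, keepdims=True)
    live = sums[:, 0] > 0
    out[live] /= sums[live]
    return out


def threshold_membership(theta_norm: np.ndarray, tau: float = 0.2) -> np.ndarray:
    """Binarize a row-normalized affinity matrix: θ*_ik = 1 iff θ̂_ik ≥ τ."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    return (np.asarray(theta_norm, dtype=float) >= tau).astype(np.int8)


def split_components(members: set[int], net: PPINetwork) -> list[set[int]]:
    """Split a candidate complex into the connected components it induces.

    A candidate assembled from a locally optimal Θ̂ column may consist of
    several mutually disconnected subnetworks; each connected subnetwork is
    regarded as a complex of its own.
    """
    members = set(members)
    if not members:
        return []
    if members - set(range(net.n_proteins)):
        raise ValueError("members contains indices outside the network")
    g = nx.from_numpy_array(net.A)
    return [set(c) for c in nx.connected_components(g.subgraph(members))]


def detect_complexes(fit: FitResult, net: PPINetwork,
                     cfg: DetectConfig | None = None) -> ComplexSet:
    """Full detection pipeline from a fitted model.

    Normalize Θ̂ → threshold at τ → split every column's member set into
    connected components → drop components smaller than ``min_size`` →
    de-duplicate identical protein sets (first occurrence kept).  Output
    order is by source column, then component discovery order.
    """
    cfg = cfg or DetectConfig()
    theta_hat = fit.params_hat.Theta
    if theta_hat.shape[0] != net.n_proteins:
        raise ValueError("fit dimensions do not match the network")

    theta_norm = normalize_affinity(theta_hat, cfg.zero_floor)
    member = threshold_membership(theta_norm, cfg.tau)
    unassigned = [int(i) for i in np.nonzero(theta_norm.sum(axis=1) == 0)[0]]

    g = nx.from_numpy_array(net.A)
    seen: set[frozenset[int]] = set()
    complexes: list[frozenset[int]] = []
    for k in range(member.shape[1]):
        col = np.nonzero(member[:, k])[0]
        if col.size == 0:
            continue
        for comp in nx.connected_components(g.subgraph(col.tolist())):
            if len(comp) < cfg.min_size:
                continue
            c = frozenset(int(i) for i in comp)
            if c not in seen:
                seen.add(c)
                complexes.append(c)
    return ComplexSet(complexes=complexes, n_proteins=net.n_proteins,
                      unassigned=unassigned)
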