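"""Scoring predicted complexes against a gold standard, plus GO enrichment.

Four complementary quality criteria are provided:

* **FRAC** — fraction of reference complexes matched by at least one
  prediction with overlap score ω above a threshold (default 0.25);
* **MMR** — total weight of a maximum-weight bipartite matching between
  references and predictions (weights ω), divided by the number of
  references, so each complex on either side is used at most once;
* **ACC** — geometric mean of clustering-wise sensitivity Sn and positive
  predictive value PPV from the reference×prediction overlap table;
* **PR** — geometric mean of match precision and FRAC-style recall.  The
  exact composite from the literature is not recoverable from public
  sources; this geometric-mean form is a documented stand-in.

The overlap score between sets a, b is ω(a, b) = |a∩b|² / (|a|·|b|).

Functional homogeneity is assessed per complex by the minimum, over all
terms, of the hypergeometric upper tail P(X ≥ k) and binned into four
P-value intervals.  Raw (uncorrected) P-values are binned by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .detection import ComplexSet
from .model import FunctionalProfile

__all__ = [
    "EvaluationReport",
    "EnrichmentTable",
    "overlap_score",
    "frac",
    "mmr",
    "acc",
    "pr_score",
    "evaluate",
    "enrichment",
]

#: Bin edges for the per-complex minimum enrichment P-value.
ENRICHMENT_BINS = (1e-15, 1e-10, 1e-5)
ENRICHMENT_BIN_LABELS = ("<1e-15", "[1e-15,1e-10)", "[1e-10,1e-5)", "[1e-5,1]")


@dataclass
class EvaluationReport:
    frac: float
    mmr: float
    acc: float
    pr: float
    n_predicted: int
    coverage: int


@dataclass
class EnrichmentTable:
    """Per-complex minimum hypergeometric P-values and their bin counts."""

    p_values: list[float]  # NaN for complexes with no annotated member
    bin_counts: tuple[int, int, int, int]
    n_unscored: int  # complexes with no annotated member, excluded from bins


def overlap_score(a: set[int] | frozenset[int], b: set[int] | frozenset[int]) -> float:
    """ω(a, b) = |a∩b|² / (|a|·|b|); 1 iff a = b, 0 iff disjoint."""
    if not a or not b:
        raise ValueError("overlap_score requires nonempty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def _omega_matrix(ref: ComplexSet, pred: ComplexSet) -> np.ndarray:
    w = np.zeros((len(ref), len(pred)))
    for r, rc in enumerate(ref):
        for p, pc in enumerate(pred):
            w[r, p] = overlap_score(rc, pc)
    return w


def frac(pred: ComplexSet, ref: ComplexSet, match_thresh: float = 0.25) -> float:
    """Fraction of reference complexes matched by some prediction (ω > thresh)."""
    if len(ref) == 0:
        raise ValueError("reference complex set is empty")
    if len(pred) == 0:
        return 0.0
    w = _omega_matrix(ref, pred)
    return float((w.max(axis=1) > match_thresh).mean())


def mmr(pred: ComplexSet, ref: ComplexSet) -> float:
    """Maximum matching ratio: max-weight one-to-one matching weight / |ref|."""
    if len(ref) == 0:
        raise ValueError("reference complex set is empty")
    if len(pred) == 0:
        return 0.0
    w = _omega_matrix(ref, pred)
    ri, pi = linear_sum_assignment(w, maximize=True)
    return float(w[ri, pi].sum() / len(ref))


def acc(pred: ComplexSet, ref: ComplexSet) -> float:
    """Geometric mean of clustering-wise sensitivity and PPV.

    With T_rj = |ref_r ∩ pred_j|:
    Sn = Σ_r max_j T_rj / Σ_r |ref_r|,
    PPV = Σ_j max_r T_rj / Σ_j Σ_r T_rj.
    Returns 0 for an empty prediction set.
    """
    if len(ref) == 0:
        raise ValueError("reference complex set is empty")
    if len(pred) == 0:
        return 0.0
    t = np.array([[len(rc & pc) for pc in pred] for rc in ref], dtype=float)
    sn = t.max(axis=1).sum() / sum(len(rc) for rc in ref)
    total = t.sum()
    ppv = t.max(axis=0).sum() / total if total > 0 else 0.0
    return float(np.sqrt(sn * ppv))


def pr_score(pred: ComplexSet, ref: ComplexSet, match_thresh: float = 0.25) -> float:
    """Geometric mean of match precision and recall (FRAC).

    precision = fraction of predictions matching some reference (ω > thresh);
    recall = FRAC.  Composite stand-in for the literature's PR score.
    """
    if len(ref) == 0:
        raise ValueError("reference complex set is empty")
    if len(pred) == 0:
        return 0.0
    w = _omega_matrix(ref, pred)
    precision = float((w.max(axis=0) > match_thresh).mean())
    recall = float((w.max(axis=1) > match_thresh).mean())
    return float(np.sqrt(precision * recall))


def evaluate(pred: ComplexSet, ref: ComplexSet,
             match_thresh: float = 0.25) -> EvaluationReport:
    """All four criteria plus prediction count and protein coverage."""
    return EvaluationReport(
        frac=frac(pred, ref, match_thresh),
        mmr=mmr(pred, ref),
        acc=acc(pred, ref),
        pr=pr_score(pred, ref, match_thresh),
        n_predicted=len(pred),
        coverage=pred.coverage,
    )


def enrichment(pred: ComplexSet, prof: FunctionalProfile,
               bonferroni: bool = False) -> EnrichmentTable:
    """Functional homogeneity of each predicted complex.

    For every complex and term, the hypergeometric upper-tail probability
    P(X ≥ k) of observing k annotated members carrying the term, drawing the
    complex's annotated members from the population of annotated proteins in
    the network.  Per complex the minimum over terms is kept and binned into
    (<1e-15), [1e-15, 1e-10), [1e-10, 1e-5), [1e-5, 1].

    Complexes with no annotated member are excluded from the bins and counted
    in ``n_unscored``.  With ``bonferroni=True`` each P-value is multiplied by
    the number of terms (capped at 1) before binning.
    """
    annotated = np.nonzero(prof.S)[0]
    if annotated.size == 0:
        raise ValueError("profile contains no annotated protein")
    pop = set(int(i) for i in annotated)
    m_pop = len(pop)
    term_totals = prof.F[annotated].sum(axis=0)  # annotated proteins per term

    p_values: list[float] = []
    n_unscored = 0
    counts = [0, 0, 0, 0]
    for c in pred:
        members = [i for i in c if i in pop]
        if not members:
            p_values.append(float("nan"))
            n_unscored += 1
            continue
        n_draw = len(members)
        k_obs = prof.F[members].sum(axis=0)
        p = 1.0
        if prof.n_terms:
            tails = hypergeom.sf(k_obs - 1, m_pop, term_totals, n_draw)
            p = float(tails.min())
        if bonferroni:
            p = min(1.0, p * max(prof.n_terms, 1))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        p_values.append(p)
        if p < ENRICHMENT_BINS[0]:
            counts[0] += 1
        elif p < ENRICHMENT_BINS[1]:
            counts[1] += 1
        elif p < ENRICHMENT_BINS[2]:
            counts[2] += 1
        else:
            counts[3] += 1
    return EnrichmentTable(p_values=p_values,
                           bin_counts=(counts[0], counts[1], counts[2], counts[3]),
                           n_unscored=n_unscored)
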