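import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmftp import (
    ComplexSet,
    FunctionalProfile,
    acc,
    enrichment,
    evaluate,
    frac,
    mmr,
    overlap_score,
    pr_score,
)


def cs(*sets, n=30):
    return ComplexSet(complexes=[frozenset(s) for s in sets], n_proteins=n)


def brute_force_mmr(pred, ref):
    """Exhaustive maximum-weight matching over all injections ref→pred."""
    w = [[overlap_score(r, p) for p in pred] for r in ref]
    nr, npred = len(ref), len(pred)
    best = 0.0
    for k in range(min(nr, npred) + 1):
        for rows in itertools.combinations(range(nr), k):
            for cols in itertools.permutations(range(npred), k):
                best = max(best, sum(w[r][c] for r, c in zip(rows, cols)))
    return best / nr


class TestOverlapScore:
    def test_identical_and_disjoint(self):
        assert overlap_score({1, 2}, {1, 2}) == 1.0
        assert overlap_score({1, 2}, {3, 4}) == 0.0

    def test_partial_overlap(self):
        assert overlap_score({1, 2}, {1, 2, 3, 4}) == pytest.approx(0.5)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            overlap_score(set(), {1})


class TestFrac:
    def test_perfect_and_empty(self):
        ref = cs({0, 1, 2}, {3, 4, 5})
        assert frac(ref, ref) == 1.0
        assert frac(cs(), ref) == 0.0

    def test_half_matched(self):
        ref = cs({0, 1, 2, 3}, {10, 11, 12, 13})
        pred = cs({0, 1, 2, 7})  # ω = 9/16 > 0.25 with ref 0 only
        assert frac(pred, ref) == 0.5

    def test_match_is_strict_inequality(self):
        ref = cs({0, 1, 2, 3})
        pred = cs({0, 1, 8, 9})  # ω = 4/16 = 0.25 exactly: not a match
        assert frac(pred, ref) == 0.0

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            frac(cs({0, 1}), cs())


class TestMmr:
    def test_perfect_and_disjoint(self):
        ref = cs({0, 1, 2}, {3, 4, 5})
        assert mmr(ref, ref) == 1.0
        assert mmr(cs({20, 21, 22}), ref) == 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=200)
    def test_matches_exhaustive_oracle(self, seed):
        """Assignment-solver MMR equals brute-force enumeration (≤ 6×6)."""
        rng = np.random.default_rng(seed)
        universe = 14
        ref = [frozenset(rng.choice(universe, size=rng.integers(2, 5),
                                    replace=False).tolist())
               for _ in range(rng.integers(1, 7))]
        pred = [frozenset(rng.choice(universe, size=rng.integers(2, 5),
                                     replace=False).tolist())
                for _ in range(rng.integers(1, 7))]
        r = ComplexSet(complexes=ref, n_proteins=universe)
        p = ComplexSet(complexes=pred, n_proteins=universe)
        assert mmr(p, r) == pytest.approx(brute_force_mmr(pred, ref), abs=1e-12)

    def test_order_invariance(self):
        ref = cs({0, 1, 2}, {3, 4, 5}, {6, 7, 8})
        pred = cs({0, 1, 9}, {3, 4, 5})
        shuffled = cs({3, 4, 5}, {0, 1, 9})
        assert mmr(pred, ref) == mmr(shuffled, ref)
        assert frac(pred, ref) == frac(shuffled, ref)
        assert acc(pred, ref) == acc(shuffled, ref)
        assert pr_score(pred, ref) == pr_score(shuffled, ref)


class TestAcc:
    def test_perfect_on_disjoint_reference(self):
        ref = cs({0, 1, 2}, {3, 4})
        assert acc(ref, ref) == 1.0

    def test_hand_computed_contingency(self):
        # refs {a,b,c}, {d,e}; pred {a,b,d}: Sn = 3/5, PPV = 2/3, ACC = √0.4
        ref = cs({0, 1, 2}, {3, 4})
        pred = cs({0, 1, 3})
        assert acc(pred, ref) == pytest.approx(math.sqrt(0.4))

    def test_empty_prediction_scores_zero(self):
        assert acc(cs(), cs({0, 1, 2})) == 0.0


class TestPrScore:
    def test_perfect(self):
        ref = cs({0, 1, 2}, {3, 4, 5})
        assert pr_score(ref, ref) == 1.0

    def test_half_spurious_predictions(self):
        ref = cs({0, 1, 2}, {3, 4, 5})
        pred = cs({0, 1, 2}, {3, 4, 5}, {10, 11, 12}, {13, 14, 15})
        assert pr_score(pred, ref) == pytest.approx(math.sqrt(0.5))

    def test_empty_prediction(self):
        assert pr_score(cs(), cs({0, 1, 2})) == 0.0


class TestEvaluateReport:
    def test_report_fields(self):
        ref = cs({0, 1, 2}, {3, 4, 5})
        rep = evaluate(ref, ref)
        assert (rep.frac, rep.mmr, rep.acc, rep.pr) == (1.0, 1.0, 1.0, 1.0)
        assert rep.n_predicted == 2
        assert rep.coverage == 6


def exact_hypergeom_tail(k, m_pop, n_term, n_draw):
    """Exact P(X ≥ k) as a ratio of binomial-coefficient sums."""
    total = math.comb(m_pop, n_draw)
    hits = sum(math.comb(n_term, x) * math.comb(m_pop - n_term, n_draw - x)
               for x in range(k, min(n_term, n_draw) + 1))
    return hits / total


class TestEnrichment:
    @staticmethod
    def profile(n, term_members):
        f = np.zeros((n, len(term_members)), dtype=np.int8)
        for c, members in enumerate(term_members):
            f[list(members), c] = 1
        return FunctionalProfile([f"t{c}" for c in range(len(term_members))],
                                 F=f, S=np.ones(n, dtype=np.int8))

    def test_private_term_matches_exact_tail(self):
        """Complex whose members all carry a term absent elsewhere: the
        minimum P-value equals the exact hypergeometric tail sum."""
        n = 20
        prof = self.profile(n, [{0, 1, 2, 3}])
        table = enrichment(cs({0, 1, 2, 3}, n=n), prof)
        assert table.p_values[0] == pytest.approx(
            exact_hypergeom_tail(4, n, 4, 4), rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_enumeration_oracle(self, seed):
        """scipy tail equals both the comb-ratio closed form and a literal
        enumeration over all draws, for populations ≤ 25."""
        rng = np.random.default_rng(seed)
        m_pop = int(rng.integers(8, 26))
        n_draw = int(rng.integers(3, 7))
        term = set(rng.choice(m_pop, size=rng.integers(2, m_pop // 2 + 1),
                              replace=False).tolist())
        complex_members = set(rng.choice(m_pop, size=n_draw, replace=False).tolist())
        k = len(complex_members & term)
        prof = self.profile(m_pop, [term])
        table = enrichment(cs(complex_members, n=m_pop), prof)
        expected = exact_hypergeom_tail(k, m_pop, len(term), n_draw)
        assert table.p_values[0] == pytest.approx(expected, rel=1e-10)
        # literal enumeration of every possible draw of size n_draw
        hits = sum(1 for draw in itertools.combinations(range(m_pop), n_draw)
                   if len(set(draw) & term) >= k)
        assert expected == pytest.approx(hits / math.comb(m_pop, n_draw), rel=1e-12)

    def test_universal_term_gives_p_one(self):
        n = 10
        prof = self.profile(n, [set(range(n))])
        table = enrichment(cs({0, 1, 2}, n=n), prof)
        assert table.p_values[0] == 1.0
        assert table.bin_counts[3] == 1

    def test_unannotated_complex_excluded_from_bins(self):
        f = np.zeros((10, 1), dtype=np.int8)
        s = np.zeros(10, dtype=np.int8)
        s[:5] = 1
        f[0, 0] = 1
        prof = FunctionalProfile(["t0"], F=f, S=s)
        table = enrichment(cs({7, 8, 9}, n=10), prof)
        assert table.n_unscored == 1
        assert sum(table.bin_counts) == 0
        assert math.isnan(table.p_values[0])

    def test_bins_partition_scored_complexes(self):
        n = 25
        prof = self.profile(n, [set(range(12)), {20, 21, 22, 23, 24}])
        table = enrichment(cs({0, 1, 2, 3}, {20, 21, 22}, {5, 13, 17}, n=n), prof)
        assert sum(table.bin_counts) + table.n_unscored == 3
        for p in table.p_values:
            assert math.isnan(p) or 0 < p <= 1

    def test_requires_annotated_population(self):
        prof = FunctionalProfile.empty(5)
        with pytest.raises(ValueError):
            enrichment(cs({0, 1, 2}, n=5), prof)
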