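import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import regimenet as rn
from regimenet.associations import AssociationError, RankedList, _log10_tail_vec


def exact_log10_tail(n_a: int, n_b: int, n_ab: int, n: int) -> float:
    """Independent oracle: exact rational binomial upper tail in log10.

    Full summation for small n. For large n (deep-tail checks) the terms
    above the mean decay geometrically, so the recursion stops once the
    remaining terms cannot move log10 p at the 1e-12 level; the
    truncation bound is checked explicitly.
    """
    if n_ab == 0:
        return 0.0
    p0 = Fraction(n_a * n_b, n * n)
    if p0 >= 1:
        return 0.0
    q0 = 1 - p0
    if n <= 100:
        tail = sum(
            Fraction(math.comb(n, k)) * p0**k * q0 ** (n - k)
            for k in range(n_ab, n + 1)
        )
    else:
        assert Fraction(n_ab) > n * p0, "truncated oracle needs k above the mean"
        term = Fraction(math.comb(n, n_ab)) * p0**n_ab * q0 ** (n - n_ab)
        tail = term
        for k in range(n_ab, n):
            term = term * (n - k) * p0 / ((k + 1) * q0)
            tail += term
            ratio = Fraction(n - k - 1) * p0 / (Fraction(k + 2) * q0)
            if ratio < 1 and term * ratio / (1 - ratio) < tail * Fraction(1, 10**15):
                break
    return math.log10(tail.numerator) - math.log10(tail.denominator)


class TestCooccurrenceTail:
    def test_worked_example(self):
        # n_a=n_b=n_ab=5 of n=10: p0=1/4, tail = sum_{k>=5} C(10,k)/4^k(3/4)^(10-k)
        lp = rn.cooccurrence_log10_p(5, 5, 5, 10)
        assert lp == pytest.approx(math.log10(0.07812690734863281), abs=1e-9)
        assert lp == pytest.approx(-1.107, abs=1e-3)

    def test_zero_overlap_gives_p_one(self):
        assert rn.cooccurrence_log10_p(5, 5, 0, 10) == 0.0

    @pytest.mark.parametrize("n", [1, 7, 100])
    def test_saturated_marginals_give_p_one(self, n):
        assert rn.cooccurrence_log10_p(n, n, n, n) == 0.0

    def test_inconsistent_counts_error(self):
        with pytest.raises(AssociationError):
            rn.cooccurrence_log10_p(3, 2, 3, 10)
        with pytest.raises(AssociationError):
            rn.cooccurrence_log10_p(0, 5, 1, 10)

    @pytest.mark.parametrize("n", [5, 12, 25])
    def test_matches_exact_rational_oracle(self, n):
        for n_a in range(1, n + 1):
            for n_b in range(n_a, n + 1):
                for n_ab in range(0, n_a + 1):
                    got = rn.cooccurrence_log10_p(n_a, n_b, n_ab, n)
                    want = exact_log10_tail(n_a, n_b, n_ab, n)
                    assert got == pytest.approx(want, abs=1e-9), (n_a, n_b, n_ab, n)

    def test_deep_tail_against_oracle(self):
        # p ~ 1e-125: far beyond double-precision linear space
        got = rn.cooccurrence_log10_p(200, 200, 200, 2000)
        want = exact_log10_tail(200, 200, 200, 2000)
        assert got == pytest.approx(want, abs=1e-8)
        assert got < -100

    def test_moderate_p_matches_scipy_sf(self):
        from scipy import stats

        lp = rn.cooccurrence_log10_p(50, 60, 10, 200)
        sf = stats.binom.sf(9, 200, 50 * 60 / 200**2)
        assert lp == pytest.approx(math.log10(sf), rel=1e-8)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_monotone_in_overlap(self, data):
        n = data.draw(st.integers(2, 60))
        n_a = data.draw(st.integers(1, n))
        n_b = data.draw(st.integers(1, n))
        hi = min(n_a, n_b)
        k = data.draw(st.integers(0, hi - 1)) if hi > 0 else 0
        assert rn.cooccurrence_log10_p(n_a, n_b, k + 1, n) <= rn.cooccurrence_log10_p(
            n_a, n_b, k, n
        )

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_symmetric_in_events(self, data):
        n = data.draw(st.integers(2, 50))
        n_a = data.draw(st.integers(1, n))
        n_b = data.draw(st.integers(1, n))
        n_ab = data.draw(st.integers(0, min(n_a, n_b)))
        assert rn.cooccurrence_log10_p(n_a, n_b, n_ab, n) == rn.cooccurrence_log10_p(
            n_b, n_a, n_ab, n
        )

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(0)
        n = 500
        n_a = rng.integers(1, n, 200)
        n_b = rng.integers(1, n, 200)
        n_ab = np.minimum(n_a, n_b)  # maximal overlap: exercises deep tails
        vec = _log10_tail_vec(n_a, n_b, n_ab, n)
        for i in range(0, 200, 17):
            assert vec[i] == pytest.approx(
                rn.cooccurrence_log10_p(int(n_a[i]), int(n_b[i]), int(n_ab[i]), n),
                rel=1e-8, abs=1e-8,
            )


class TestConditionalProbability:
    @pytest.mark.parametrize("n_ab,n_b,want", [(3, 4, 0.75), (0, 4, 0.0), (4, 4, 1.0)])
    def test_values(self, n_ab, n_b, want):
        assert rn.conditional_probability(n_ab, n_b) == want

    def test_empty_conditioning_errors(self):
        with pytest.raises(AssociationError, match="empty support"):
            rn.conditional_probability(0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_bayes_identity(self, data):
        # p(a|b) * n_b = p(b|a) * n_a = n_ab, exactly
        n_a = data.draw(st.integers(1, 50))
        n_b = data.draw(st.integers(1, 50))
        n_ab = data.draw(st.integers(0, min(n_a, n_b)))
        assert rn.conditional_probability(n_ab, n_b) * n_b == pytest.approx(n_ab)
        assert rn.conditional_probability(n_ab, n_a) * n_a == pytest.approx(n_ab)


class TestMutualInformation:
    def test_identical_binary_vectors_give_entropy(self):
        v = np.array([0] * 5 + [1] * 5)
        assert rn.mutual_information(v, v) == pytest.approx(math.log(2), abs=1e-12)

    def test_exact_independence_gives_zero(self):
        a = np.repeat([0, 0, 1, 1], 4)
        b = np.tile([0, 1, 0, 1], 4)  # all four cells have count 4
        assert rn.mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_2x2_table_closed_form(self):
        # counts (3,1;1,3), N=8 -> 0.75 ln 1.5 + 0.25 ln 0.5
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        b = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        want = 0.75 * math.log(1.5) + 0.25 * math.log(0.5)
        assert rn.mutual_information(a, b) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(0.1308, abs=1e-4)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 3, 40)
            b = rng.integers(0, 2, 40)
            mi = rn.mutual_information(a, b)
            assert mi >= -1e-12
            assert mi == pytest.approx(rn.mutual_information(b, a), abs=1e-12)

    def test_pairwise_complete_only(self):
        a = np.array([0, 1, rn.MISSING_CODE, 0, 1])
        b = np.array([0, 1, 0, rn.MISSING_CODE, 1])
        trimmed = rn.mutual_information(np.array([0, 1, 1]), np.array([0, 1, 1]))
        assert rn.mutual_information(a, b) == pytest.approx(trimmed)

    def test_length_mismatch_errors(self):
        with pytest.raises(AssociationError):
            rn.mutual_information(np.zeros(3), np.zeros(4))

    def test_mi_decomposes_into_cooccurrence_terms(self):
        # MI = sum over regime combinations of (n_ab/n) ln(n_ab n / n_a n_b)
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        n = 100
        total = 0.0
        for i in (0, 1):
            for j in (0, 1):
                n_a = int((a == i).sum())
                n_b = int((b == j).sum())
                n_ab = int(((a == i) & (b == j)).sum())
                if n_ab:
                    total += (n_ab / n) * math.log(n_ab * n / (n_a * n_b))
        assert rn.mutual_information(a, b) == pytest.approx(total, abs=1e-12)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert rn.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert rn.pearson(x, -x) == pytest.approx(-1.0)

    def test_orthogonal_hand_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        assert rn.pearson(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        assert math.isnan(rn.pearson(np.ones(5), np.arange(5.0)))


class TestBonferroni:
    def test_cohort_scale_worked_case(self):
        theta = rn.bonferroni_threshold(0.001, 14341, 2, 14341, 2)
        assert theta == 0.001 / 28682**2
        assert theta == pytest.approx(1.2156e-12, rel=1e-4)

    def test_single_test_is_alpha(self):
        assert rn.bonferroni_threshold(0.05, 1, 1, 1, 1) == 0.05

    def test_symmetric_in_datasets(self):
        assert rn.bonferroni_threshold(0.01, 10, 2, 7, 3) == rn.bonferroni_threshold(
            0.01, 7, 3, 10, 2
        )


class TestAllPairs:
    def _rm_from(self, rows: dict) -> rn.RegimeMatrix:
        codes = pd.DataFrame(
            rows, index=[f"s{i}" for i in range(len(next(iter(rows.values()))))]
        ).T
        codes.columns = [f"s{i}" for i in range(codes.shape[1])]
        return rn.RegimeMatrix.from_codes(codes)

    def test_identical_codes_rank_first(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 2, 60)
        rm = self._rm_from({"A": v, "B": v, "C": rng.integers(0, 2, 60)})
        ranked, table = rn.all_pairs_associations(rm, measure="cooccurrence")
        assert ranked.pairs[0] == ("A", "B")
        assert set(table.columns) >= {"gene_a", "regime_a", "log10_p", "mi"}

    def test_unimodal_gene_excluded(self):
        rng = np.random.default_rng(4)
        rm = self._rm_from(
            {"A": rng.integers(0, 2, 40), "B": rng.integers(0, 2, 40),
             "U": np.zeros(40, dtype=int)}
        )
        ranked, table = rn.all_pairs_associations(rm)
        genes = set(table["gene_a"]) | set(table["gene_b"])
        assert "U" not in genes

    def test_fast_binary_path_matches_generic(self):
        rng = np.random.default_rng(5)
        rows = {f"G{i}": rng.integers(0, 2, 50) for i in range(6)}
        rm = self._rm_from(rows)
        _, fast = rn.all_pairs_associations(rm, measure="cooccurrence")
        from regimenet.associations import _cooccurrence_generic

        generic = _cooccurrence_generic(list(rows), rm)
        key = ["gene_a", "regime_a", "gene_b", "regime_b"]
        f = fast.sort_values(key).reset_index(drop=True)
        g = generic.sort_values(key).reset_index(drop=True)
        for col in ("n", "n_a", "n_b", "n_ab"):
            assert (f[col].to_numpy() == g[col].to_numpy()).all()
        np.testing.assert_allclose(f["log10_p"], g["log10_p"], rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(f["mi"], g["mi"], rtol=1e-9, atol=1e-12)

    def test_mi_ranking_descends(self):
        rng = np.random.default_rng(6)
        v = rng.integers(0, 2, 80)
        noisy = v.copy()
        noisy[:10] = 1 - noisy[:10]
        rm = self._rm_from({"A": v, "B": noisy, "C": rng.integers(0, 2, 80)})
        ranked, _ = rn.all_pairs_associations(rm, measure="mi")
        assert ranked.pairs[0] == ("A", "B")
        assert ranked.scores == sorted(ranked.scores, reverse=True)


class TestAgreement:
    def _mk(self, pairs):
        return RankedList("x", pairs, list(range(len(pairs))))

    def test_identical_lists_perfect_agreement(self):
        a = self._mk([("A", "B"), ("C", "D"), ("E", "F")])
        assert rn.agreement_at_depth(a, a, [1, 2, 3]) == [1.0, 1.0, 1.0]

    def test_disjoint_lists_zero(self):
        a = self._mk([("A", "B"), ("C", "D")])
        b = self._mk([("E", "F"), ("G", "H")])
        assert rn.agreement_at_depth(a, b, [1, 2]) == [0.0, 0.0]

    def test_hand_computed_example(self):
        a = self._mk([("A", "B"), ("C", "D"), ("E", "F")])
        b = self._mk([("C", "D"), ("A", "B"), ("G", "H")])
        assert rn.agreement_at_depth(a, b, [1, 2, 3]) == [0.0, 1.0, pytest.approx(2 / 3)]

    def test_depth_beyond_list_errors(self):
        a = self._mk([("A", "B")])
        with pytest.raises(AssociationError, match="depth"):
            rn.agreement_at_depth(a, a, [2])


class TestBimodalIntersection:
    def test_requires_bimodal_in_both(self):
        codes_a = pd.DataFrame(
            {"s0": [0, 0], "s1": [1, 0], "s2": [0, 0], "s3": [1, 0]},
            index=["G1", "G2"],
        )
        codes_b = pd.DataFrame(
            {"s0": [0, 0], "s1": [1, 1], "s2": [0, 0], "s3": [1, 1]},
            index=["G1", "G2"],
        )
        a = rn.RegimeMatrix.from_codes(codes_a)
        b = rn.RegimeMatrix.from_codes(codes_b)
        assert rn.bimodal_intersection_filter(a, b) == ["G1"]
        assert rn.bimodal_intersection_filter(a, a) == ["G1"]

    def test_empty_intersection_warns(self):
        codes = pd.DataFrame({"s0": [0], "s1": [0]}, index=["G1"])
        a = rn.RegimeMatrix.from_codes(codes)
        with pytest.warns(UserWarning):
            assert rn.bimodal_intersection_filter(a, a) == []
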