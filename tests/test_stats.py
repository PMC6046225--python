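"""Statistical primitives against closed forms and enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats as sps

from senesplice.stats import (
    bh_adjust,
    bonferroni_adjust,
    combine_fisher,
    combine_stouffer,
    fisher_exact_enrichment,
    hypergeom_sf,
    two_proportion_z,
    welch_t,
)


def bh_bruteforce(pvals):
    """q_i = min_{j >= i} min(1, p_(j) * m / j), mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(p[order] * m / np.arange(1, m + 1), 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_tail_enumeration(a, b, c, d):
    """P(X >= a) by direct combinatorial enumeration over the margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = math.comb(n, c1)
    prob = 0.0
    for x in range(a, min(r1, c1) + 1):
        if c1 - x <= r2:
            prob += math.comb(r1, x) * math.comb(r2, c1 - x) / total
    return prob


class TestCombineFisher:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.5], 0.5),
            ([1.0, 1.0, 1.0], 1.0),
            # closed form for df=4: exp(-x/2) * (1 + x/2), x = -2*ln(0.05)*2
            ([0.05, 0.05], math.exp(-2 * -math.log(0.05)) * (1 - 2 * math.log(0.05))),
        ],
    )
    def test_closed_forms(self, pvals, expected):
        assert combine_fisher(pvals) == pytest.approx(expected, abs=1e-10)

    def test_two_of_005_matches_printed_value(self):
        assert combine_fisher([0.05, 0.05]) == pytest.approx(0.01748, abs=5e-6)

    def test_matches_numerical_integration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(1, 8)
            p = rng.uniform(0.01, 1.0, size=k)
            x = -2 * np.sum(np.log(p))
            oracle, err = integrate.quad(
                lambda t: sps.chi2.pdf(t, 2 * k), x, np.inf, limit=200
            )
            assert combine_fisher(p) == pytest.approx(oracle, abs=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.001, 1.0), min_size=1, max_size=6),
        st.data(),
    )
    def test_monotone_in_each_input(self, pvals, data):
        i = data.draw(st.integers(0, len(pvals) - 1))
        smaller = list(pvals)
        smaller[i] = pvals[i] * data.draw(st.floats(0.1, 0.999))
        assert combine_fisher(smaller) <= combine_fisher(pvals) + 1e-12


class TestCombineStouffer:
    def test_symmetry_at_half(self):
        assert combine_stouffer([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_single_p_identity(self):
        assert combine_stouffer([0.05], [3.0]) == pytest.approx(0.05, abs=1e-12)

    def test_two_of_005_equal_weights(self):
        # Z = 2 * Phi^-1(0.95) / sqrt(2) = 2.32624, upper tail 0.0100046
        expected = sps.norm.sf(2 * sps.norm.isf(0.05) / math.sqrt(2))
        assert combine_stouffer([0.05, 0.05]) == pytest.approx(expected, abs=1e-12)
        assert combine_stouffer([0.05, 0.05]) == pytest.approx(0.010005, abs=1e-6)

    def test_weight_scale_invariance(self):
        p = [0.03, 0.4, 0.7]
        assert combine_stouffer(p, [1, 2, 3]) == pytest.approx(
            combine_stouffer(p, [2, 4, 6]), abs=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=6), st.data())
    def test_monotone_in_each_input(self, pvals, data):
        i = data.draw(st.integers(0, len(pvals) - 1))
        smaller = list(pvals)
        smaller[i] = pvals[i] * data.draw(st.floats(0.1, 0.999))
        assert combine_stouffer(smaller) <= combine_stouffer(pvals) + 1e-12


class TestMultipleTesting:
    def test_bh_equals_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_bonferroni_caps_at_one(self):
        np.testing.assert_allclose(
            bonferroni_adjust([0.5, 0.001], 10), [1.0, 0.01]
        )


class TestFisherExact:
    def test_equals_enumeration_for_all_small_tables(self):
        for r1 in range(13):
            for r2 in range(13):
                for a in range(r1 + 1):
                    b = r1 - a
                    for c in range(r2 + 1):
                        d = r2 - c
                        _, p = fisher_exact_enrichment(a, b, c, d)
                        oracle = hypergeom_tail_enumeration(a, b, c, d)
                        assert p == pytest.approx(oracle, abs=1e-9), (a, b, c, d)

    def test_perfect_separation_example(self):
        oratio, p = fisher_exact_enrichment(10, 0, 0, 10)
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
        assert oratio == math.inf

    def test_zero_a_cell_gives_p_one(self):
        _, p = fisher_exact_enrichment(0, 10, 5, 5)
        assert p == pytest.approx(1.0)

    def test_hypergeom_sf_go_example(self):
        # universe 100, list 10, term 10, overlap >= 5
        assert hypergeom_sf(5, 100, 10, 10) == pytest.approx(6.716e-4, rel=1e-3)


class TestWelch:
    def test_hand_example(self):
        x = np.array([[1.0, 2, 3, 4, 2, 3, 4, 5]])
        mask = np.array([True] * 4 + [False] * 4)
        t, p = welch_t(x, mask)
        assert t[0] == pytest.approx(-1.0954, abs=1e-4)
        assert p[0] == pytest.approx(0.3153, abs=1e-4)

    def test_constant_rows(self):
        x = np.array([[1.0] * 6, [1, 1, 1, 2, 2, 2]])
        mask = np.array([True] * 3 + [False] * 3)
        t, p = welch_t(x, mask)
        assert t[0] == 0 and p[0] == 1.0
        assert np.isinf(t[1]) and p[1] < 1e-10

    def test_one_sided_split_at_half(self):
        x = np.array([[1.0, 2, 1, 2]])
        mask = np.array([True, True, False, False])
        _, p_down = welch_t(x, mask, "less")
        _, p_up = welch_t(x, mask, "greater")
        assert p_down[0] == pytest.approx(0.5)
        assert p_up[0] == pytest.approx(0.5)


class TestTwoProportionZ:
    def test_equal_fractions_give_one(self):
        assert two_proportion_z(10, 100, 10, 100) == 1.0

    def test_extreme_difference_is_significant(self):
        assert two_proportion_z(95, 100, 5, 100) < 1e-10

    def test_empty_group_degenerate(self):
        assert two_proportion_z(0, 0, 5, 10) == 1.0
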