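"""Arc-model generating functions against enumeration and closed forms."""

import itertools
import math
from fractions import Fraction

import pytest

from rnasparse import (ArcEnergyModel, b_constant, claim_identity_check,
                       expected_candidate_entries, g_structure_series,
                       growth_rate_arc, irreducible_series,
                       irreducibility_probability, matching_series,
                       theory_expected_candidates, TruncatedSeries)

GOLDEN = (3 + math.sqrt(5)) / 2            # growth rate at tau = 1
B_CLOSED = (7 - 3 * math.sqrt(5)) / 2      # rho^2 = lim d*_g(n)/d_g(n)


# ---------------------------------------------------------------------------
# independent genus oracle for perfect matchings (no 1-arc restriction)
# ---------------------------------------------------------------------------
def _matching_genus(pairs):
    """Cycles of (rotation o involution) on the 2*ell endpoints."""
    m = 2 * len(pairs)
    inv = {}
    for i, j in pairs:
        inv[i], inv[j] = j, i
    seen, r = set(), 0
    for s in range(m):
        if s in seen:
            continue
        r += 1
        x = s
        while x not in seen:
            seen.add(x)
            x = (inv[x] + 1) % m
    return (len(pairs) + 1 - r) // 2


def _all_perfect_matchings(points):
    if not points:
        yield ()
        return
    first, rest = points[0], points[1:]
    for k, second in enumerate(rest):
        sub = rest[:k] + rest[k + 1:]
        for tail in _all_perfect_matchings(sub):
            yield ((first, second),) + tail


def _matching_count_oracle(g, n_arcs):
    return sum(1 for m in _all_perfect_matchings(tuple(range(2 * n_arcs)))
               if _matching_genus(m) == g)


class TestMatchingSeries:
    @pytest.mark.parametrize("g, n, expected", [
        (0, 3, 5), (1, 2, 1), (1, 3, 10), (2, 4, 21),
    ])
    def test_low_order_counts(self, g, n, expected):
        assert matching_series(g, 10)[n] == expected

    def test_against_brute_force_genus_enumeration(self):
        for g in (0, 1, 2):
            for n_arcs in range(0, 6):
                assert matching_series(g, 8)[n_arcs] == \
                    _matching_count_oracle(g, n_arcs)

    def test_genus_zero_is_catalan(self):
        cat = [1, 1, 2, 5, 14, 42, 132, 429]
        assert matching_series(0, 7).coefficients() == cat


class TestStructureSeries:
    def test_genus_zero_counts(self):
        d0 = g_structure_series(0, 1, 10).series
        assert [int(d0[n]) for n in range(7)] == [1, 1, 1, 2, 4, 8, 17]

    def test_genus_one_counts(self):
        d1 = g_structure_series(1, 1, 10).series
        assert int(d1[4]) == 1 and int(d1[5]) == 5

    def test_general_tau_n4(self):
        # empty structure plus three one-arc structures of length >= 2
        tau = Fraction(3, 7)
        d = g_structure_series(0, tau, 6).series
        assert d[4] == 1 + 3 * tau

    def test_matches_enumeration_exactly(self, genus_counts):
        for g in (0, 1, 2):
            d = g_structure_series(g, 1, 12).series
            for n in range(1, 13):
                assert int(d[n]) == genus_counts.get((g, n), (0, 0))[0]

    def test_total_over_genera_is_all_structures(self, enumerated):
        series = [g_structure_series(g, 1, 12).series for g in range(4)]
        for n in range(1, 13):
            assert sum(int(s[n]) for s in series) == len(enumerated[n])

    def test_vanishing_below_4g(self):
        d2 = g_structure_series(2, 1, 12).series
        assert all(int(d2[n]) == 0 for n in range(8))


class TestIrreducibleSeries:
    def test_genus_zero_counts(self):
        ds = irreducible_series(0, 1, 10).series
        assert [int(ds[n]) for n in range(1, 6)] == [1, 0, 1, 1, 2]

    def test_empty_structure_not_irreducible(self):
        for g in (0, 1, 2):
            assert irreducible_series(g, 1, 10).series[0] == 0

    def test_genus_one_first_coefficient(self):
        assert int(irreducible_series(1, 1, 8).series[4]) == 1

    def test_matches_enumeration_exactly(self, genus_counts):
        for g in (0, 1, 2):
            ds = irreducible_series(g, 1, 12).series
            for n in range(1, 13):
                assert int(ds[n]) == genus_counts.get((g, n), (0, 0))[1]

    @pytest.mark.parametrize("tau", [Fraction(1, 2), 1, float(Fraction(6, 16)) * math.e])
    def test_dominated_by_structure_series(self, tau):
        d = g_structure_series(0, tau, 40).series
        ds = irreducible_series(0, tau, 40).series
        for n in range(41):
            assert 0 <= ds[n] <= d[n]

    def test_d1_closed_form_oracle(self):
        """d_1 equals the expansion of u^2/(1-4u)^{5/2} / (z^2-z+1) with
        u = z^2/(z^2-z+1)^2 (the genus-1 singular polynomial is u^2)."""
        N = 80
        den_inv = TruncatedSeries([1, -1, 1], N, "exact").reciprocal()
        u = TruncatedSeries.monomial(1, 2, N) * den_inv * den_inv
        # (1-4x)^{-5/2} = sum_k 4^k / k! * prod_{i<k} (5/2 + i) x^k
        coeffs, rising = [], Fraction(1)
        fact = 1
        for k in range(N + 1):
            coeffs.append(rising * Fraction(4 ** k, fact))
            rising *= Fraction(5 + 2 * k, 2)
            fact *= k + 1
        outer = TruncatedSeries([0, 0] + coeffs[:-2], N, "exact")
        oracle = den_inv * outer.compose(u)
        assert oracle == g_structure_series(1, 1, N).series


class TestClaimIdentity:
    @pytest.mark.parametrize("g", [1, 2, 3])
    def test_composition_identity_holds(self, g):
        assert claim_identity_check(g, 100)

    def test_negative_control_with_corrupted_d0(self):
        corrupted = g_structure_series(0, 1, 10).series + \
            TruncatedSeries.monomial(1, 3, 10)
        assert not claim_identity_check(1, 10, d0_override=corrupted)

    def test_genus_out_of_range(self):
        with pytest.raises(ValueError):
            claim_identity_check(4)


class TestIrreducibilityProbability:
    def test_single_vertex_certain(self):
        assert irreducibility_probability(0, 1) == 1.0

    def test_two_vertices_impossible(self):
        assert irreducibility_probability(0, 2) == 0.0

    def test_three_vertices_tau_over_one_plus_tau(self):
        assert irreducibility_probability(0, 3, 1) == pytest.approx(0.5)
        tau = Fraction(2, 5)
        p = irreducibility_probability(0, 3, tau)
        assert p == pytest.approx(float(tau / (1 + tau)))

    def test_zero_when_no_structure_exists(self):
        # intervals shorter than 4g cannot host a genus-g sub-structure
        assert irreducibility_probability(1, 3) == 0.0

    def test_weighted_enumeration_identity(self, enumerated):
        """Assumption-1 weighted irreducible fraction equals P_g(m) exactly
        (exact backend, tau rational)."""
        tau = Fraction(1, 3)
        d = g_structure_series(0, tau, 10).series
        ds = irreducible_series(0, tau, 10).series
        for m in range(1, 11):
            num = sum(tau ** s.ell for s in enumerated[m]
                      if s.genus == 0 and s.irreducible)
            den = sum(tau ** s.ell for s in enumerated[m] if s.genus == 0)
            assert Fraction(num, den) == Fraction(ds[m], d[m])


class TestGrowthRate:
    def test_tau_one_golden_ratio_square(self):
        assert growth_rate_arc(1.0) == pytest.approx(GOLDEN, rel=1e-12)
        assert round(growth_rate_arc(1.0), 3) == 2.618

    def test_default_model_tau(self):
        gamma = growth_rate_arc(ArcEnergyModel().tau)
        assert gamma == pytest.approx(2.632, abs=2e-3)

    def test_reciprocal_is_rho(self):
        tau = 0.7
        gamma = growth_rate_arc(tau)
        rho = 1.0 / gamma
        assert tau * rho ** 2 / (tau * rho ** 2 - rho + 1) ** 2 == \
            pytest.approx(0.25, rel=1e-10)

    def test_subcritical_tau_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_arc(0.2)


class TestBConstant:
    def test_b0_closed_form(self):
        est = b_constant(0, 1)
        assert est.ratio_limit == pytest.approx(B_CLOSED, abs=1e-3)
        assert est.gamma == pytest.approx(GOLDEN)

    def test_b1_same_limit_as_b0(self):
        """d*_1/d_1 -> rho^2: the (z^2-z+1) prefactor of D*_g against the
        1/(z^2-z+1) of D_g makes the amplitude ratio rho^2 for every g."""
        est = b_constant(1, 1)
        assert est.ratio_limit == pytest.approx(B_CLOSED, abs=2e-3)

    def test_window_fits_are_cauchy(self):
        est = b_constant(0, 1)
        fits = [v for _, v in est.diagnostics]
        assert abs(fits[1] - fits[0]) < 1e-3


class TestExpectedCandidates:
    def test_entry_count(self):
        assert expected_candidate_entries(5) == 15

    def test_small_n_by_hand(self):
        E, En = theory_expected_candidates(0, 3, 1)
        assert E == pytest.approx(3.5)
        assert En == pytest.approx(3.5 / 6)

    def test_normalized_expectation_approaches_b(self):
        _, En = theory_expected_candidates(0, 400, 1.0, N=400)
        b = b_constant(0, 1).ratio_limit
        assert 0.0 <= En <= 1.0
        assert abs(En - b) < 0.02
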