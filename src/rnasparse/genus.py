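"""Genus-filtered generating functions for the arc-based energy model.

The objects counted here are *g-structures*: partial matchings (diagrams) on
vertices 1..n with no arcs (i, i+1), whose fatgraph surface has topological
genus g.  Genus 0 recovers classical pseudoknot-free secondary structures.

Main quantities:

* ``c_g(n)`` — genus-g perfect matchings with n arcs, via the Harer–Zagier
  three-term recurrence;
* ``d_{g,tau}(n)`` — tau-weighted g-structures on n vertices, where each arc
  carries weight tau (an algebraic substitution into C_g);
* ``d*_{g,tau}(n)`` — the irreducible subclass, by the genus-indexed
  convolution recursion D*_g = (D_g/D_0 - sum D*_{g1} D_{g-g1}) / D_0;
* ``P_g(m) = d*_{g,tau}(m)/d_{g,tau}(m)`` — the probability that the
  minimum-free-energy structure over an interval of length m is irreducible,
  i.e. that the interval is a candidate of the interval-splitting
  decomposition rule;
* the expected candidate count E_g(n) = sum_m (n-m+1) P_g(m) and its
  normalization by M(n) = n(n+1)/2, which converges to the constant
  b_g = lim d*_g(n)/d_g(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Sequence, Union

from .series import (DEFAULT_ORDER_EXACT, DEFAULT_ORDER_FLOAT,
                     TruncatedSeries)

Weight = Union[int, Fraction, float]

KAPPA = Fraction(6, 16)  # chance that two uniform bases can pair (6 of 16)


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ArcEnergyModel:
    """Nussinov-like model: every arc scores ``c``; the ensemble weight of a
    structure with ``ell`` arcs is ``(kappa * eta**c)**ell = tau**ell``.

    ``tau`` is always derived from the formula, never a rounded decimal.
    """

    c: float = 1.0
    eta: float = math.e
    kappa: Fraction = KAPPA

    @property
    def tau(self) -> float:
        return float(self.kappa) * self.eta ** self.c

    def structure_weight(self, n_arcs: int) -> float:
        return self.tau ** n_arcs


@dataclass
class GenusSeriesFamily:
    """A d_{g,tau} (or d*_{g,tau}) coefficient family."""

    g: int
    tau: Weight
    N: int
    series: TruncatedSeries

    def coefficient(self, n: int) -> Weight:
        return self.series[n]


@dataclass
class AsymptoticEstimate:
    """A numerically fitted coefficient asymptotic a * n^exponent * gamma^n."""

    gamma: float
    exponent: float
    amplitude: float | None = None
    ratio_limit: float | None = None
    diagnostics: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# matchings: Harer-Zagier recurrence
# ---------------------------------------------------------------------------
@lru_cache(maxsize=None)
def _matching_counts(g_max: int, n_max: int) -> tuple:
    """c_g(n) table, 0 <= g <= g_max, 0 <= n <= n_max (number of arcs).

    Three-term recurrence on the genus-refined matching counts:
    (n+1) c_g(n) = 2(2n-1) c_g(n-1) + (2n-1)(n-1)(2n-3) c_{g-1}(n-2),
    with c_0(n) the Catalan numbers.
    """
    c = [[0] * (n_max + 1) for _ in range(g_max + 1)]
    c[0][0] = 1
    for n in range(1, n_max + 1):
        for g in range(g_max + 1):
            val = 2 * (2 * n - 1) * c[g][n - 1]
            if g >= 1 and n >= 2:
                val += (2 * n - 1) * (n - 1) * (2 * n - 3) * c[g - 1][n - 2]
            quot, rem = divmod(val, n + 1)
            assert rem == 0, "Harer-Zagier recurrence must divide exactly"
            c[g][n] = quot
    return tuple(tuple(row) for row in c)


def matching_series(g: int, N: int = DEFAULT_ORDER_EXACT) -> TruncatedSeries:
    """C_g(z): coefficient of z^n is the number of genus-g perfect matchings
    with n arcs.  C_0 is the Catalan generating function."""
    if g < 0:
        raise ValueError("genus must be >= 0")
    counts = _matching_counts(g, N)[g]
    return TruncatedSeries(list(counts), N, "exact")


# ---------------------------------------------------------------------------
# g-structures and their irreducible subclass
# ---------------------------------------------------------------------------
def _backend_for(tau: Weight) -> str:
    return "exact" if isinstance(tau, (int, Fraction)) else "float"


def _tau_key(tau: Weight) -> Weight:
    return Fraction(tau) if isinstance(tau, int) else tau


@lru_cache(maxsize=None)
def _structure_series_cached(g: int, tau: Weight, N: int) -> TruncatedSeries:
    backend = _backend_for(tau)
    # denominator tau z^2 - z + 1 and the inner substitution
    den = TruncatedSeries([1, -1, tau], N, backend)
    den_inv = den.reciprocal()
    inner = TruncatedSeries.monomial(tau, 2, N, backend) * den_inv * den_inv
    n_arcs = N // 2  # the substitution has valuation 2
    cg = matching_series(g, n_arcs)
    outer = TruncatedSeries(cg.coefficients(), N, "exact")
    if backend == "float":
        outer = outer.to_float()
    return den_inv * outer.compose(inner)


def g_structure_series(g: int, tau: Weight = 1,
                       N: int | None = None) -> GenusSeriesFamily:
    """D_{g,tau}(z): coefficient of z^n is sum_m e_g(n, m) tau^m, the
    tau-weighted count of g-structures on n vertices (d_g(n) at tau=1)."""
    if g < 0:
        raise ValueError("genus must be >= 0")
    if not tau > 0:
        raise ValueError("tau must be positive")
    if N is None:
        N = DEFAULT_ORDER_EXACT if _backend_for(tau) == "exact" else DEFAULT_ORDER_FLOAT
    series = _structure_series_cached(g, _tau_key(tau), N)
    return GenusSeriesFamily(g=g, tau=tau, N=N, series=series)


@lru_cache(maxsize=None)
def _irreducible_series_cached(g: int, tau: Weight, N: int) -> TruncatedSeries:
    d0 = _structure_series_cached(0, tau, N)
    d0_inv = d0.reciprocal()
    if g == 0:
        one = TruncatedSeries.one(N, d0.backend)
        return one - d0_inv
    # D*_g = (D_g / D_0 - sum_{g1=1}^{g-1} D*_{g1} D_{g-g1}) / D_0
    acc = _structure_series_cached(g, tau, N) * d0_inv
    for g1 in range(1, g):
        acc = acc - (_irreducible_series_cached(g1, tau, N)
                     * _structure_series_cached(g - g1, tau, N))
    return acc * d0_inv


def irreducible_series(g: int, tau: Weight = 1,
                       N: int | None = None) -> GenusSeriesFamily:
    """D*_{g,tau}(z): tau-weighted irreducible g-structures (structures that
    cannot be split by cutting the backbone without cutting an arc)."""
    if g < 0:
        raise ValueError("genus must be >= 0")
    if not tau > 0:
        raise ValueError("tau must be positive")
    if N is None:
        N = DEFAULT_ORDER_EXACT if _backend_for(tau) == "exact" else DEFAULT_ORDER_FLOAT
    series = _irreducible_series_cached(g, _tau_key(tau), N)
    return GenusSeriesFamily(g=g, tau=tau, N=N, series=series)


def _compositions(total: int, parts: int):
    """All compositions of ``total`` into ``parts`` positive parts."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def claim_identity_check(g: int, N: int = 100,
                         d0_override: TruncatedSeries | None = None) -> bool:
    """Verify the composition identity for D*_g against the convolution
    recursion, coefficient-exactly at tau=1:

    D*_g = D_g/D_0^2 + sum_{j=0}^{g-2} (-1)^{g+1-j} D_0^{-(g+1-j)}
           * sum over compositions of g into (g-j) parts of prod_i D_{sigma_i}.

    ``d0_override`` substitutes a (deliberately corrupted) D_0 on the
    composition side; used as a negative control in tests.
    """
    if not 1 <= g <= 3:
        raise ValueError("identity check supported for 1 <= g <= 3")
    tau = Fraction(1)
    d = {h: _structure_series_cached(h, tau, N) for h in range(g + 1)}
    d0 = d0_override if d0_override is not None else d[0]
    d0_inv = d0.reciprocal()
    rhs = d[g] * d0_inv * d0_inv
    for j in range(0, g - 1):
        sign = (-1) ** (g + 1 - j)
        power = TruncatedSeries.one(N, "exact")
        for _ in range(g + 1 - j):
            power = power * d0_inv
        total = TruncatedSeries.zero(N, "exact")
        for sigma in _compositions(g, g - j):
            prod = TruncatedSeries.one(N, "exact")
            for part in sigma:
                prod = prod * d[part]
            total = total + prod
        term = power * total
        rhs = rhs + term if sign > 0 else rhs - term
    lhs = _irreducible_series_cached(g, tau, N)
    return lhs == rhs


# ---------------------------------------------------------------------------
# candidate probabilities and expectations
# ---------------------------------------------------------------------------
def irreducibility_probability(g: int, m: int, tau: Weight = 1,
                               N: int | None = None) -> float:
    """P_g(m) = d*_{g,tau}(m) / d_{g,tau}(m) in [0, 1].

    Returns 0 when d_{g,tau}(m) = 0 (such intervals cannot host a genus-g
    sub-structure, hence cannot be candidates).
    """
    if N is None:
        N = max(m, 8)
    d = g_structure_series(g, tau, N).series[m]
    if d == 0:
        return 0.0
    dstar = irreducible_series(g, tau, N).series[m]
    return float(Fraction(dstar, d)) if isinstance(d, Fraction) else dstar / d


def growth_rate_arc(tau: float = 1.0) -> float:
    """Exponential growth rate gamma_tau = 1/rho_tau of d_{g,tau}(n), where
    rho_tau is the smallest positive root of tau z^2 - (1+2 sqrt(tau)) z + 1
    (equivalently of tau z^2/(tau z^2 - z + 1)^2 = 1/4).

    Valid in the supercritical regime tau > 1/4; gamma_1 = (3+sqrt(5))/2.
    """
    tau = float(tau)
    if tau <= 0.25:
        raise ValueError("tau must exceed 1/4 (supercritical regime)")
    b = 1.0 + 2.0 * math.sqrt(tau)
    disc = b * b - 4.0 * tau
    rho = (b - math.sqrt(disc)) / (2.0 * tau)
    return 1.0 / rho


def b_constant(g: int, tau: Weight = 1, N: int = DEFAULT_ORDER_FLOAT,
               tol: float = 1e-3) -> AsymptoticEstimate:
    """b_g = lim_n d*_{g,tau}(n)/d_{g,tau}(n).

    The raw ratio carries slowly decaying corrections (O(n^{-1/2}) for
    g >= 1, from the subleading (1-4u)^{-(3g-1)} singular term of D*_g), so
    the limit is extracted by a least-squares fit of the tail of the ratio
    sequence against the asymptotic basis {1, n^{-1/2}, n^{-1}, n^{-3/2}}.
    Two half-window fits must agree within ``tol`` (Cauchy check) before the
    value is accepted.
    """
    import numpy as np

    tau_f = float(tau)
    d = np.asarray(g_structure_series(g, tau_f, N).series.coefficients())
    dstar = np.asarray(irreducible_series(g, tau_f, N).series.coefficients())

    def _fit(lo: int, hi: int) -> float:
        ns = np.arange(lo, hi + 1)
        ratios = dstar[ns] / d[ns]
        basis = np.column_stack([np.ones(ns.size), ns ** -0.5,
                                 1.0 / ns, ns ** -1.5])
        coef, *_ = np.linalg.lstsq(basis, ratios, rcond=None)
        return float(coef[0])

    lo = max(4 * g + 4, N // 4)
    fits = [_fit(lo, N // 2), _fit(N // 2, N), _fit(lo, N)]
    diagnostics = [((lo, N // 2), fits[0]), ((N // 2, N), fits[1]),
                   ((lo, N), fits[2])]
    if abs(fits[1] - fits[0]) > tol:
        raise RuntimeError(
            f"b_{g} ratio did not converge within order {N}: "
            f"window fits {fits[0]:.6f}, {fits[1]:.6f}")
    return AsymptoticEstimate(
        gamma=growth_rate_arc(tau_f),
        exponent=3 * (g - 0.5),
        ratio_limit=fits[2],
        diagnostics=diagnostics,
    )


def expected_candidate_entries(n: int) -> int:
    """M(n) = sum_{m=1}^{n} (n-m+1) = n(n+1)/2: every interval the
    interval-splitting rule considers."""
    return n * (n + 1) // 2


def theory_expected_candidates(g: int, n: int, tau: Weight = 1,
                               N: int | None = None) -> tuple[float, float]:
    """(E, E/M(n)) with E = sum_{m=1}^{n} (n-m+1) P_g(m)."""
    if N is None:
        N = n
    if N < n:
        raise ValueError("series order must cover n")
    tau_f = tau if isinstance(tau, (int, Fraction)) else float(tau)
    d = g_structure_series(g, tau_f, N).series
    dstar = irreducible_series(g, tau_f, N).series
    total = 0.0
    for m in range(1, n + 1):
        dm = d[m]
        if dm == 0:
            continue
        total += (n - m + 1) * float(dstar[m] / dm if not isinstance(dm, Fraction)
                                     else Fraction(dstar[m], dm))
    return total, total / expected_candidate_entries(n)
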