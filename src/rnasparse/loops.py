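"""Energy-filtered generating functions for the simplified loop-based model.

A secondary structure decomposes uniquely into loops: hairpin loops (no
nested branch), interior loops (exactly one branch, including stacks and
bulges) and multiloops (at least two branches).  The simplified model scores
a loop by its type only:

* hairpin   w = 0.5
* interior  w = 1
* multiloop w = -5

and a structure sigma with ell arcs gets ensemble weight
``W(sigma) = kappa**ell * eta**(sum of loop scores)`` with kappa = 6/16 and
eta = e.  The irreducible structures of this filtration are those closed by
the outer arc (1, n); their weighted generating function F*(z) satisfies a
quadratic functional equation (the hairpin/interior/multiloop grammar), and
arbitrary structures are sequences of irreducible blocks interleaved with
unpaired runs:

    F(z) = 1/(1-z) * 1 / (1 - F*(z)/(1-z)).

Both coefficient sequences grow like ``amplitude * n^{-3/2} * gamma^n`` with
the same gamma = 1/rho, rho the branch point of the quadratic's
discriminant; the ratio f*(n)/f(n) tends to the constant b = alpha/beta that
governs the density of candidate intervals under this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .genus import KAPPA, AsymptoticEstimate
from .series import TruncatedSeries


@dataclass(frozen=True)
class LoopEnergyModel:
    """Per-loop scores; each arc additionally contributes one factor kappa."""

    w_hairpin: float = 0.5
    w_interior: float = 1.0
    w_multi: float = -5.0
    eta: float = math.e
    kappa: Fraction = KAPPA

    def loop_factor(self, kind: str) -> float:
        w = {"hairpin": self.w_hairpin,
             "interior": self.w_interior,
             "multi": self.w_multi}[kind]
        return self.eta ** w

    @property
    def term_weights(self) -> tuple[float, float, float]:
        """(kappa*eta^wh, kappa*eta^wi, kappa*eta^wm): the per-closing-arc
        prefactors of the hairpin, interior and multiloop grammar terms."""
        k = float(self.kappa)
        return (k * self.eta ** self.w_hairpin,
                k * self.eta ** self.w_interior,
                k * self.eta ** self.w_multi)


@dataclass
class LoopSeriesPair:
    """f*_0(n) and f_0(n) for one model (0 <= f* <= f coefficient-wise)."""

    f_star: TruncatedSeries
    f: TruncatedSeries
    model: LoopEnergyModel


# ---------------------------------------------------------------------------
# series solutions of the grammar
# ---------------------------------------------------------------------------
def _f_star_coeffs(model: LoopEnergyModel, N: int, scale: float = 1.0) -> np.ndarray:
    """Coefficients of F*(scale * y) up to order N by forward recursion.

    The grammar (s = 1/(1-z)):

        F* = kh z^2 (z s)  +  ki z^2 s^2 F*  +  km z^2 s G,
        G  = (F* s)^2 + (F* s) G      (G = sum_{i>=2} (F* s)^i),

    determines every coefficient from strictly smaller ones because each term
    carries z^2.  ``scale`` rescales the variable so that coefficients stay
    bounded when N is large (used with scale = rho for asymptotics).
    """
    kh, ki, km = model.term_weights
    r = scale
    rpow = r ** np.arange(N + 1)          # coefficients of s = 1/(1 - r y)
    s2 = (np.arange(N + 1) + 1.0) * rpow  # coefficients of s^2
    f = np.zeros(N + 1)
    G = np.zeros(N + 1)
    u = np.zeros(N + 1)                   # u = F* s
    for n in range(N + 1):
        val = 0.0
        if n >= 3:
            val += kh * r ** n
        if n >= 2:
            m = n - 2
            val += ki * r * r * np.dot(s2[: m + 1][::-1], f[: m + 1])
            val += km * r * r * np.dot(rpow[: m + 1][::-1], G[: m + 1])
        f[n] = val
        u[n] = np.dot(rpow[: n + 1][::-1], f[: n + 1])
        G[n] = np.dot(u[: n + 1], u[: n + 1][::-1]) + \
            np.dot(u[1: n + 1], G[: n][::-1])
        if not np.isfinite(f[n]):
            raise OverflowError(
                "loop-model recursion overflowed; use a smaller order or a "
                "rescaled computation")
    return f


def f_star_series(model: LoopEnergyModel | None = None, N: int = 400,
                  _scale: float = 1.0) -> TruncatedSeries:
    """F*_0(z): coefficient n is the total Assumption-1 weight of irreducible
    secondary structures on n vertices (those closed by the arc (1, n))."""
    if N < 3:
        raise ValueError("N must be at least 3 (smallest irreducible needs 3)")
    model = model or LoopEnergyModel()
    return TruncatedSeries(_f_star_coeffs(model, N, _scale), N, "float")


def f_series(model: LoopEnergyModel | None = None, N: int = 400,
             f_star: TruncatedSeries | None = None,
             _scale: float = 1.0) -> TruncatedSeries:
    """F_0(z) = s / (1 - F*_0(z) s), s = 1/(1-z): arbitrary secondary
    structures as sequences of irreducible blocks with unpaired runs."""
    model = model or LoopEnergyModel()
    if f_star is None:
        f_star = f_star_series(model, N, _scale)
    N = f_star.order
    s = TruncatedSeries(_scale ** np.arange(N + 1), N, "float")
    one = TruncatedSeries.one(N, "float")
    return s * (one - f_star * s).reciprocal()


def loop_series_pair(model: LoopEnergyModel | None = None,
                     N: int = 400) -> LoopSeriesPair:
    model = model or LoopEnergyModel()
    fs = f_star_series(model, N)
    return LoopSeriesPair(f_star=fs, f=f_series(model, N, f_star=fs), model=model)


# ---------------------------------------------------------------------------
# singularity analysis
# ---------------------------------------------------------------------------
def _discriminant_poly(model: LoopEnergyModel) -> np.ndarray:
    """Clearing the grammar to a(z) F*^2 + b(z) F* + c(z) = 0 and returning
    the polynomial (1-z)^4 (b^2 - 4ac), highest degree first.

    With s = 1/(1-z), h = kh z^3 s, i = ki z^2 s^2, m = km z^2 s^3:
        a = -s + i s - m,   b = 1 + h s - i,   c = -h,
    so  A = a (1-z)^3 = -(1-z)^2 + (ki - km) z^2,
        B = b (1-z)^2 = (1-z)^2 + kh z^3 - ki z^2,
        C = c (1-z)   = -kh z^3,
    and (1-z)^4 (b^2 - 4ac) = B^2 - 4 A C.
    """
    from numpy.polynomial import polynomial as P

    kh, ki, km = model.term_weights
    omz = np.array([1.0, -1.0])                    # 1 - z, ascending powers
    omz2 = P.polymul(omz, omz)
    A = P.polyadd(-omz2, [0, 0, ki - km])
    B = P.polyadd(omz2, [0, 0, -ki, kh])
    C = np.array([0.0, 0.0, 0.0, -kh])
    disc = P.polysub(P.polymul(B, B), 4.0 * P.polymul(A, C))
    return disc  # ascending powers


def loop_singularity(model: LoopEnergyModel | None = None) -> float:
    """Dominant singularity rho of F*_0(z): the smallest positive real root
    of the discriminant of the cleared quadratic (the branch point)."""
    model = model or LoopEnergyModel()
    roots = np.polynomial.polynomial.polyroots(_discriminant_poly(model))
    real = sorted(r.real for r in roots
                  if abs(r.imag) < 1e-9 and 1e-12 < r.real < 1.0 - 1e-9)
    if not real:
        raise RuntimeError("no real branch point in (0, 1); "
                           "model parameters look pathological")
    return float(real[0])


@dataclass
class LoopAsymptotics:
    """Fitted constants of f*_0(n) ~ alpha n^{-3/2} gamma^n and
    f_0(n) ~ beta n^{-3/2} gamma^n."""

    rho: float
    gamma: float
    alpha: AsymptoticEstimate
    beta: AsymptoticEstimate
    model: LoopEnergyModel

    @property
    def b(self) -> float:
        """b = alpha/beta, the limiting irreducibility probability."""
        return self.alpha.amplitude / self.beta.amplitude


def _extrapolate_amplitude(values: np.ndarray, checkpoints: list[int]) -> tuple[float, list]:
    """Aitken Delta^2 acceleration on a_n at dyadic checkpoints."""
    seq = [values[n] for n in checkpoints]
    diagnostics = list(zip(checkpoints, seq))
    x0, x1, x2 = seq[-3], seq[-2], seq[-1]
    denom = (x2 - x1) - (x1 - x0)
    if abs(denom) < 1e-300:
        return x2, diagnostics
    return x2 - (x2 - x1) ** 2 / denom, diagnostics


def loop_asymptotics(model: LoopEnergyModel | None = None,
                     N: int = 2048) -> LoopAsymptotics:
    """Amplitudes alpha (f*) and beta (f), estimated as extrapolated limits
    of f(n) n^{3/2} rho^n; the subexponential exponent is fixed at -3/2.

    Coefficients are computed in the rescaled variable z = rho*y so that no
    overflow occurs at large N.
    """
    model = model or LoopEnergyModel()
    if N < 256:
        raise ValueError("N too small for a stable amplitude extrapolation")
    rho = loop_singularity(model)
    fs = f_star_series(model, N, _scale=rho)
    f = f_series(model, N, f_star=fs, _scale=rho)
    n = np.arange(N + 1, dtype=float)
    n[0] = 1.0
    weights_star = np.asarray(fs.coefficients()) * n ** 1.5
    weights_all = np.asarray(f.coefficients()) * n ** 1.5
    checkpoints = [N // 4, N // 2, N]
    alpha_val, alpha_diag = _extrapolate_amplitude(weights_star, checkpoints)
    beta_val, beta_diag = _extrapolate_amplitude(weights_all, checkpoints)
    gamma = 1.0 / rho
    # convergence guard: the accelerated value must be consistent with the
    # raw tail (the raw error decays like 1/n)
    for val, raw in ((alpha_val, weights_star[N]), (beta_val, weights_all[N])):
        if not np.isfinite(val) or abs(val - raw) > 0.25 * abs(val):
            raise RuntimeError("amplitude extrapolation did not converge")
    return LoopAsymptotics(
        rho=rho,
        gamma=gamma,
        alpha=AsymptoticEstimate(gamma=gamma, exponent=-1.5,
                                 amplitude=float(alpha_val),
                                 diagnostics=alpha_diag),
        beta=AsymptoticEstimate(gamma=gamma, exponent=-1.5,
                                amplitude=float(beta_val),
                                diagnostics=beta_diag),
        model=model,
    )


def loop_irreducibility_probability(m: int,
                                    model: LoopEnergyModel | None = None,
                                    pair: LoopSeriesPair | None = None) -> float:
    """P_0(m) = f*_0(m)/f_0(m) in [0, 1] (0 for m < 3: no irreducible
    structure fits under this filtration)."""
    model = model or LoopEnergyModel()
    if pair is None or pair.f.order < m:
        pair = loop_series_pair(model, max(m, 8))
    fm = pair.f[m]
    if fm == 0:
        return 0.0
    return pair.f_star[m] / fm


def theory_expected_candidates_loop(n: int,
                                    model: LoopEnergyModel | None = None,
                                    pair: LoopSeriesPair | None = None
                                    ) -> tuple[float, float]:
    """(E_0(n), E_0(n)/M(n)) with E_0(n) = sum_m (n-m+1) P_0(m) under the
    loop filtration."""
    model = model or LoopEnergyModel()
    if pair is None or pair.f.order < n:
        pair = loop_series_pair(model, max(n, 8))
    fstar = pair.f_star.coefficients()
    f = pair.f.coefficients()
    total = 0.0
    for m in range(1, n + 1):
        if f[m]:
            total += (n - m + 1) * fstar[m] / f[m]
    return total, total / (n * (n + 1) / 2)
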