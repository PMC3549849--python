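"""Truncated formal power series over exact rationals or floats.

All generating-function computations in this package run on
:class:`TruncatedSeries`: a coefficient vector cut at a fixed order ``N``.
Two coefficient backends are supported:

``exact``
    ``fractions.Fraction`` coefficients; never rounds.  Used for all counting
    series that are cross-checked against integer enumeration.
``float``
    ``float`` coefficients (stored in a numpy array).  Used for
    energy-weighted series whose constants involve ``e``.

Design rules enforced here:

* accessing a coefficient beyond the truncation order raises ``IndexError``
  (never silent zero-extension);
* arithmetic between series of different orders truncates to the smaller
  order;
* mixing backends raises ``TypeError`` unless one operand is explicitly
  promoted with :meth:`TruncatedSeries.to_float`.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence, Union

import numpy as np

Number = Union[int, Fraction, float]

DEFAULT_ORDER_EXACT = 120
DEFAULT_ORDER_FLOAT = 400


def _is_exact(value: Number) -> bool:
    return isinstance(value, (int, Fraction)) and not isinstance(value, bool)


class TruncatedSeries:
    """A formal power series truncated at degree ``order``."""

    __slots__ = ("_coeffs", "order", "backend")

    def __init__(self, coeffs: Sequence[Number], order: int, backend: str):
        if backend not in ("exact", "float"):
            raise ValueError(f"unknown backend {backend!r}")
        if order < 0:
            raise ValueError("order must be >= 0")
        self.order = order
        self.backend = backend
        if backend == "exact":
            data = [Fraction(c) for c in coeffs[: order + 1]]
            data += [Fraction(0)] * (order + 1 - len(data))
            self._coeffs = data
        else:
            arr = np.zeros(order + 1, dtype=float)
            vals = np.asarray(coeffs[: order + 1], dtype=float)
            arr[: len(vals)] = vals
            self._coeffs = arr

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_coeffs(cls, coeffs: Iterable[Number], order: int,
                    backend: str | None = None) -> "TruncatedSeries":
        coeffs = list(coeffs)
        if backend is None:
            backend = "exact" if all(_is_exact(c) for c in coeffs) else "float"
        return cls(coeffs, order, backend)

    @classmethod
    def zero(cls, order: int, backend: str = "exact") -> "TruncatedSeries":
        return cls([], order, backend)

    @classmethod
    def one(cls, order: int, backend: str = "exact") -> "TruncatedSeries":
        return cls([1], order, backend)

    @classmethod
    def monomial(cls, coeff: Number, degree: int, order: int,
                 backend: str | None = None) -> "TruncatedSeries":
        if backend is None:
            backend = "exact" if _is_exact(coeff) else "float"
        c = [0] * degree + [coeff]
        return cls(c, order, backend)

    # ------------------------------------------------------------------
    # coefficient access
    # ------------------------------------------------------------------
    def __getitem__(self, degree: int) -> Number:
        if degree < 0 or degree > self.order:
            raise IndexError(
                f"degree {degree} outside truncation order {self.order}")
        c = self._coeffs[degree]
        return c if self.backend == "exact" else float(c)

    def coefficients(self) -> list:
        """All coefficients 0..order as a list."""
        if self.backend == "exact":
            return list(self._coeffs)
        return [float(c) for c in self._coeffs]

    def __len__(self) -> int:
        return self.order + 1

    def __eq__(self, other) -> bool:
        if not isinstance(other, TruncatedSeries):
            return NotImplemented
        if self.backend != other.backend or self.order != other.order:
            return False
        if self.backend == "exact":
            return self._coeffs == other._coeffs
        return bool(np.array_equal(self._coeffs, other._coeffs))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        head = ", ".join(str(self._coeffs[k]) for k in range(min(6, self.order + 1)))
        return f"TruncatedSeries([{head}, ...], order={self.order}, backend={self.backend})"

    # ------------------------------------------------------------------
    # backend / order management
    # ------------------------------------------------------------------
    def to_float(self) -> "TruncatedSeries":
        """Explicit promotion of an exact series to the float backend."""
        if self.backend == "float":
            return self
        return TruncatedSeries([float(c) for c in self._coeffs],
                               self.order, "float")

    def truncate(self, order: int) -> "TruncatedSeries":
        if order > self.order:
            raise ValueError("cannot extend a truncated series")
        return TruncatedSeries(self._coeffs[: order + 1], order, self.backend)

    def _check_compatible(self, other: "TruncatedSeries") -> int:
        if not isinstance(other, TruncatedSeries):
            raise TypeError("operand must be a TruncatedSeries")
        if self.backend != other.backend:
            raise TypeError(
                "backend mismatch: promote explicitly with to_float()")
        return min(self.order, other.order)

    # ------------------------------------------------------------------
    # ring operations
    # ------------------------------------------------------------------
    def __add__(self, other: "TruncatedSeries") -> "TruncatedSeries":
        n = self._check_compatible(other)
        if self.backend == "float":
            return TruncatedSeries(self._coeffs[: n + 1] + other._coeffs[: n + 1],
                                   n, "float")
        return TruncatedSeries(
            [a + b for a, b in zip(self._coeffs, other._coeffs)], n, "exact")

    def __sub__(self, other: "TruncatedSeries") -> "TruncatedSeries":
        n = self._check_compatible(other)
        if self.backend == "float":
            return TruncatedSeries(self._coeffs[: n + 1] - other._coeffs[: n + 1],
                                   n, "float")
        return TruncatedSeries(
            [a - b for a, b in zip(self._coeffs, other._coeffs)], n, "exact")

    def __neg__(self) -> "TruncatedSeries":
        if self.backend == "float":
            return TruncatedSeries(-self._coeffs, self.order, "float")
        return TruncatedSeries([-c for c in self._coeffs], self.order, "exact")

    def __mul__(self, other) -> "TruncatedSeries":
        if isinstance(other, TruncatedSeries):
            n = self._check_compatible(other)
            if self.backend == "float":
                prod = np.convolve(self._coeffs[: n + 1], other._coeffs[: n + 1])
                return TruncatedSeries(prod[: n + 1], n, "float")
            a, b = self._coeffs, other._coeffs
            out = [Fraction(0)] * (n + 1)
            for i in range(n + 1):
                ai = a[i]
                if ai:
                    for j in range(n + 1 - i):
                        if b[j]:
                            out[i + j] += ai * b[j]
            return TruncatedSeries(out, n, "exact")
        # scalar
        if self.backend == "float":
            return TruncatedSeries(self._coeffs * float(other), self.order, "float")
        if not _is_exact(other):
            raise TypeError("cannot scale an exact series by a float; "
                            "promote with to_float() first")
        s = Fraction(other)
        return TruncatedSeries([c * s for c in self._coeffs], self.order, "exact")

    __rmul__ = __mul__

    def reciprocal(self) -> "TruncatedSeries":
        """Multiplicative inverse up to the truncation order.

        Requires a nonzero constant term.
        """
        c0 = self._coeffs[0]
        if c0 == 0:
            raise ZeroDivisionError(
                "series with zero constant term has no reciprocal")
        n = self.order
        if self.backend == "exact":
            inv0 = Fraction(1) / Fraction(c0)
            out = [Fraction(0)] * (n + 1)
            out[0] = inv0
            a = self._coeffs
            for k in range(1, n + 1):
                acc = Fraction(0)
                for j in range(1, k + 1):
                    if a[j]:
                        acc += a[j] * out[k - j]
                out[k] = -acc * inv0
            return TruncatedSeries(out, n, "exact")
        a = self._coeffs
        out = np.zeros(n + 1)
        out[0] = 1.0 / c0
        for k in range(1, n + 1):
            out[k] = -np.dot(a[1: k + 1], out[k - 1:: -1][: k]) * out[0]
        return TruncatedSeries(out, n, "float")

    def compose(self, inner: "TruncatedSeries") -> "TruncatedSeries":
        """Horner-style substitution ``self(inner(z))``.

        ``inner`` must have zero constant term, which makes the composition
        well defined degree by degree.
        """
        n = self._check_compatible(inner)
        if inner._coeffs[0] != 0:
            raise ValueError("inner series must have zero constant term")
        result = TruncatedSeries.zero(n, self.backend)
        inner = inner.truncate(n)
        for k in range(min(self.order, n), -1, -1):
            result = result * inner
            ck = self._coeffs[k]
            const = TruncatedSeries.monomial(ck, 0, n, self.backend)
            result = result + const
        return result

    # ------------------------------------------------------------------
    # rational building blocks (built from reciprocal+mul on purpose:
    # one audited code path rather than closed-form coefficient formulas)
    # ------------------------------------------------------------------
    @classmethod
    def geometric(cls, order: int, backend: str = "exact") -> "TruncatedSeries":
        """1/(1-z)."""
        one_minus_z = cls([1, -1], order, backend)
        return one_minus_z.reciprocal()


def series_arith(a: TruncatedSeries, b: TruncatedSeries, op: str) -> TruncatedSeries:
    """Functional wrapper over +, -, * used by the CLI layer."""
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op == "mul":
        return a * b
    raise ValueError(f"unknown op {op!r}")
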