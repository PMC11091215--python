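"""Exact arithmetic in the ring Q + Q*sqrt(2) + Q*sqrt(3) + Q*sqrt(6).

Every per-edge value of the nine degree-based indices on the Fuchsine
sheet's three edge classes -- endpoint-degree pairs (1,3), (2,3), (3,3) --
lies in this ring: the square roots that appear are sqrt(2/3), sqrt(1/2),
sqrt(3), sqrt(6) and rationals.  Working in the ring makes "the closed form
equals the direct computation" a decidable equality instead of a floating
point tolerance check.

The ring is the biquadratic field Q(sqrt(2), sqrt(3)).  Multiplication uses
sqrt(2)*sqrt(3) = sqrt(6), sqrt(2)*sqrt(6) = 2*sqrt(3),
sqrt(3)*sqrt(6) = 3*sqrt(2).  Inversion multiplies by the three Galois
conjugates (sign flips of sqrt(2) and sqrt(3)), which lands the norm in Q.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Union

Rational = Union[int, Fraction]

_SQRT2 = math.sqrt(2.0)
_SQRT3 = math.sqrt(3.0)
_SQRT6 = math.sqrt(6.0)


class Surd:
    """An exact number a + b*sqrt(2) + c*sqrt(3) + d*sqrt(6), a..d rational."""

    __slots__ = ("a", "b", "c", "d")

    def __init__(
        self,
        a: Rational = 0,
        b: Rational = 0,
        c: Rational = 0,
        d: Rational = 0,
    ) -> None:
        object.__setattr__(self, "a", Fraction(a))
        object.__setattr__(self, "b", Fraction(b))
        object.__setattr__(self, "c", Fraction(c))
        object.__setattr__(self, "d", Fraction(d))

    def __setattr__(self, name: str, value) -> None:  # immutable
        raise AttributeError("Surd is immutable")

    # -- predicates ------------------------------------------------------

    @property
    def is_rational(self) -> bool:
        return self.b == 0 and self.c == 0 and self.d == 0

    def as_fraction(self) -> Fraction:
        if not self.is_rational:
            raise ValueError(f"{self} is irrational")
        return self.a

    # -- arithmetic ------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Surd | None":
        if isinstance(other, Surd):
            return other
        if isinstance(other, (int, Fraction)):
            return Surd(other)
        return None

    def __add__(self, other):
        o = self._coerce(other)
        if o is None:
            if isinstance(other, float):
                return float(self) + other
            return NotImplemented
        return Surd(self.a + o.a, self.b + o.b, self.c + o.c, self.d + o.d)

    __radd__ = __add__

    def __sub__(self, other):
        o = self._coerce(other)
        if o is None:
            if isinstance(other, float):
                return float(self) - other
            return NotImplemented
        return Surd(self.a - o.a, self.b - o.b, self.c - o.c, self.d - o.d)

    def __rsub__(self, other):
        return (-self) + other

    def __neg__(self) -> "Surd":
        return Surd(-self.a, -self.b, -self.c, -self.d)

    def __mul__(self, other):
        o = self._coerce(other)
        if o is None:
            if isinstance(other, float):
                return float(self) * other
            return NotImplemented
        a1, b1, c1, d1 = self.a, self.b, self.c, self.d
        a2, b2, c2, d2 = o.a, o.b, o.c, o.d
        return Surd(
            a1 * a2 + 2 * b1 * b2 + 3 * c1 * c2 + 6 * d1 * d2,
            a1 * b2 + b1 * a2 + 3 * (c1 * d2 + d1 * c2),
            a1 * c2 + c1 * a2 + 2 * (b1 * d2 + d1 * b2),
            a1 * d2 + d1 * a2 + b1 * c2 + c1 * b2,
        )

    __rmul__ = __mul__

    def conjugate2(self) -> "Surd":
        """Galois conjugate sending sqrt(2) -> -sqrt(2) (and sqrt(6) -> -sqrt(6))."""
        return Surd(self.a, -self.b, self.c, -self.d)

    def conjugate3(self) -> "Surd":
        """Galois conjugate sending sqrt(3) -> -sqrt(3) (and sqrt(6) -> -sqrt(6))."""
        return Surd(self.a, self.b, -self.c, -self.d)

    def inverse(self) -> "Surd":
        if self == 0:
            raise ZeroDivisionError("inverse of zero Surd")
        c2, c3 = self.conjugate2(), self.conjugate3()
        c23 = Surd(self.a, -self.b, -self.c, self.d)
        numer = c2 * c3 * c23
        norm = (self * numer).as_fraction()
        return numer * Surd(Fraction(1) / norm)

    def __truediv__(self, other):
        o = self._coerce(other)
        if o is None:
            if isinstance(other, float):
                return float(self) / other
            return NotImplemented
        if o.is_rational:
            q = o.as_fraction()
            if q == 0:
                raise ZeroDivisionError("division by zero")
            return self * Surd(Fraction(1) / q)
        return self * o.inverse()

    def __rtruediv__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return o / self

    def __pow__(self, k: int) -> "Surd":
        if not isinstance(k, int) or k < 0:
            return NotImplemented
        out = Surd(1)
        for _ in range(k):
            out = out * self
        return out

    # -- comparison / conversion ----------------------------------------

    def __eq__(self, other) -> bool:
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return (self.a, self.b, self.c, self.d) == (o.a, o.b, o.c, o.d)

    def __hash__(self) -> int:
        return hash((self.a, self.b, self.c, self.d))

    def __float__(self) -> float:
        return (
            float(self.a)
            + float(self.b) * _SQRT2
            + float(self.c) * _SQRT3
            + float(self.d) * _SQRT6
        )

    def coefficients(self) -> tuple[Fraction, Fraction, Fraction, Fraction]:
        """The (a, b, c, d) tuple over the basis (1, sqrt2, sqrt3, sqrt6)."""
        return (self.a, self.b, self.c, self.d)

    # -- rendering -------------------------------------------------------

    def __str__(self) -> str:
        parts: list[str] = []
        for coef, sym in zip(
            (self.a, self.b, self.c, self.d), ("", "sqrt2", "sqrt3", "sqrt6")
        ):
            if coef == 0:
                continue
            mag = abs(coef)
            if sym and mag == 1:
                body = sym
            elif sym:
                body = f"{mag}*{sym}"
            else:
                body = f"{mag}"
            if not parts:
                parts.append(body if coef > 0 else f"-{body}")
            else:
                parts.append(f"+ {body}" if coef > 0 else f"- {body}")
        return " ".join(parts) if parts else "0"

    def __repr__(self) -> str:
        return f"Surd({self.a!r}, {self.b!r}, {self.c!r}, {self.d!r})"


#: convenient constants
ZERO = Surd(0)
ONE = Surd(1)
SQRT2 = Surd(0, 1)
SQRT3 = Surd(0, 0, 1)
SQRT6 = Surd(0, 0, 0, 1)


def _squarefree_split(t: int) -> tuple[int, int]:
    """Write t = s*s * k with k squarefree; return (s, k).  t >= 1."""
    s, k = 1, 1
    p = 2
    while p * p <= t:
        e = 0
        while t % p == 0:
            t //= p
            e += 1
        s *= p ** (e // 2)
        if e % 2:
            k *= p
        p += 1 if p == 2 else 2
    k *= t  # leftover prime
    return s, k


def surd_sqrt(q: Rational) -> Surd | None:
    """Exact square root of a non-negative rational, if it lies in the ring.

    Returns None when sqrt(q) is not of the form r*sqrt(k) with rational r
    and k in {1, 2, 3, 6}.
    """
    q = Fraction(q)
    if q < 0:
        return None
    if q == 0:
        return ZERO
    # sqrt(num/den) = sqrt(num*den) / den
    t = q.numerator * q.denominator
    s, k = _squarefree_split(t)
    r = Fraction(s, q.denominator)
    if k == 1:
        return Surd(r)
    if k == 2:
        return Surd(0, r)
    if k == 3:
        return Surd(0, 0, r)
    if k == 6:
        return Surd(0, 0, 0, r)
    return None
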