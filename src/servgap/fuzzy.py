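"""Trapezoidal fuzzy numbers and the componentwise algebra used throughout.

A trapezoidal fuzzy number ``A = (a, b, c, d)`` with ``a <= b <= c <= d``
describes a piecewise-linear membership function that ramps from 0 at ``a``
to 1 at ``b``, stays at 1 on the plateau ``[b, c]``, and ramps back to 0 at
``d``.  ``b == c`` degenerates to a triangular number and ``a == b``,
``c == d`` to a crisp interval; both are permitted.

The algebra here is deliberately *componentwise*: sums, differences,
products, quotients and scalar multiples act coordinate by coordinate on the
4-tuples.  Addition, nonnegative multiplication and nonnegative scaling
preserve the trapezoid ordering; subtraction and division in general do
not, so those two return a :class:`SignedTuple` that carries an ``ordered``
flag instead of silently re-sorting the components.

Defuzzification uses the segmentation-integral value
``(a + 2b + 2c + d) / 6``, which is linear in the components — a property
the gap analysis relies on (the crisp difference of two defuzzified
trapezoids equals the defuzzified componentwise difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Iterator, Sequence, Union

__all__ = [
    "TrapezoidalFuzzyNumber",
    "SignedTuple",
    "add",
    "subtract",
    "multiply",
    "divide",
    "scale",
    "mean_of",
    "weighted_mean",
    "defuzzify",
    "round_half_up",
]


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"components must be finite, got {v!r}")


@dataclass(frozen=True)
class TrapezoidalFuzzyNumber:
    """An ordered 4-tuple ``(a, b, c, d)`` with ``a <= b <= c <= d``."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        _check_finite(self.a, self.b, self.c, self.d)
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(
                f"trapezoid components must satisfy a <= b <= c <= d, got "
                f"({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())

    @property
    def is_triangular(self) -> bool:
        return self.b == self.c

    @property
    def is_interval(self) -> bool:
        return self.a == self.b and self.c == self.d

    def membership(self, x: float) -> float:
        """Membership grade of ``x``, piecewise linear, 1 on ``[b, c]``.

        Degenerate ramps (``a == b`` or ``c == d``) are treated as steps:
        the plateau edge itself has membership 1.
        """
        if not math.isfinite(x):
            raise ValueError(f"x must be finite, got {x!r}")
        if x < self.a or x > self.d:
            return 0.0
        if self.b <= x <= self.c:
            return 1.0
        if x < self.b:
            # a <= x < b with a < b guaranteed here
            return (x - self.a) / (self.b - self.a)
        # c < x <= d with c < d guaranteed here
        return (self.d - x) / (self.d - self.c)

    def defuzzify(self) -> float:
        return defuzzify(self)

    def scale(self, lam: float) -> "TrapezoidalFuzzyNumber":
        return scale(lam, self)


@dataclass(frozen=True)
class SignedTuple:
    """Formal componentwise result whose ordering is not guaranteed.

    Produced by :func:`subtract` and :func:`divide`, whose printed
    componentwise definitions can break ``a <= b <= c <= d``.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        _check_finite(self.a, self.b, self.c, self.d)

    @property
    def ordered(self) -> bool:
        return self.a <= self.b <= self.c <= self.d

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())

    def as_trapezoid(self) -> TrapezoidalFuzzyNumber:
        """Reinterpret as a trapezoid; raises if the ordering is broken."""
        return TrapezoidalFuzzyNumber(*self.as_tuple())

    def defuzzify(self) -> float:
        return defuzzify(self)


FuzzyLike = Union[TrapezoidalFuzzyNumber, SignedTuple, Sequence[float]]


def _components(x: FuzzyLike) -> tuple[float, float, float, float]:
    if isinstance(x, (TrapezoidalFuzzyNumber, SignedTuple)):
        return x.as_tuple()
    t = tuple(float(v) for v in x)
    if len(t) != 4:
        raise ValueError(f"expected 4 components, got {len(t)}")
    _check_finite(*t)
    return t  # type: ignore[return-value]


def add(x: FuzzyLike, y: FuzzyLike) -> TrapezoidalFuzzyNumber:
    """Componentwise sum; ordering is preserved for ordered operands."""
    xa, xb, xc, xd = _components(x)
    ya, yb, yc, yd = _components(y)
    return TrapezoidalFuzzyNumber(xa + ya, xb + yb, xc + yc, xd + yd)


def subtract(x: FuzzyLike, y: FuzzyLike) -> SignedTuple:
    """Componentwise difference; may be unordered, hence a SignedTuple."""
    xa, xb, xc, xd = _components(x)
    ya, yb, yc, yd = _components(y)
    return SignedTuple(xa - ya, xb - yb, xc - yc, xd - yd)


def multiply(x: FuzzyLike, y: FuzzyLike) -> TrapezoidalFuzzyNumber:
    """Componentwise product of nonnegative trapezoids."""
    xs = _components(x)
    ys = _components(y)
    if any(v < 0 for v in xs) or any(v < 0 for v in ys):
        raise ValueError("componentwise multiplication requires nonnegative operands")
    return TrapezoidalFuzzyNumber(*(u * v for u, v in zip(xs, ys)))


def divide(x: FuzzyLike, y: FuzzyLike) -> SignedTuple:
    """Literal componentwise quotient ``(a1/a2, b1/b2, c1/c2, d1/d2)``.

    This is not a standard fuzzy division (the standard extension-principle
    quotient pairs opposite components); it is kept componentwise for
    fidelity with the rest of the algebra and therefore returns a
    :class:`SignedTuple`.  Every component of the divisor must be > 0.
    """
    xs = _components(x)
    ys = _components(y)
    if any(v <= 0 for v in ys):
        raise ZeroDivisionError("divisor components must all be > 0")
    return SignedTuple(*(u / v for u, v in zip(xs, ys)))


def scale(lam: float, x: FuzzyLike) -> TrapezoidalFuzzyNumber:
    """``lam * x`` componentwise, defined for ``lam >= 0`` only."""
    if not math.isfinite(lam):
        raise ValueError(f"scale factor must be finite, got {lam!r}")
    if lam < 0:
        raise ValueError(f"scale factor must be >= 0, got {lam}")
    return TrapezoidalFuzzyNumber(*(lam * v for v in _components(x)))


def mean_of(collection: Iterable[FuzzyLike]) -> TrapezoidalFuzzyNumber:
    """Componentwise arithmetic mean of a non-empty collection."""
    items = [_components(x) for x in collection]
    if not items:
        raise ValueError("mean_of requires a non-empty collection")
    n = len(items)
    return TrapezoidalFuzzyNumber(*(sum(col) / n for col in zip(*items)))


def weighted_mean(
    collection: Sequence[FuzzyLike], weights: Sequence[float]
) -> TrapezoidalFuzzyNumber:
    """Componentwise weighted mean with crisp nonnegative weights."""
    items = [_components(x) for x in collection]
    if not items:
        raise ValueError("weighted_mean requires a non-empty collection")
    if len(weights) != len(items):
        raise ValueError("weights and collection must have the same length")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("total weight must be > 0")
    return TrapezoidalFuzzyNumber(
        *(sum(w * comp[i] for w, comp in zip(weights, items)) / total for i in range(4))
    )


def defuzzify(x: FuzzyLike) -> float:
    """Segmentation-integral crisp value ``(a + 2b + 2c + d) / 6``.

    Linear in the components; ordering of the tuple is not required.
    """
    a, b, c, d = _components(x)
    return (a + 2.0 * b + 2.0 * c + d) / 6.0


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties going away from zero, as the report tables do.

    A 12-decimal guard quantisation absorbs binary floating-point noise so
    that values like ``0.7584999999999999`` (an ulp below the intended
    0.7585) still round up to 0.759.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    guarded = Decimal(repr(x)).quantize(Decimal("1e-12"), rounding=ROUND_HALF_UP)
    return float(guarded.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))
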