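"""Linguistic term sets and their trapezoidal-fuzzy encoding.

Raters answer on an ordered verbal scale ``S = {S_0, ..., S_T}`` whose
granularity (``T + 1`` terms) they choose themselves — a 5-term rater and a
7-term rater can sit on the same panel.  An answer is either a single term
``S_t`` or, when the rater hesitates, an interval ``[S_m, S_n]`` of
consecutive terms.

Commensurability across granularities comes from encoding every value onto
the unit interval with its *own* scale's ``T``:

    A = ( max{(2m-1)/(2T+1), 0},  2m/(2T+1),  (2n+1)/(2T+1),
          min{(2n+2)/(2T+1), 1} )

after which trapezoids from different scales mix freely in the downstream
arithmetic.  No explicit granularity-transformation step is needed.

A scale may declare an *extended* maximum index ``extended_T > T`` so that
out-of-scale judgements remain representable; indices above ``T`` encode
with the base ``T`` denominator and saturate at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .fuzzy import TrapezoidalFuzzyNumber

__all__ = [
    "LinguisticTermSet",
    "LinguisticValue",
    "encode",
    "TERMSET_5",
    "TERMSET_7",
    "DEFAULT_TERM_SETS",
]


@dataclass(frozen=True)
class LinguisticTermSet:
    """An ordered verbal rating scale with ``T + 1`` labelled terms."""

    id: str
    labels: tuple[str, ...]
    extended_T: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("a term set needs at least 2 terms (T >= 1)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"term labels must be unique in set {self.id!r}")
        if self.extended_T is not None and self.extended_T < self.T:
            raise ValueError("extended_T must be >= T")

    @property
    def T(self) -> int:
        """Maximum base term index (granularity minus one)."""
        return len(self.labels) - 1

    @property
    def max_index(self) -> int:
        """Largest legal index: ``extended_T`` when configured, else ``T``."""
        return self.extended_T if self.extended_T is not None else self.T

    def label(self, t: int) -> str:
        if not 0 <= t <= self.T:
            raise IndexError(f"term index {t} outside 0..{self.T}")
        return self.labels[t]

    def negate(self, t: int) -> int:
        """Scale reversal ``Neg(S_t) = S_{T-t}``."""
        if not 0 <= t <= self.T:
            raise IndexError(f"term index {t} outside 0..{self.T}")
        return self.T - t

    @staticmethod
    def term_max(t1: int, t2: int) -> int:
        return max(t1, t2)

    @staticmethod
    def term_min(t1: int, t2: int) -> int:
        return min(t1, t2)

    def value(self, m: int, n: int | None = None, *, clamp: bool = False) -> "LinguisticValue":
        """Build a (possibly interval) value on this scale.

        With ``clamp=True`` out-of-range indices snap to ``[0, max_index]``
        instead of raising.
        """
        if n is None:
            n = m
        if clamp:
            m = min(max(m, 0), self.max_index)
            n = min(max(n, 0), self.max_index)
        return LinguisticValue(self, m, n)

    def encode(self, m: int, n: int | None = None) -> TrapezoidalFuzzyNumber:
        """Trapezoidal encoding of ``[S_m, S_n]`` on the unit interval."""
        return self.value(m, n).encode()

    def reference_encodings(self) -> list[TrapezoidalFuzzyNumber]:
        """Encodings of every base term ``S_0 .. S_T`` (the reference set)."""
        return [self.encode(t) for t in range(self.T + 1)]

    def to_dict(self) -> dict:
        out: dict = {"id": self.id, "labels": list(self.labels)}
        if self.extended_T is not None:
            out["extended_T"] = self.extended_T
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinguisticTermSet":
        return cls(id=d["id"], labels=tuple(d["labels"]), extended_T=d.get("extended_T"))


@dataclass(frozen=True)
class LinguisticValue:
    """An uncertain linguistic answer ``[S_m, S_n]`` on a concrete scale.

    ``m == n`` is an ordinary point answer.  Indices up to the scale's
    ``extended_T`` (when configured) are accepted.
    """

    term_set: LinguisticTermSet
    m: int
    n: int

    def __post_init__(self) -> None:
        hi = self.term_set.max_index
        if not (0 <= self.m <= self.n <= hi):
            raise ValueError(
                f"require 0 <= m <= n <= {hi} on set {self.term_set.id!r}, "
                f"got m={self.m}, n={self.n}"
            )

    @property
    def set_id(self) -> str:
        return self.term_set.id

    @property
    def is_point(self) -> bool:
        return self.m == self.n

    def encode(self) -> TrapezoidalFuzzyNumber:
        """Encode onto [0, 1] with this value's own scale granularity.

        Besides the lower clamp on ``a`` and upper clamp on ``d``, the inner
        components are clamped to [0, 1] too so that extended-set indices
        (above ``T``) still yield a valid normalized trapezoid.
        """
        T = self.term_set.T
        den = 2 * T + 1

        def clip(x: float) -> float:
            return min(max(x, 0.0), 1.0)

        a = max((2 * self.m - 1) / den, 0.0)
        b = clip(2 * self.m / den)
        c = clip((2 * self.n + 1) / den)
        d = min((2 * self.n + 2) / den, 1.0)
        return TrapezoidalFuzzyNumber(min(a, 1.0), b, c, d)

    def __str__(self) -> str:
        ts = self.term_set
        lo = ts.labels[self.m] if self.m <= ts.T else f"S_{self.m}"
        if self.is_point:
            return lo
        hi = ts.labels[self.n] if self.n <= ts.T else f"S_{self.n}"
        return f"[{lo}, {hi}]"


def encode(value: LinguisticValue) -> TrapezoidalFuzzyNumber:
    """Functional form of :meth:`LinguisticValue.encode`."""
    return value.encode()


# Preset scales matching the two example granularities: a coarse 5-term
# scale and the 7-term scale used both for performance and for importance
# ("very unimportant" .. "very important") wording.
TERMSET_5 = LinguisticTermSet(
    "termset-5", ("fail", "pass", "good", "very good", "excellent")
)
TERMSET_7 = LinguisticTermSet(
    "termset-7",
    ("very poor", "poor", "slightly poor", "fair", "slightly good", "good", "very good"),
)

DEFAULT_TERM_SETS: dict[str, LinguisticTermSet] = {
    ts.id: ts for ts in (TERMSET_5, TERMSET_7)
}
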