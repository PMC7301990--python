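"""Panel and survey aggregation into per-indicator trapezoids.

Two aggregation paths share the same componentwise mean machinery:

* expert importance panels — ``f`` experts each rate every indicator's
  importance on their preferred scale; the weighted mean of the encoded
  trapezoids summarises the panel.  The case study uses equal crisp
  weights, under which the weighted mean reduces exactly to the plain
  componentwise mean.
* respondent surveys — ``l`` respondents give paired perception and
  expectation answers per indicator; the componentwise means AP and AE feed
  the gap analysis.

Linguistic (fuzzy) expert weights are supported literally — fuzzy multiply
then componentwise divide by the fuzzy weight total — but only behind an
explicit opt-in, because the componentwise quotient may return an unordered
tuple.  Equal crisp weights are the validated configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

from .fuzzy import (
    SignedTuple,
    TrapezoidalFuzzyNumber,
    add,
    divide,
    mean_of,
    multiply,
    weighted_mean,
)
from .linguistic import LinguisticValue

__all__ = [
    "Expert",
    "ExpertRatings",
    "SurveyResponses",
    "expert_mean",
    "expert_means",
    "survey_means",
    "survey_means_all",
]

Weight = Union[float, int, LinguisticValue]


@dataclass(frozen=True)
class Expert:
    id: str
    weight: Weight = 1.0


@dataclass
class ExpertRatings:
    """A complete grid of expert importance ratings.

    ``cells`` maps ``(expert_id, indicator_id)`` to the expert's linguistic
    answer on their own scale.  ``indicator_ids`` fixes the indicator order.
    """

    experts: tuple[Expert, ...]
    indicator_ids: tuple[str, ...]
    cells: dict[tuple[str, str], LinguisticValue]

    def __post_init__(self) -> None:
        self.experts = tuple(self.experts)
        self.indicator_ids = tuple(self.indicator_ids)
        ids = [e.id for e in self.experts]
        if len(set(ids)) != len(ids):
            raise ValueError("expert ids must be unique")
        if not self.experts:
            raise ValueError("need at least one expert")
        weights = [e.weight for e in self.experts]
        crisp = [w for w in weights if not isinstance(w, LinguisticValue)]
        if crisp and len(crisp) != len(weights):
            raise ValueError("mixed crisp and linguistic expert weights are not supported")
        if crisp:
            if any(w < 0 for w in crisp):
                raise ValueError("crisp expert weights must be >= 0")
            if sum(crisp) <= 0:
                raise ValueError("total expert weight must be > 0")

    @property
    def f(self) -> int:
        """Number of experts."""
        return len(self.experts)

    @property
    def has_fuzzy_weights(self) -> bool:
        return any(isinstance(e.weight, LinguisticValue) for e in self.experts)

    def cell(self, expert_id: str, indicator_id: str) -> LinguisticValue:
        try:
            return self.cells[(expert_id, indicator_id)]
        except KeyError:
            raise KeyError(
                f"missing rating: expert {expert_id!r}, indicator {indicator_id!r}"
            ) from None


@dataclass
class SurveyResponses:
    """Congruent perception and expectation grids over ``l`` respondents."""

    respondent_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    perception: dict[tuple[str, str], LinguisticValue]
    expectation: dict[tuple[str, str], LinguisticValue]

    def __post_init__(self) -> None:
        self.respondent_ids = tuple(self.respondent_ids)
        self.indicator_ids = tuple(self.indicator_ids)
        if not self.respondent_ids:
            raise ValueError("need at least one respondent (l >= 1)")
        if len(set(self.respondent_ids)) != len(self.respondent_ids):
            raise ValueError("respondent ids must be unique")

    @property
    def l(self) -> int:  # noqa: E741 - field name from the survey notation
        """Number of respondents."""
        return len(self.respondent_ids)


def expert_mean(
    ratings: ExpertRatings,
    indicator_id: str,
    *,
    allow_fuzzy_weights: bool = False,
) -> TrapezoidalFuzzyNumber | SignedTuple:
    """Weighted mean trapezoid of one indicator's expert panel.

    Crisp weights give an exact componentwise weighted mean of the encoded
    ratings (a valid trapezoid).  Linguistic weights evaluate the literal
    fuzzy form — sum of fuzzy products over fuzzy weight total, via the
    componentwise product and quotient — and return a
    :class:`~servgap.fuzzy.SignedTuple` whose ``ordered`` flag must be
    checked by the caller; this path requires ``allow_fuzzy_weights=True``.
    """
    encoded = [
        ratings.cell(e.id, indicator_id).encode() for e in ratings.experts
    ]
    if not ratings.has_fuzzy_weights:
        return weighted_mean(encoded, [float(e.weight) for e in ratings.experts])

    if not allow_fuzzy_weights:
        raise ValueError(
            "panel has linguistic expert weights; pass allow_fuzzy_weights=True "
            "to evaluate the literal fuzzy form (componentwise division may "
            "yield an unordered tuple)"
        )
    warnings.warn(
        "fuzzy expert weights use componentwise division; the result may be "
        "an unordered tuple",
        stacklevel=2,
    )
    w_enc = [e.weight.encode() for e in ratings.experts]  # type: ignore[union-attr]
    numerator: TrapezoidalFuzzyNumber | None = None
    total: TrapezoidalFuzzyNumber | None = None
    for w, v in zip(w_enc, encoded):
        term = multiply(w, v)
        numerator = term if numerator is None else add(numerator, term)
        total = w if total is None else add(total, w)
    assert numerator is not None and total is not None
    return divide(numerator, total)


def expert_means(
    ratings: ExpertRatings, *, allow_fuzzy_weights: bool = False
) -> dict[str, TrapezoidalFuzzyNumber | SignedTuple]:
    """Per-indicator panel means, in the grid's indicator order."""
    return {
        iid: expert_mean(ratings, iid, allow_fuzzy_weights=allow_fuzzy_weights)
        for iid in ratings.indicator_ids
    }


def _grid_mean(
    grid: Mapping[tuple[str, str], LinguisticValue],
    respondent_ids: Sequence[str],
    indicator_id: str,
    missing: str,
) -> TrapezoidalFuzzyNumber:
    encoded = []
    for rid in respondent_ids:
        val = grid.get((rid, indicator_id))
        if val is None:
            if missing == "drop":
                continue
            raise KeyError(
                f"missing answer: respondent {rid!r}, indicator {indicator_id!r}"
            )
        encoded.append(val.encode())
    if not encoded:
        raise ValueError(f"no answers left for indicator {indicator_id!r}")
    return mean_of(encoded)


def survey_means(
    responses: SurveyResponses,
    indicator_id: str,
    *,
    missing: str = "error",
) -> tuple[TrapezoidalFuzzyNumber, TrapezoidalFuzzyNumber]:
    """(AP, AE): componentwise mean perception and expectation trapezoids.

    ``missing`` is ``"error"`` (default, any absent cell raises) or
    ``"drop"`` (drop that respondent for this indicator only; perception
    and expectation are dropped independently per grid).
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-data policy {missing!r}")
    ap = _grid_mean(responses.perception, responses.respondent_ids, indicator_id, missing)
    ae = _grid_mean(responses.expectation, responses.respondent_ids, indicator_id, missing)
    return ap, ae


def survey_means_all(
    responses: SurveyResponses, *, missing: str = "error"
) -> dict[str, tuple[TrapezoidalFuzzyNumber, TrapezoidalFuzzyNumber]]:
    return {
        iid: survey_means(responses, iid, missing=missing)
        for iid in responses.indicator_ids
    }
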