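"""Similarity-based indicator screening.

Each indicator's panel-mean trapezoid ``f*`` is compared against the
encodings ``M_0 .. M_g`` of a reference importance scale through the scaled
L1 similarity

    Y(f*, M_t) = 1 - (1/4) * sum_h |f*_h - M_t^h|,

taken componentwise over the four tuple entries.  The reference term with
the highest similarity classifies the indicator into a configured zone
partition of the scale — remove (unimportant end), review (the middle), or
keep (important end).  Ties at the argmax always force "review": borderline
calls are left to the experts, as are the merges that resolve them
(:class:`~servgap.hierarchy.MergePlan`).

``ImportanceScreening`` / ``ScreeningResults`` wrap the pipeline in the
model/results idiom: the model holds the data and configuration, ``fit()``
aggregates, profiles and decides, and the results object carries the
similarity table, the decisions and the hierarchy editing step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import ExpertRatings, expert_means
from .fuzzy import FuzzyLike, TrapezoidalFuzzyNumber, round_half_up, _components
from .hierarchy import IndicatorHierarchy, MergePlan, apply_plan
from .linguistic import TERMSET_7, LinguisticTermSet

__all__ = [
    "similarity",
    "SimilarityProfile",
    "Zones",
    "ScreeningDecision",
    "decide",
    "ImportanceScreening",
    "ScreeningResults",
]

_TIE_TOL = 1e-9


def similarity(f: FuzzyLike, M: FuzzyLike) -> float:
    """Scaled-L1 similarity ``1 - mean |f_h - M_h|`` between two 4-tuples.

    Both tuples are expected on the normalized [0, 1] scale; a warning is
    emitted otherwise because the value may then leave [0, 1].
    """
    fs = _components(f)
    ms = _components(M)
    if any(not 0.0 <= v <= 1.0 for v in fs + ms):
        warnings.warn(
            "similarity inputs are not normalized to [0, 1]; the similarity "
            "degree may leave [0, 1]",
            stacklevel=2,
        )
    return 1.0 - 0.25 * sum(abs(u - v) for u, v in zip(fs, ms))


@dataclass(frozen=True)
class SimilarityProfile:
    """Similarities of one indicator's mean trapezoid to every reference term."""

    indicator_id: str
    similarities: tuple[float, ...]
    argmax_term: int
    tie: bool

    @classmethod
    def compute(
        cls,
        f: FuzzyLike,
        reference_set: LinguisticTermSet,
        indicator_id: str = "",
        tie_tol: float = _TIE_TOL,
    ) -> "SimilarityProfile":
        sims = tuple(
            similarity(f, M) for M in reference_set.reference_encodings()
        )
        best = int(np.argmax(sims))
        n_max = sum(1 for s in sims if s >= sims[best] - tie_tol)
        return cls(
            indicator_id=indicator_id,
            similarities=sims,
            argmax_term=best,
            tie=n_max >= 2,
        )


@dataclass(frozen=True)
class Zones:
    """Partition of reference term indices into remove / review / keep."""

    remove: frozenset[int]
    review: frozenset[int]
    keep: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "remove", frozenset(self.remove))
        object.__setattr__(self, "review", frozenset(self.review))
        object.__setattr__(self, "keep", frozenset(self.keep))
        if (
            self.remove & self.review
            or self.remove & self.keep
            or self.review & self.keep
        ):
            raise ValueError("zones must be disjoint")

    def validate_for(self, T: int) -> None:
        covered = self.remove | self.review | self.keep
        if covered != set(range(T + 1)):
            raise ValueError(
                f"zones must partition term indices 0..{T}, got {sorted(covered)}"
            )

    def zone_of(self, term: int) -> str:
        if term in self.remove:
            return "remove"
        if term in self.review:
            return "review"
        if term in self.keep:
            return "keep"
        raise ValueError(f"term index {term} not covered by any zone")

    @classmethod
    def default_for(cls, T: int) -> "Zones":
        """Lower half removes, upper half keeps, exact middle (even T) reviews.

        For the 7-term importance scale (T=6) this is remove {0,1,2},
        review {3}, keep {4,5,6}.
        """
        if T < 1:
            raise ValueError("T must be >= 1")
        if T % 2 == 0:
            mid = T // 2
            return cls(
                remove=frozenset(range(0, mid)),
                review=frozenset({mid}),
                keep=frozenset(range(mid + 1, T + 1)),
            )
        half = (T + 1) // 2
        return cls(
            remove=frozenset(range(0, half)),
            review=frozenset(),
            keep=frozenset(range(half, T + 1)),
        )


@dataclass(frozen=True)
class ScreeningDecision:
    indicator_id: str
    decision: str  # keep | remove | review
    argmax_term: int
    rationale: str


def decide(profile: SimilarityProfile, zones: Zones) -> ScreeningDecision:
    """Zone of the argmax term; ties always yield "review"."""
    if profile.tie:
        return ScreeningDecision(
            indicator_id=profile.indicator_id,
            decision="review",
            argmax_term=profile.argmax_term,
            rationale="tie at the similarity argmax; referred to expert judgement",
        )
    zone = zones.zone_of(profile.argmax_term)
    return ScreeningDecision(
        indicator_id=profile.indicator_id,
        decision=zone,
        argmax_term=profile.argmax_term,
        rationale=f"highest similarity at reference term S_{profile.argmax_term}",
    )


class ImportanceScreening:
    """Screen an indicator system from an expert importance panel.

    Parameters
    ----------
    ratings
        Complete expert panel over the hierarchy's indicators.
    hierarchy
        The initial indicator hierarchy being screened.
    reference_set
        Importance scale whose term encodings act as reference trapezoids;
        defaults to the 7-term scale.
    zones
        Remove/review/keep partition of the reference indices; defaults to
        :meth:`Zones.default_for` of the reference scale.
    """

    def __init__(
        self,
        ratings: ExpertRatings,
        hierarchy: IndicatorHierarchy,
        reference_set: LinguisticTermSet = TERMSET_7,
        zones: Zones | None = None,
        *,
        allow_fuzzy_weights: bool = False,
    ) -> None:
        missing = set(hierarchy.indicator_ids) - set(ratings.indicator_ids)
        if missing:
            raise ValueError(f"ratings lack indicators: {sorted(missing)}")
        self.ratings = ratings
        self.hierarchy = hierarchy
        self.reference_set = reference_set
        self.zones = zones if zones is not None else Zones.default_for(reference_set.T)
        self.zones.validate_for(reference_set.T)
        self.allow_fuzzy_weights = allow_fuzzy_weights

    def fit(self) -> "ScreeningResults":
        aggregates = expert_means(
            self.ratings, allow_fuzzy_weights=self.allow_fuzzy_weights
        )
        profiles = {}
        decisions = {}
        for iid in self.hierarchy.indicator_ids:
            agg = aggregates[iid]
            if not isinstance(agg, TrapezoidalFuzzyNumber):
                if not agg.ordered:
                    warnings.warn(
                        f"aggregate for {iid!r} is an unordered tuple; similarity "
                        "is still the componentwise scaled L1",
                        stacklevel=2,
                    )
            prof = SimilarityProfile.compute(agg, self.reference_set, indicator_id=iid)
            profiles[iid] = prof
            decisions[iid] = decide(prof, self.zones)
        return ScreeningResults(self, aggregates, profiles, decisions)


class ScreeningResults:
    """Fitted screening: aggregates, similarity profiles and decisions."""

    def __init__(
        self,
        model: ImportanceScreening,
        aggregates: Mapping[str, FuzzyLike],
        profiles: Mapping[str, SimilarityProfile],
        decisions: Mapping[str, ScreeningDecision],
    ) -> None:
        self.model = model
        self.aggregates = dict(aggregates)
        self.profiles = dict(profiles)
        self.decisions = dict(decisions)

    @property
    def hierarchy(self) -> IndicatorHierarchy:
        return self.model.hierarchy

    @property
    def removed_ids(self) -> tuple[str, ...]:
        return tuple(
            iid
            for iid in self.hierarchy.indicator_ids
            if self.decisions[iid].decision == "remove"
        )

    @property
    def review_ids(self) -> tuple[str, ...]:
        return tuple(
            iid
            for iid in self.hierarchy.indicator_ids
            if self.decisions[iid].decision == "review"
        )

    @property
    def kept_ids(self) -> tuple[str, ...]:
        return tuple(
            iid
            for iid in self.hierarchy.indicator_ids
            if self.decisions[iid].decision == "keep"
        )

    def similarity_table(self, decimals: int | None = None) -> pd.DataFrame:
        """Indicators × reference terms similarity matrix.

        Full precision by default; pass ``decimals`` (the reports use 4)
        for the half-up-rounded presentation.
        """
        ref = self.model.reference_set
        cols = [f"S_{t}" for t in range(ref.T + 1)]
        rows = {
            iid: list(self.profiles[iid].similarities)
            for iid in self.hierarchy.indicator_ids
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        df.index.name = "indicator_id"
        if decimals is not None:
            df = df.map(lambda v: round_half_up(v, decimals))
        return df

    def decision_frame(self) -> pd.DataFrame:
        rows = []
        for iid in self.hierarchy.indicator_ids:
            dec = self.decisions[iid]
            prof = self.profiles[iid]
            rows.append(
                {
                    "indicator_id": iid,
                    "name": self.hierarchy.indicator(iid).name,
                    "argmax_term": dec.argmax_term,
                    "argmax_label": self.model.reference_set.label(dec.argmax_term)
                    if dec.argmax_term <= self.model.reference_set.T
                    else f"S_{dec.argmax_term}",
                    "max_similarity": prof.similarities[prof.argmax_term],
                    "tie": prof.tie,
                    "decision": dec.decision,
                    "rationale": dec.rationale,
                }
            )
        return pd.DataFrame(rows).set_index("indicator_id")

    def apply_plan(self, plan: MergePlan | None = None) -> IndicatorHierarchy:
        """Optimized hierarchy: removals applied, then the given merges."""
        return apply_plan(self.hierarchy, self.decisions, plan)

    def summary(self, decimals: int = 4) -> str:
        df = self.decision_frame().copy()
        df["max_similarity"] = df["max_similarity"].map(
            lambda v: round_half_up(v, decimals)
        )
        counts = df["decision"].value_counts().to_dict()
        head = (
            "Indicator importance screening\n"
            f"  experts: {self.model.ratings.f}, "
            f"indicators: {self.hierarchy.n_indicators}, "
            f"reference scale: {self.model.reference_set.id} "
            f"(T={self.model.reference_set.T})\n"
            f"  decisions: "
            + ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
            + "\n\n"
        )
        return head + df.drop(columns=["rationale"]).to_string()
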