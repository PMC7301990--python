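"""Synthetic expert panels and surveys with planted structure.

The raw questionnaires behind the case study are not redistributable, so
this module generates stand-ins with the same shape and known ground
truth: a panel of 15 equally weighted experts rating 24 indicators on
scales of mixed granularity, and 434 respondents giving paired
perception/expectation answers on the 7-term scale.

Planted structure and noise model
---------------------------------
Every cell starts from a *planted* true term on a canonical scale (the
7-term set).  An expert using a coarser scale sees the planted term mapped
by proportional index scaling, ``round_half_up(t * T_expert / T_canon)``.
Ordinal noise then perturbs the term by one step up or down (equal
probability, clipped to the scale) with probability ``noise_prob``, and
with probability ``interval_prob`` the answer widens to a two-term
interval — the minimal structure-preserving model of respondent hesitation;
nothing else about real raters (covariates, item non-response, acquiescence
bias) is modelled.

Generation is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .aggregation import Expert, ExpertRatings, SurveyResponses
from .fuzzy import round_half_up
from .hierarchy import IndicatorHierarchy
from .linguistic import DEFAULT_TERM_SETS, LinguisticTermSet, LinguisticValue

__all__ = [
    "SimulationSpec",
    "map_to_granularity",
    "generate_expert_panel",
    "generate_survey",
    "response_recovery_rate",
]

#: Questionnaire counts reported for the case study: 691 collected, 434 valid.
CASE_STUDY_COLLECTED = 691
CASE_STUDY_VALID = 434


def map_to_granularity(t: int, T_from: int, T_to: int) -> int:
    """Proportional index rescaling between scales, rounded half-up."""
    if not (0 <= t <= T_from):
        raise ValueError(f"term index {t} outside 0..{T_from}")
    return int(round_half_up(t * T_to / T_from, 0))


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to regenerate a panel + survey reproducibly.

    ``expert_granularities`` lists, per expert, the id of the term set that
    expert answers on; respondents all answer on ``respondent_set_id``.
    Planted maps give the true term index on the canonical scale.
    """

    seed: int
    planted_importance: Mapping[str, int]
    planted_P: Mapping[str, int]
    planted_E: Mapping[str, int]
    n_experts: int = 15
    n_respondents: int = 434
    expert_granularities: tuple[str, ...] = ()
    respondent_set_id: str = "termset-7"
    canonical_set_id: str = "termset-7"
    noise_prob: float = 0.1
    interval_prob: float = 0.05
    term_sets: Mapping[str, LinguisticTermSet] = field(
        default_factory=lambda: dict(DEFAULT_TERM_SETS)
    )

    def __post_init__(self) -> None:
        if self.n_experts < 1 or self.n_respondents < 1:
            raise ValueError("n_experts and n_respondents must be >= 1")
        if not (0.0 <= self.noise_prob <= 1.0 and 0.0 <= self.interval_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        grans = self.expert_granularities or ("termset-7",) * self.n_experts
        if len(grans) != self.n_experts:
            raise ValueError("expert_granularities length must equal n_experts")
        object.__setattr__(self, "expert_granularities", tuple(grans))
        for sid in (*self.expert_granularities, self.respondent_set_id, self.canonical_set_id):
            if sid not in self.term_sets:
                raise ValueError(f"unknown term set id {sid!r}")
        T_c = self.canonical_T
        for name, planted in (
            ("planted_importance", self.planted_importance),
            ("planted_P", self.planted_P),
            ("planted_E", self.planted_E),
        ):
            for iid, t in planted.items():
                if not 0 <= t <= T_c:
                    raise ValueError(
                        f"{name}[{iid!r}]={t} outside canonical scale 0..{T_c}"
                    )

    @property
    def canonical_T(self) -> int:
        return self.term_sets[self.canonical_set_id].T

    @classmethod
    def case_study(cls, seed: int) -> "SimulationSpec":
        """A spec shaped like the published study.

        15 equal-weight experts on mixed 7-/5-term scales rating the
        initial 24 indicators, with importances planted at each
        indicator's published similarity argmax; 434 respondents on the
        7-term scale over the optimized 19 indicators, with perception
        planted one term below (above) expectation where the published gap
        is negative (positive).
        """
        from .fixtures import (
            load_fixture,
            optimized_hierarchy,
            table3_trapezoids,
        )
        from .screening import SimilarityProfile

        ref = load_fixture("termset_7")
        importance = {
            iid: SimilarityProfile.compute(f, ref).argmax_term
            for iid, f in table3_trapezoids().items()
        }
        t6 = load_fixture("table6_subindicators")
        planted_P: dict[str, int] = {}
        planted_E: dict[str, int] = {}
        for row in t6.itertuples():
            if row.gap < 0:
                planted_P[row.indicator_id], planted_E[row.indicator_id] = 4, 5
            else:
                planted_P[row.indicator_id], planted_E[row.indicator_id] = 5, 4
        # Alternating scale choice emulates raters picking their own granularity.
        grans = tuple(
            "termset-7" if k % 2 == 0 else "termset-5" for k in range(15)
        )
        return cls(
            seed=seed,
            planted_importance=importance,
            planted_P=planted_P,
            planted_E=planted_E,
            expert_granularities=grans,
        )

    def with_seed(self, seed: int) -> "SimulationSpec":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_experts": self.n_experts,
            "n_respondents": self.n_respondents,
            "expert_granularities": list(self.expert_granularities),
            "respondent_set_id": self.respondent_set_id,
            "canonical_set_id": self.canonical_set_id,
            "noise_prob": self.noise_prob,
            "interval_prob": self.interval_prob,
            "planted_importance": dict(self.planted_importance),
            "planted_P": dict(self.planted_P),
            "planted_E": dict(self.planted_E),
            "term_sets": {sid: ts.to_dict() for sid, ts in self.term_sets.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationSpec":
        term_sets = {
            sid: LinguisticTermSet.from_dict(td)
            for sid, td in d.get("term_sets", {}).items()
        } or dict(DEFAULT_TERM_SETS)
        return cls(
            seed=int(d["seed"]),
            planted_importance=dict(d.get("planted_importance", {})),
            planted_P=dict(d.get("planted_P", {})),
            planted_E=dict(d.get("planted_E", {})),
            n_experts=int(d.get("n_experts", 15)),
            n_respondents=int(d.get("n_respondents", 434)),
            expert_granularities=tuple(d.get("expert_granularities", ())),
            respondent_set_id=d.get("respondent_set_id", "termset-7"),
            canonical_set_id=d.get("canonical_set_id", "termset-7"),
            noise_prob=float(d.get("noise_prob", 0.1)),
            interval_prob=float(d.get("interval_prob", 0.05)),
            term_sets=term_sets,
        )


def _noisy_value(
    rng: np.random.Generator,
    term_set: LinguisticTermSet,
    t: int,
    noise_prob: float,
    interval_prob: float,
) -> LinguisticValue:
    T = term_set.T
    if noise_prob > 0 and rng.random() < noise_prob:
        t = t + (1 if rng.random() < 0.5 else -1)
        t = min(max(t, 0), T)
    if interval_prob > 0 and rng.random() < interval_prob:
        if t < T:
            return LinguisticValue(term_set, t, t + 1)
        return LinguisticValue(term_set, t - 1, t)
    return LinguisticValue(term_set, t, t)


def generate_expert_panel(spec: SimulationSpec) -> ExpertRatings:
    """Equal-weight expert importance panel over the planted indicators."""
    rng = np.random.default_rng([spec.seed, 0])
    T_c = spec.canonical_T
    indicator_ids = tuple(spec.planted_importance.keys())
    experts = tuple(Expert(f"expert-{k + 1:02d}", 1.0) for k in range(spec.n_experts))
    cells: dict[tuple[str, str], LinguisticValue] = {}
    for expert, sid in zip(experts, spec.expert_granularities):
        ts = spec.term_sets[sid]
        for iid in indicator_ids:
            t = map_to_granularity(spec.planted_importance[iid], T_c, ts.T)
            cells[(expert.id, iid)] = _noisy_value(
                rng, ts, t, spec.noise_prob, spec.interval_prob
            )
    return ExpertRatings(experts=experts, indicator_ids=indicator_ids, cells=cells)


def generate_survey(spec: SimulationSpec) -> SurveyResponses:
    """Paired perception/expectation grids over the planted indicators."""
    if set(spec.planted_P.keys()) != set(spec.planted_E.keys()):
        raise ValueError("planted_P and planted_E must cover the same indicators")
    rng = np.random.default_rng([spec.seed, 1])
    T_c = spec.canonical_T
    ts = spec.term_sets[spec.respondent_set_id]
    indicator_ids = tuple(spec.planted_P.keys())
    respondent_ids = tuple(f"resp-{k + 1:04d}" for k in range(spec.n_respondents))
    perception: dict[tuple[str, str], LinguisticValue] = {}
    expectation: dict[tuple[str, str], LinguisticValue] = {}
    for rid in respondent_ids:
        for iid in indicator_ids:
            tp = map_to_granularity(spec.planted_P[iid], T_c, ts.T)
            te = map_to_granularity(spec.planted_E[iid], T_c, ts.T)
            perception[(rid, iid)] = _noisy_value(
                rng, ts, tp, spec.noise_prob, spec.interval_prob
            )
            expectation[(rid, iid)] = _noisy_value(
                rng, ts, te, spec.noise_prob, spec.interval_prob
            )
    return SurveyResponses(
        respondent_ids=respondent_ids,
        indicator_ids=indicator_ids,
        perception=perception,
        expectation=expectation,
    )


def response_recovery_rate(
    collected: int = CASE_STUDY_COLLECTED, valid: int = CASE_STUDY_VALID
) -> float:
    """Valid-questionnaire rate in percent, one decimal (434/691 -> 62.8).

    Questionnaire validity screening happens upstream of the method; it
    enters the analysis only as this reported count.
    """
    if collected < 1 or not 0 <= valid <= collected:
        raise ValueError("need 0 <= valid <= collected, collected >= 1")
    return round_half_up(100.0 * valid / collected, 1)
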