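"""Indicator hierarchies (dimensions × sub-indicators) and merge plans.

The evaluation index system is a two-level hierarchy: a handful of quality
dimensions, each holding an ordered list of sub-indicators.  Screening may
remove indicators outright; borderline ("review") indicators are merged by
an explicitly configured :class:`MergePlan` — merges encode expert
judgement and are never inferred from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Dimension",
    "Indicator",
    "IndicatorHierarchy",
    "MergeRule",
    "DimensionMergeRule",
    "MergePlan",
    "apply_plan",
]


@dataclass(frozen=True)
class Dimension:
    id: str
    name: str


@dataclass(frozen=True)
class Indicator:
    id: str
    name: str
    dimension_id: str


@dataclass(frozen=True)
class IndicatorHierarchy:
    dimensions: tuple[Dimension, ...]
    indicators: tuple[Indicator, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        object.__setattr__(self, "indicators", tuple(self.indicators))
        dim_ids = [d.id for d in self.dimensions]
        ind_ids = [i.id for i in self.indicators]
        if len(set(dim_ids)) != len(dim_ids):
            raise ValueError("dimension ids must be unique")
        if len(set(ind_ids)) != len(ind_ids):
            raise ValueError("indicator ids must be unique")
        known = set(dim_ids)
        for ind in self.indicators:
            if ind.dimension_id not in known:
                raise ValueError(
                    f"indicator {ind.id!r} references unknown dimension "
                    f"{ind.dimension_id!r}"
                )

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self.indicators)

    @property
    def dimension_ids(self) -> tuple[str, ...]:
        return tuple(d.id for d in self.dimensions)

    def indicator(self, indicator_id: str) -> Indicator:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise KeyError(indicator_id)

    def indicators_in(self, dimension_id: str) -> tuple[Indicator, ...]:
        if dimension_id not in self.dimension_ids:
            raise KeyError(dimension_id)
        return tuple(i for i in self.indicators if i.dimension_id == dimension_id)

    def to_dict(self) -> dict:
        return {
            "dimensions": [{"id": d.id, "name": d.name} for d in self.dimensions],
            "indicators": [
                {"id": i.id, "name": i.name, "dimension_id": i.dimension_id}
                for i in self.indicators
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IndicatorHierarchy":
        return cls(
            dimensions=tuple(Dimension(x["id"], x["name"]) for x in d["dimensions"]),
            indicators=tuple(
                Indicator(x["id"], x["name"], x["dimension_id"])
                for x in d["indicators"]
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "IndicatorHierarchy":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MergeRule:
    """Replace ``sources`` (>= 2 existing indicators) with ``target``."""

    sources: tuple[str, ...]
    target: Indicator

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if len(self.sources) < 1:
            raise ValueError("merge rule needs at least one source")
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("merge sources must be distinct")


@dataclass(frozen=True)
class DimensionMergeRule:
    sources: tuple[str, ...]
    target: Dimension

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if len(self.sources) < 1:
            raise ValueError("dimension merge rule needs at least one source")


@dataclass(frozen=True)
class MergePlan:
    indicator_merges: tuple[MergeRule, ...] = ()
    dimension_merges: tuple[DimensionMergeRule, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicator_merges", tuple(self.indicator_merges))
        object.__setattr__(self, "dimension_merges", tuple(self.dimension_merges))
        seen: set[str] = set()
        for rule in self.indicator_merges:
            overlap = seen.intersection(rule.sources)
            if overlap:
                raise ValueError(f"merge sources overlap across rules: {sorted(overlap)}")
            seen.update(rule.sources)

    def to_dict(self) -> dict:
        return {
            "indicator_merges": [
                {
                    "sources": list(r.sources),
                    "target": {
                        "id": r.target.id,
                        "name": r.target.name,
                        "dimension_id": r.target.dimension_id,
                    },
                }
                for r in self.indicator_merges
            ],
            "dimension_merges": [
                {
                    "sources": list(r.sources),
                    "target": {"id": r.target.id, "name": r.target.name},
                }
                for r in self.dimension_merges
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MergePlan":
        return cls(
            indicator_merges=tuple(
                MergeRule(
                    sources=tuple(r["sources"]),
                    target=Indicator(
                        r["target"]["id"],
                        r["target"]["name"],
                        r["target"]["dimension_id"],
                    ),
                )
                for r in d.get("indicator_merges", ())
            ),
            dimension_merges=tuple(
                DimensionMergeRule(
                    sources=tuple(r["sources"]),
                    target=Dimension(r["target"]["id"], r["target"]["name"]),
                )
                for r in d.get("dimension_merges", ())
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MergePlan":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _removed_ids(decisions) -> set[str]:
    """Accepts a mapping id -> decision (str or object with .decision) or an
    iterable of objects with .indicator_id/.decision."""
    removed: set[str] = set()
    if decisions is None:
        return removed
    if isinstance(decisions, Mapping):
        items = decisions.items()
        for iid, dec in items:
            label = dec if isinstance(dec, str) else getattr(dec, "decision")
            if label == "remove":
                removed.add(iid)
        return removed
    for dec in decisions:
        if getattr(dec, "decision") == "remove":
            removed.add(getattr(dec, "indicator_id"))
    return removed


def apply_plan(
    hierarchy: IndicatorHierarchy,
    decisions=None,
    plan: MergePlan | None = None,
) -> IndicatorHierarchy:
    """Drop removed indicators, then apply indicator and dimension merges.

    Ordering is deterministic: a merge target takes the position of its
    first source in the original indicator order, and a merged dimension
    takes the position of its first source dimension.  Referencing a
    removed or unknown indicator in a merge rule is an error.
    """
    plan = plan or MergePlan()
    removed = _removed_ids(decisions)
    known = set(hierarchy.indicator_ids)

    unknown_removed = removed - known
    if unknown_removed:
        raise ValueError(f"decisions reference unknown indicators: {sorted(unknown_removed)}")

    for rule in plan.indicator_merges:
        for src in rule.sources:
            if src not in known:
                raise ValueError(f"merge plan references unknown indicator {src!r}")
            if src in removed:
                raise ValueError(
                    f"merge plan references removed indicator {src!r}"
                )

    # Dimension remapping comes from dimension merges.
    dim_map: dict[str, str] = {}
    for rule in plan.dimension_merges:
        for src in rule.sources:
            if src not in hierarchy.dimension_ids:
                raise ValueError(f"merge plan references unknown dimension {src!r}")
            dim_map[src] = rule.target.id

    # New dimension list: target at the first source's position.
    new_dims: list[Dimension] = []
    emitted_dim_targets: set[str] = set()
    for dim in hierarchy.dimensions:
        if dim.id in dim_map:
            tgt_id = dim_map[dim.id]
            if tgt_id not in emitted_dim_targets:
                rule = next(
                    r for r in plan.dimension_merges if r.target.id == tgt_id
                )
                new_dims.append(rule.target)
                emitted_dim_targets.add(tgt_id)
        else:
            new_dims.append(dim)

    # New indicator list: skip removed, emit merge target at first source.
    rule_by_source = {
        src: rule for rule in plan.indicator_merges for src in rule.sources
    }
    new_inds: list[Indicator] = []
    emitted_targets: set[str] = set()
    for ind in hierarchy.indicators:
        if ind.id in removed:
            continue
        rule = rule_by_source.get(ind.id)
        if rule is None:
            new_inds.append(
                Indicator(ind.id, ind.name, dim_map.get(ind.dimension_id, ind.dimension_id))
            )
        elif rule.target.id not in emitted_targets:
            tgt = rule.target
            new_inds.append(
                Indicator(tgt.id, tgt.name, dim_map.get(tgt.dimension_id, tgt.dimension_id))
            )
            emitted_targets.add(tgt.id)
    return IndicatorHierarchy(tuple(new_dims), tuple(new_inds))
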