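"""Tabular I/O and run configuration.

CSV dialects (RFC-4180, header row required):

* ratings (long form): ``expert_id, indicator_id, set_id, m, n, weight`` —
  one row per expert × indicator, ``[m, n]`` the answer interval on the
  expert's own term set, ``weight`` a crisp nonnegative expert weight.
* survey (long form): ``respondent_id, indicator_id, p_set_id, p_m, p_n,
  e_set_id, e_m, e_n`` — paired perception/expectation answers.

Configuration files are YAML or JSON; every key is optional and falls back
to the packaged defaults (preset term sets, initial hierarchy, default
zones, 4/3-decimal report rounding, strict missing-data policy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .aggregation import Expert, ExpertRatings, SurveyResponses
from .hierarchy import IndicatorHierarchy, MergePlan
from .linguistic import DEFAULT_TERM_SETS, LinguisticTermSet, LinguisticValue
from .screening import Zones

__all__ = [
    "read_ratings_csv",
    "write_ratings_csv",
    "read_survey_csv",
    "write_survey_csv",
    "RunConfig",
]


class ParseError(ValueError):
    """Input file failed validation; message carries the offending row."""


def _term_set(
    set_id: str, term_sets: Mapping[str, LinguisticTermSet], path: Path, row: int
) -> LinguisticTermSet:
    try:
        return term_sets[set_id]
    except KeyError:
        raise ParseError(
            f"{path}, data row {row}: unknown term set id {set_id!r}"
        ) from None


def _value(
    term_sets: Mapping[str, LinguisticTermSet],
    set_id: str,
    m: int,
    n: int,
    path: Path,
    row: int,
) -> LinguisticValue:
    ts = _term_set(set_id, term_sets, path, row)
    try:
        return LinguisticValue(ts, int(m), int(n))
    except ValueError as exc:
        raise ParseError(f"{path}, data row {row}: {exc}") from None


def read_ratings_csv(
    path: str | Path,
    term_sets: Mapping[str, LinguisticTermSet] | None = None,
) -> ExpertRatings:
    path = Path(path)
    term_sets = term_sets or DEFAULT_TERM_SETS
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty ratings file") from None
    required = {"expert_id", "indicator_id", "set_id", "m", "n", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: ratings file has no data rows")

    experts: dict[str, Expert] = {}
    indicator_ids: list[str] = []
    cells: dict[tuple[str, str], LinguisticValue] = {}
    for i, row in enumerate(df.itertuples(), start=1):
        eid, iid = str(row.expert_id), str(row.indicator_id)
        w = float(row.weight)
        if eid in experts and experts[eid].weight != w:
            raise ParseError(
                f"{path}, data row {i}: expert {eid!r} has inconsistent weights"
            )
        experts.setdefault(eid, Expert(eid, w))
        if iid not in indicator_ids:
            indicator_ids.append(iid)
        cells[(eid, iid)] = _value(term_sets, str(row.set_id), row.m, row.n, path, i)
    return ExpertRatings(
        experts=tuple(experts.values()),
        indicator_ids=tuple(indicator_ids),
        cells=cells,
    )


def write_ratings_csv(ratings: ExpertRatings, path: str | Path) -> None:
    rows = []
    for expert in ratings.experts:
        for iid in ratings.indicator_ids:
            val = ratings.cell(expert.id, iid)
            rows.append(
                {
                    "expert_id": expert.id,
                    "indicator_id": iid,
                    "set_id": val.set_id,
                    "m": val.m,
                    "n": val.n,
                    "weight": float(expert.weight),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survey_csv(
    path: str | Path,
    term_sets: Mapping[str, LinguisticTermSet] | None = None,
) -> SurveyResponses:
    path = Path(path)
    term_sets = term_sets or DEFAULT_TERM_SETS
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty survey file") from None
    required = {
        "respondent_id", "indicator_id",
        "p_set_id", "p_m", "p_n", "e_set_id", "e_m", "e_n",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: survey file has no data rows")

    respondent_ids: list[str] = []
    indicator_ids: list[str] = []
    perception: dict[tuple[str, str], LinguisticValue] = {}
    expectation: dict[tuple[str, str], LinguisticValue] = {}
    for i, row in enumerate(df.itertuples(), start=1):
        rid, iid = str(row.respondent_id), str(row.indicator_id)
        if rid not in respondent_ids:
            respondent_ids.append(rid)
        if iid not in indicator_ids:
            indicator_ids.append(iid)
        perception[(rid, iid)] = _value(
            term_sets, str(row.p_set_id), row.p_m, row.p_n, path, i
        )
        expectation[(rid, iid)] = _value(
            term_sets, str(row.e_set_id), row.e_m, row.e_n, path, i
        )
    return SurveyResponses(
        respondent_ids=tuple(respondent_ids),
        indicator_ids=tuple(indicator_ids),
        perception=perception,
        expectation=expectation,
    )


def write_survey_csv(responses: SurveyResponses, path: str | Path) -> None:
    rows = []
    for rid in responses.respondent_ids:
        for iid in responses.indicator_ids:
            p = responses.perception[(rid, iid)]
            e = responses.expectation[(rid, iid)]
            rows.append(
                {
                    "respondent_id": rid,
                    "indicator_id": iid,
                    "p_set_id": p.set_id, "p_m": p.m, "p_n": p.n,
                    "e_set_id": e.set_id, "e_m": e.m, "e_n": e.n,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved run configuration with packaged defaults."""

    term_sets: dict[str, LinguisticTermSet] = field(
        default_factory=lambda: dict(DEFAULT_TERM_SETS)
    )
    hierarchy: IndicatorHierarchy | None = None
    zones: Zones | None = None
    merge_plan: MergePlan | None = None
    similarity_decimals: int = 4
    gap_decimals: int = 3
    missing: str = "error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.similarity_decimals < 0 or self.gap_decimals < 0:
            raise ValueError("rounding decimals must be >= 0")
        if self.missing not in ("error", "drop"):
            raise ValueError(f"unknown missing-data policy {self.missing!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        ) or {}
        base = path.parent

        term_sets = dict(DEFAULT_TERM_SETS)
        for td in raw.get("term_sets", []):
            ts = LinguisticTermSet.from_dict(td)
            term_sets[ts.id] = ts

        hierarchy = None
        if raw.get("hierarchy"):
            hpath = base / raw["hierarchy"]
            if not hpath.exists():
                raise ParseError(f"{path}: hierarchy file {hpath} does not exist")
            hierarchy = IndicatorHierarchy.from_json(hpath)

        merge_plan = None
        if raw.get("merge_plan"):
            mpath = base / raw["merge_plan"]
            if not mpath.exists():
                raise ParseError(f"{path}: merge plan file {mpath} does not exist")
            merge_plan = MergePlan.from_json(mpath)

        zones = None
        if raw.get("zones"):
            z = raw["zones"]
            zones = Zones(
                remove=frozenset(z.get("remove", [])),
                review=frozenset(z.get("review", [])),
                keep=frozenset(z.get("keep", [])),
            )

        rounding = raw.get("rounding", {})
        return cls(
            term_sets=term_sets,
            hierarchy=hierarchy,
            zones=zones,
            merge_plan=merge_plan,
            similarity_decimals=int(rounding.get("similarity", 4)),
            gap_decimals=int(rounding.get("gaps", 3)),
            missing=raw.get("missing", "error"),
            seed=int(raw.get("seed", 0)),
        )
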