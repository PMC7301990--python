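"""Packaged fixtures transcribing the published case-study tables.

Shipped as plain-text data inside the package:

* ``termset_5`` / ``termset_7`` — the two preset rating scales;
* ``hierarchy_initial`` — the initial 24-indicator / 5-dimension system;
* ``table3_expert_trapezoids`` — panel-mean importance trapezoids for the
  24 initial indicators (two obvious transcription typos corrected, see
  :data:`TYPO_CORRECTIONS`);
* ``table5_dimensions`` / ``table6_subindicators`` — the published AP/AE
  trapezoids and crisp P/E/gap columns for the optimized 4-dimension /
  19-indicator system, as printed;
* ``paper_merge_plan`` — the expert merge plan that turns the screened
  24-indicator system into the optimized 19-indicator one.

Sub-indicator names in the published gap table are only partially stated in
the surrounding text; rows whose name is inferred from position carry
``name_source == "positional"`` in the CSV.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .fuzzy import TrapezoidalFuzzyNumber
from .hierarchy import Dimension, Indicator, IndicatorHierarchy, MergePlan
from .linguistic import LinguisticTermSet

__all__ = [
    "FIXTURE_NAMES",
    "TYPO_CORRECTIONS",
    "load_fixture",
    "table3_trapezoids",
    "optimized_hierarchy",
    "gap_results_from_table6",
]

#: Corrections applied while transcribing the expert-mean table.
TYPO_CORRECTIONS = {
    "network-service-provider": "second component printed '0301', read as 0.301",
    "regional-hospital-level": "printed '0.864.0.932', read as 0.864, 0.932",
}

FIXTURE_NAMES = (
    "termset_5",
    "termset_7",
    "hierarchy_initial",
    "table3_expert_trapezoids",
    "table5_dimensions",
    "table6_subindicators",
    "paper_merge_plan",
)


def _data(name: str):
    return resources.files("servgap").joinpath("data", name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_data(name)) as path:
        return pd.read_csv(path)


def _read_json(name: str):
    return json.loads(_data(name).read_text())


def load_fixture(name: str):
    """Load a packaged fixture by name (see :data:`FIXTURE_NAMES`)."""
    if name in ("termset_5", "termset_7"):
        sets = _read_json("termsets.json")
        return LinguisticTermSet.from_dict(sets[name.replace("_", "-")])
    if name == "hierarchy_initial":
        return IndicatorHierarchy.from_dict(_read_json("hierarchy_initial.json"))
    if name == "table3_expert_trapezoids":
        return _read_csv("table3_expert_trapezoids.csv")
    if name == "table5_dimensions":
        return _read_csv("table5_dimensions.csv")
    if name == "table6_subindicators":
        return _read_csv("table6_subindicators.csv")
    if name == "paper_merge_plan":
        return MergePlan.from_dict(_read_json("merge_plan.json"))
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )


def table3_trapezoids() -> dict[str, TrapezoidalFuzzyNumber]:
    """Panel-mean importance trapezoid per initial indicator id."""
    df = load_fixture("table3_expert_trapezoids")
    return {
        row.indicator_id: TrapezoidalFuzzyNumber(row.a, row.b, row.c, row.d)
        for row in df.itertuples()
    }


def optimized_hierarchy() -> IndicatorHierarchy:
    """The published optimized 19-indicator / 4-dimension hierarchy."""
    t5 = load_fixture("table5_dimensions")
    t6 = load_fixture("table6_subindicators")
    code_to_dim = dict(zip(t5.code, t5.dimension_id))
    dims = tuple(
        Dimension(row.dimension_id, row.name) for row in t5.itertuples()
    )
    inds = tuple(
        Indicator(row.indicator_id, row.name, code_to_dim[row.dimension_code])
        for row in t6.itertuples()
    )
    return IndicatorHierarchy(dims, inds)


def gap_results_from_table6():
    """Gap report rebuilt from the printed sub-indicator AP/AE trapezoids.

    Crisp P/E/gap columns and the dimension roll-up are recomputed by the
    package; only the trapezoids are taken as printed.
    """
    from .gaps import GapResults

    t6 = load_fixture("table6_subindicators")
    hier = optimized_hierarchy()
    ap = {
        row.indicator_id: TrapezoidalFuzzyNumber(
            row.ap_a, row.ap_b, row.ap_c, row.ap_d
        )
        for row in t6.itertuples()
    }
    ae = {
        row.indicator_id: TrapezoidalFuzzyNumber(
            row.ae_a, row.ae_b, row.ae_c, row.ae_d
        )
        for row in t6.itertuples()
    }
    return GapResults.from_aggregates(hier, ap, ae)
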