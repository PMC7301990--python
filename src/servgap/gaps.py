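"""Perception–expectation gap analysis over an indicator hierarchy.

For every indicator the respondent survey yields a mean perception
trapezoid AP and a mean expectation trapezoid AE; their defuzzified crisp
values P and E give the gap

    GAP = P - E,

negative when the service falls short of what respondents expected.  By
linearity of the defuzzifier this equals the defuzzified componentwise
difference of the trapezoids, so the crisp route loses nothing.
Dimension-level rows are the unweighted componentwise means of their
sub-indicators' AP/AE trapezoids.

Key factors — the indicators most in need of improvement — are ranked by
ascending *signed* gap: a large positive gap is a strength, not a problem,
so ranking by magnitude would be wrong.  Ranking operates on gaps at
reporting precision (3 decimals, half-up) with the indicator id as a
deterministic tie-break, so indicators whose reported gaps are
indistinguishable order reproducibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .aggregation import SurveyResponses, survey_means_all
from .fuzzy import TrapezoidalFuzzyNumber, defuzzify, mean_of, round_half_up
from .hierarchy import IndicatorHierarchy

__all__ = ["GapRow", "GapAnalysis", "GapResults"]

_GAP_DECIMALS = 3


@dataclass(frozen=True)
class GapRow:
    """AP/AE trapezoids and their crisp P, E, gap for one row."""

    id: str
    name: str
    ap: TrapezoidalFuzzyNumber
    ae: TrapezoidalFuzzyNumber

    @property
    def p(self) -> float:
        return defuzzify(self.ap)

    @property
    def e(self) -> float:
        return defuzzify(self.ae)

    @property
    def gap(self) -> float:
        return self.p - self.e


class GapAnalysis:
    """Model: survey responses + hierarchy -> fitted gap report.

    Parameters
    ----------
    responses
        Paired perception/expectation grids over the hierarchy's indicators.
    hierarchy
        The (optimized) indicator hierarchy the survey covers.
    missing
        Missing-cell policy forwarded to the aggregation step:
        ``"error"`` (default) or ``"drop"``.
    """

    def __init__(
        self,
        responses: SurveyResponses,
        hierarchy: IndicatorHierarchy,
        *,
        missing: str = "error",
    ) -> None:
        lacking = set(hierarchy.indicator_ids) - set(responses.indicator_ids)
        if lacking:
            raise ValueError(f"survey lacks indicators: {sorted(lacking)}")
        self.responses = responses
        self.hierarchy = hierarchy
        self.missing = missing

    def fit(self) -> "GapResults":
        means = survey_means_all(self.responses, missing=self.missing)
        ap = {iid: means[iid][0] for iid in self.hierarchy.indicator_ids}
        ae = {iid: means[iid][1] for iid in self.hierarchy.indicator_ids}
        return GapResults.from_aggregates(self.hierarchy, ap, ae)


class GapResults:
    """Fitted gap report: per-indicator and per-dimension rows.

    Can also be constructed directly from pre-aggregated AP/AE trapezoids
    (e.g. transcribed report tables) via :meth:`from_aggregates`, bypassing
    the raw survey.
    """

    def __init__(
        self,
        hierarchy: IndicatorHierarchy,
        indicator_rows: Sequence[GapRow],
        dimension_rows: Sequence[GapRow],
    ) -> None:
        self.hierarchy = hierarchy
        self.indicator_rows = tuple(indicator_rows)
        self.dimension_rows = tuple(dimension_rows)
        self._by_id = {r.id: r for r in self.indicator_rows}
        self._dim_by_id = {r.id: r for r in self.dimension_rows}

    @classmethod
    def from_aggregates(
        cls,
        hierarchy: IndicatorHierarchy,
        ap: Mapping[str, TrapezoidalFuzzyNumber],
        ae: Mapping[str, TrapezoidalFuzzyNumber],
    ) -> "GapResults":
        """Build the report from per-indicator AP/AE trapezoids.

        Dimension rows are recomputed as unweighted componentwise means of
        the sub-indicator trapezoids; every dimension must hold at least
        one indicator.
        """
        ind_rows = [
            GapRow(ind.id, ind.name, ap[ind.id], ae[ind.id])
            for ind in hierarchy.indicators
        ]
        dim_rows = []
        for dim in hierarchy.dimensions:
            members = hierarchy.indicators_in(dim.id)
            if not members:
                raise ValueError(f"dimension {dim.id!r} has no indicators")
            dim_rows.append(
                GapRow(
                    dim.id,
                    dim.name,
                    mean_of([ap[i.id] for i in members]),
                    mean_of([ae[i.id] for i in members]),
                )
            )
        return cls(hierarchy, ind_rows, dim_rows)

    def row(self, row_id: str) -> GapRow:
        if row_id in self._by_id:
            return self._by_id[row_id]
        return self._dim_by_id[row_id]

    @staticmethod
    def _frame(rows: Sequence[GapRow]) -> pd.DataFrame:
        data = []
        for r in rows:
            data.append(
                {
                    "id": r.id,
                    "name": r.name,
                    "ap_a": r.ap.a, "ap_b": r.ap.b, "ap_c": r.ap.c, "ap_d": r.ap.d,
                    "ae_a": r.ae.a, "ae_b": r.ae.b, "ae_c": r.ae.c, "ae_d": r.ae.d,
                    "P": r.p,
                    "E": r.e,
                    "gap": r.gap,
                }
            )
        return pd.DataFrame(data).set_index("id")

    def indicator_table(self) -> pd.DataFrame:
        """Full-precision per-indicator AP/AE/P/E/gap table."""
        return self._frame(self.indicator_rows)

    def dimension_table(self) -> pd.DataFrame:
        """Full-precision per-dimension roll-up table."""
        return self._frame(self.dimension_rows)

    def rank_key_factors(
        self, k: int, *, level: str = "indicator"
    ) -> list[tuple[str, float]]:
        """Top-``k`` rows by most negative reported gap.

        Returns ``(id, gap rounded to 3 decimals)`` pairs sorted by
        ascending rounded gap, ties broken by id.  ``k`` larger than the
        row count returns all rows with a warning.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        rows = self.indicator_rows if level == "indicator" else self.dimension_rows
        if k > len(rows):
            warnings.warn(
                f"k={k} exceeds the {len(rows)} available rows; returning all",
                stacklevel=2,
            )
            k = len(rows)
        ranked = sorted(
            ((r.id, round_half_up(r.gap, _GAP_DECIMALS)) for r in rows),
            key=lambda item: (item[1], item[0]),
        )
        return ranked[:k]

    def radar_data(self) -> pd.DataFrame:
        """Plain per-axis P and E series (for radar-style charts)."""
        rows = list(self.dimension_rows) + list(self.indicator_rows)
        return pd.DataFrame(
            {
                "axis": [r.id for r in rows],
                "level": ["dimension"] * len(self.dimension_rows)
                + ["indicator"] * len(self.indicator_rows),
                "P": [r.p for r in rows],
                "E": [r.e for r in rows],
            }
        ).set_index("axis")

    def summary(self, decimals: int = _GAP_DECIMALS, top_k: int = 5) -> str:
        def rounded(df: pd.DataFrame) -> pd.DataFrame:
            out = df.copy()
            for col in out.columns:
                if col != "name":
                    out[col] = out[col].map(lambda v: round_half_up(v, decimals))
            return out

        k = min(top_k, len(self.indicator_rows))
        key = self.rank_key_factors(k)
        lines = [
            "Service-quality gap analysis",
            f"  respondents aggregated per indicator; "
            f"{len(self.indicator_rows)} indicators in "
            f"{len(self.dimension_rows)} dimensions",
            "",
            "Dimensions:",
            rounded(self.dimension_table()).to_string(),
            "",
            "Sub-indicators:",
            rounded(self.indicator_table()).to_string(),
            "",
            f"Key factors (most negative gaps, k={k}): "
            + ", ".join(f"{iid} ({gap:+.3f})" for iid, gap in key),
        ]
        return "\n".join(lines)
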