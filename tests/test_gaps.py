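"""Perception-expectation gap computation, roll-up and key-factor ranking."""

import dataclasses

import numpy as np
import pytest

from servgap import fixtures
from servgap.fuzzy import TrapezoidalFuzzyNumber, defuzzify, round_half_up, subtract
from servgap.gaps import GapAnalysis, GapResults
from servgap.hierarchy import Dimension, Indicator, IndicatorHierarchy
from servgap.linguistic import TERMSET_7, LinguisticValue
from servgap.aggregation import SurveyResponses

TFN = TrapezoidalFuzzyNumber


@pytest.fixture(scope="module")
def table6_results():
    return fixtures.gap_results_from_table6()


def tiny_hierarchy(n_ind=2):
    return IndicatorHierarchy(
        dimensions=(Dimension("d1", "D1"),),
        indicators=tuple(Indicator(f"i{k}", f"I{k}", "d1") for k in range(n_ind)),
    )


def make_survey(p_terms_by_ind, e_terms_by_ind):
    inds = tuple(p_terms_by_ind)
    n = len(next(iter(p_terms_by_ind.values())))
    rids = tuple(f"r{k}" for k in range(n))
    P, E = {}, {}
    for iid in inds:
        for r, (tp, te) in zip(rids, zip(p_terms_by_ind[iid], e_terms_by_ind[iid])):
            P[(r, iid)] = LinguisticValue(TERMSET_7, tp, tp)
            E[(r, iid)] = LinguisticValue(TERMSET_7, te, te)
    return SurveyResponses(rids, inds, P, E)


class TestIndicatorGaps:
    @pytest.mark.parametrize(
        "ap,ae,p,e,gap",
        [
            ((0.560, 0.637, 0.713, 0.790), (0.590, 0.667, 0.744, 0.821),
             0.675, 0.706, -0.031),
            ((0.626, 0.703, 0.780, 0.857), (0.589, 0.666, 0.743, 0.820),
             0.742, 0.705, 0.037),
        ],
    )
    def test_published_rows(self, ap, ae, p, e, gap):
        hier = tiny_hierarchy(1)
        res = GapResults.from_aggregates(hier, {"i0": TFN(*ap)}, {"i0": TFN(*ae)})
        row = res.indicator_rows[0]
        assert round_half_up(row.p, 3) == p
        assert round_half_up(row.e, 3) == e
        assert round_half_up(row.gap, 3) == gap

    def test_equal_perception_expectation_zero_gap(self):
        s = make_survey({"i0": [4, 5, 3], "i1": [2, 2, 2]},
                        {"i0": [4, 5, 3], "i1": [2, 2, 2]})
        res = GapAnalysis(s, tiny_hierarchy(2)).fit()
        for row in res.indicator_rows:
            assert row.gap == pytest.approx(0.0, abs=1e-12)

    def test_crisp_gap_equals_defuzzified_fuzzy_difference(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ap = TFN(*sorted(rng.uniform(0, 1, 4)))
            ae = TFN(*sorted(rng.uniform(0, 1, 4)))
            assert defuzzify(subtract(ap, ae)) == pytest.approx(
                defuzzify(ap) - defuzzify(ae), abs=1e-12
            )

    def test_perception_shift_up_never_decreases_gaps(self):
        p = {"i0": [3, 4, 5, 2], "i1": [1, 2, 0, 3]}
        e = {"i0": [5, 5, 5, 5], "i1": [4, 4, 4, 4]}
        base = GapAnalysis(make_survey(p, e), tiny_hierarchy(2)).fit()
        shifted_p = {k: [min(t + 1, 6) for t in v] for k, v in p.items()}
        shifted = GapAnalysis(make_survey(shifted_p, e), tiny_hierarchy(2)).fit()
        for b, s in zip(base.indicator_rows, shifted.indicator_rows):
            assert s.gap >= b.gap - 1e-12


class TestDimensionRollup:
    def test_published_dimension_c1(self, table6_results):
        row = table6_results.row("system-quality")
        assert row.ap.as_tuple() == pytest.approx(
            (0.607, 0.684, 0.761, 0.838), abs=1.5e-3
        )
        assert round_half_up(row.p, 3) == 0.723

    def test_published_dimension_c2_first_component(self, table6_results):
        row = table6_results.row("structure-quality")
        assert row.ap.a == pytest.approx(0.581, abs=1e-3)
        assert round_half_up(row.gap, 3) == -0.019

    def test_single_indicator_dimension_is_identity(self):
        hier = tiny_hierarchy(1)
        ap = {"i0": TFN(0.1, 0.2, 0.3, 0.4)}
        ae = {"i0": TFN(0.2, 0.3, 0.4, 0.5)}
        res = GapResults.from_aggregates(hier, ap, ae)
        assert res.dimension_rows[0].ap == ap["i0"]
        assert res.dimension_rows[0].gap == pytest.approx(
            res.indicator_rows[0].gap
        )

    def test_empty_dimension_rejected(self):
        hier = IndicatorHierarchy(
            dimensions=(Dimension("d1", "D1"), Dimension("d2", "D2")),
            indicators=(Indicator("i0", "I0", "d1"),),
        )
        with pytest.raises(ValueError, match="no indicators"):
            GapResults.from_aggregates(
                hier, {"i0": TFN(0, 0, 0, 0)}, {"i0": TFN(0, 0, 0, 0)}
            )


class TestRanking:
    def test_published_key_factors(self, table6_results):
        top = table6_results.rank_key_factors(5)
        ids = [iid for iid, _ in top]
        # the two worst gaps tie at -0.031 once rounded to report precision
        assert set(ids[:2]) == {"turnover-rates", "operators-attitude"}
        assert ids[2:] == ["consultation-duration", "charges", "experts-attitude"]
        assert [g for _, g in top] == [-0.031, -0.031, -0.029, -0.026, -0.025]

    def test_published_worst_dimension(self, table6_results):
        top = table6_results.rank_key_factors(1, level="dimension")
        assert top == [("structure-quality", -0.019)]

    def test_all_equal_gaps_rank_by_id(self):
        hier = tiny_hierarchy(3)
        ap = {f"i{k}": TFN(0.4, 0.5, 0.6, 0.7) for k in range(3)}
        ae = {f"i{k}": TFN(0.5, 0.6, 0.7, 0.8) for k in range(3)}
        res = GapResults.from_aggregates(hier, ap, ae)
        assert [iid for iid, _ in res.rank_key_factors(2)] == ["i0", "i1"]

    def test_k_exceeding_rows_warns_and_returns_all(self, table6_results):
        with pytest.warns(UserWarning, match="returning all"):
            out = table6_results.rank_key_factors(99)
        assert len(out) == 19

    def test_k_below_one_rejected(self, table6_results):
        with pytest.raises(ValueError):
            table6_results.rank_key_factors(0)


class TestReporting:
    def test_tables_and_summary_shapes(self, table6_results):
        ind = table6_results.indicator_table()
        dim = table6_results.dimension_table()
        assert ind.shape == (19, 12)
        assert dim.shape == (4, 12)
        radar = table6_results.radar_data()
        assert set(radar["level"]) == {"dimension", "indicator"}
        text = table6_results.summary()
        assert "Key factors" in text and "structure-quality" in text

    def test_model_requires_survey_coverage(self):
        s = make_survey({"i0": [4]}, {"i0": [4]})
        with pytest.raises(ValueError, match="lacks indicators"):
            GapAnalysis(s, tiny_hierarchy(2))
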