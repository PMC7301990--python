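"""Similarity profiles, screening decisions and hierarchy optimization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from servgap import fixtures
from servgap.aggregation import Expert, ExpertRatings
from servgap.fuzzy import TrapezoidalFuzzyNumber, mean_of
from servgap.hierarchy import MergePlan, apply_plan
from servgap.linguistic import TERMSET_7, LinguisticValue
from servgap.screening import (
    ImportanceScreening,
    SimilarityProfile,
    Zones,
    decide,
    similarity,
)

TFN = TrapezoidalFuzzyNumber

unit_tuples = (
    st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4)
    .map(sorted)
    .map(lambda v: TFN(*v))
)


class TestSimilarity:
    def test_published_cell_first_indicator(self, termset_7):
        y = similarity(TFN(0.206, 0.301, 0.431, 0.527), termset_7.encode(2))
        assert y == pytest.approx(0.9641, abs=5e-4)

    def test_published_cell_expert_level(self, termset_7):
        y = similarity(TFN(0.810, 0.905, 1.000, 1.000), termset_7.encode(6))
        assert y == pytest.approx(0.9864, abs=5e-4)

    def test_self_similarity_is_one(self):
        A = TFN(0.2, 0.3, 0.5, 0.7)
        assert similarity(A, A) == 1.0

    def test_warns_outside_unit_scale(self):
        with pytest.warns(UserWarning, match="not normalized"):
            similarity(TFN(0, 1, 2, 3), TFN(0, 0.5, 0.5, 1))

    @given(unit_tuples, unit_tuples)
    def test_symmetric_and_bounded(self, A, B):
        assert similarity(A, B) == pytest.approx(similarity(B, A), abs=1e-12)
        assert 0.0 <= similarity(A, B) <= 1.0 + 1e-12

    @given(unit_tuples, unit_tuples, unit_tuples)
    def test_one_minus_similarity_is_a_metric(self, A, B, C):
        d = lambda x, y: 1.0 - similarity(x, y)
        assert d(A, A) == pytest.approx(0.0, abs=1e-12)
        assert d(A, B) >= -1e-12
        assert d(A, C) <= d(A, B) + d(B, C) + 1e-12

    def test_identity_of_indiscernibles(self):
        A = TFN(0.1, 0.2, 0.3, 0.4)
        B = TFN(0.1, 0.2, 0.3, 0.5)
        assert similarity(A, B) < 1.0

    def test_monotone_in_single_component_distance(self, termset_7):
        M = termset_7.encode(3)
        base = list(M.as_tuple())
        prev = 1.0
        for shift in (0.02, 0.05, 0.1, 0.2):
            moved = TFN(base[0], base[1], base[2], min(base[3] + shift, 1.0))
            y = similarity(moved, M)
            assert y <= prev + 1e-12
            prev = y


class TestProfileAndDecide:
    def test_published_argmax_appointment_channel(self, termset_7):
        prof = SimilarityProfile.compute(
            TFN(0.226, 0.321, 0.462, 0.557), termset_7, "appointment-channel"
        )
        assert prof.argmax_term == 2
        assert prof.similarities[2] == pytest.approx(0.9523, abs=5e-4)

    def test_exact_reference_term_profiles_at_one(self, termset_7):
        prof = SimilarityProfile.compute(termset_7.encode(4), termset_7)
        assert prof.argmax_term == 4
        assert prof.similarities[4] == pytest.approx(1.0)
        assert not prof.tie

    def test_constructed_midpoint_ties(self, termset_7):
        m2, m3 = termset_7.encode(2), termset_7.encode(3)
        mid = mean_of([m2, m3])
        prof = SimilarityProfile.compute(mid, termset_7)
        assert prof.tie
        assert decide(prof, Zones.default_for(6)).decision == "review"

    def test_zone_decisions(self, table3, termset_7):
        zones = Zones.default_for(6)
        dec = {
            iid: decide(SimilarityProfile.compute(f, termset_7, iid), zones)
            for iid, f in table3.items()
        }
        assert dec["network-service-provider"].decision == "remove"
        assert dec["expert-level"].decision == "keep"
        assert dec["process-convenience"].decision == "review"

    def test_decide_depends_only_on_argmax(self):
        sims = (0.1, 0.4, 0.2, 0.9, 0.5, 0.3, 0.2)
        prof = SimilarityProfile("x", sims, 3, False)
        squashed = tuple(s**3 for s in sims)  # strictly monotone transform
        prof2 = SimilarityProfile("x", squashed, int(np.argmax(squashed)), False)
        zones = Zones.default_for(6)
        assert decide(prof, zones).decision == decide(prof2, zones).decision

    def test_default_zones_partition(self):
        z = Zones.default_for(6)
        assert z.remove == {0, 1, 2} and z.review == {3} and z.keep == {4, 5, 6}
        z.validate_for(6)
        with pytest.raises(ValueError):
            Zones(remove={0, 1}, review={1}, keep={2})  # overlap
        with pytest.raises(ValueError):
            Zones(remove={0}, review=set(), keep={1}).validate_for(2)  # gap


class TestTableReproduction:
    def test_similarity_table_and_argmax_reproduce_print(
        self, table3, table4_printed, termset_7
    ):
        """All 168 published cells within transcription precision (printed
        panel means carry only 3 decimals), and every argmax column matches."""
        for iid, f in table3.items():
            prof = SimilarityProfile.compute(f, termset_7, iid)
            printed = table4_printed.loc[iid]
            assert prof.argmax_term == printed["argmax_term"]
            for t in range(7):
                assert prof.similarities[t] == pytest.approx(
                    printed[f"s{t}"], abs=1e-3
                )


class TestModelResults:
    def test_fit_on_synthetic_zero_noise_panel(self, initial_hierarchy):
        from servgap.simulate import SimulationSpec, generate_expert_panel
        import dataclasses

        spec = dataclasses.replace(
            SimulationSpec.case_study(0), noise_prob=0.0, interval_prob=0.0,
            expert_granularities=("termset-7",) * 15,
        )
        panel = generate_expert_panel(spec)
        res = ImportanceScreening(panel, initial_hierarchy).fit()
        for iid, planted in spec.planted_importance.items():
            assert res.profiles[iid].argmax_term == planted
        assert set(res.removed_ids) == {
            "network-service-provider", "appointment-channel"
        }
        df = res.similarity_table(4)
        assert df.shape == (24, 7)
        assert "decisions: keep=" in res.summary()

    def test_apply_plan_counts(self, initial_hierarchy, table3, merge_plan, termset_7):
        zones = Zones.default_for(6)
        decisions = {
            iid: decide(SimilarityProfile.compute(f, termset_7, iid), zones)
            for iid, f in table3.items()
        }
        opt = apply_plan(initial_hierarchy, decisions, merge_plan)
        assert opt.n_indicators == 19
        assert opt.n_dimensions == 4
        assert opt.indicator_ids == fixtures.optimized_hierarchy().indicator_ids

    def test_apply_plan_identity_and_pure_removals(self, initial_hierarchy):
        assert apply_plan(initial_hierarchy) == initial_hierarchy
        removed = {"network-service-provider": "remove", "appointment-channel": "remove"}
        out = apply_plan(initial_hierarchy, removed)
        assert out.n_indicators == 22
        assert out.n_dimensions == 5

    def test_apply_plan_rejects_removed_or_unknown_sources(self, initial_hierarchy):
        plan = MergePlan.from_dict(
            {
                "indicator_merges": [
                    {
                        "sources": ["appointment-channel", "waiting-time"],
                        "target": {
                            "id": "x", "name": "X",
                            "dimension_id": "interaction-quality",
                        },
                    }
                ]
            }
        )
        with pytest.raises(ValueError, match="removed"):
            apply_plan(initial_hierarchy, {"appointment-channel": "remove"}, plan)
        bad = MergePlan.from_dict(
            {
                "indicator_merges": [
                    {
                        "sources": ["no-such-indicator"],
                        "target": {
                            "id": "x", "name": "X",
                            "dimension_id": "interaction-quality",
                        },
                    }
                ]
            }
        )
        with pytest.raises(ValueError, match="unknown"):
            apply_plan(initial_hierarchy, None, bad)

    def test_overlapping_merge_sources_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MergePlan.from_dict(
                {
                    "indicator_merges": [
                        {"sources": ["a", "b"],
                         "target": {"id": "t1", "name": "T1", "dimension_id": "d"}},
                        {"sources": ["b", "c"],
                         "target": {"id": "t2", "name": "T2", "dimension_id": "d"}},
                    ]
                }
            )
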