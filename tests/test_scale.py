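"""The 8-item scale: default definition, scoring, classification, persistence."""

import itertools

import pytest
from hypothesis import given, strategies as st

from strokescale.cohort import Outcome
from strokescale.errors import ScaleError, ScoringError
from strokescale.scale import (
    ScaleDefinition,
    classify,
    default_scale,
    enumerate_totals,
    load_scale,
    packaged_default_scale,
    save_scale,
    score_patient,
)

from conftest import make_record


class TestDefaultScale:
    def test_structure(self):
        sc = default_scale()
        assert len(sc.items) == 8
        assert sc.max_total == 16.5
        assert sc.cutoff == 9.5

    def test_shipped_json_matches_programmatic_default(self):
        assert packaged_default_scale() == default_scale()

    def test_point_maps_follow_weight_times_level(self):
        for item in default_scale().items:
            assert max(item.points) == pytest.approx(item.weight * (len(item.points) - 1))

    def test_enumeration_brute_force_range(self):
        """All 864 category combinations: totals span exactly [0, 16.5] on a 0.5 grid."""
        totals = enumerate_totals(default_scale())
        assert len(totals) == 2 * 2 * 2 * 3 * 2 * 2 * 3 * 3
        assert min(totals) == 0.0
        assert max(totals) == 16.5
        assert all(t * 2 == int(t * 2) for t in totals)


class TestScoring:
    def test_worst_case_record_reaches_maximum(self):
        rec = make_record(
            age=70, dm=True, nihss_d1=12, nihss_d3=12, bi=20,
            sym_d1=("anxiety", "irritability"),
            sym_d3=("anxiety", "irritability", "circumrotating", "tinnitus"),
        )
        res = score_patient(default_scale(), rec)
        assert res.total == 16.5
        assert res.label is Outcome.POOR

    def test_all_reference_record_scores_zero_under_zero_policy(self):
        rec = make_record(age=50, nihss_d1=1, nihss_d3=0, bi=95)  # delta -1
        res = score_patient(default_scale(), rec, absent_pair_policy="zero")
        assert res.total == 0.0
        assert res.label is Outcome.GOOD

    def test_hand_summed_mixed_record(self):
        # age 60 (1) + no DM (0) + no anxiety (0) + NIHSS 4 (1) + no irritability (0)
        # + delta -2 (0) + circumrotating disappears (0) + tinnitus absent both, keep (2.5)
        rec = make_record(age=60, nihss_d1=4, nihss_d3=2, bi=95,
                          sym_d1=("circumrotating",), sym_d3=())
        res = score_patient(default_scale(), rec)
        assert res.total == 4.5
        assert res.label is Outcome.GOOD

    def test_absent_pair_keep_policy_scores_keep_points(self):
        rec = make_record(age=50, nihss_d1=1, nihss_d3=0, bi=95)
        res = score_patient(default_scale(), rec, absent_pair_policy="keep")
        # circumrotating keep (2) + tinnitus keep (2.5)
        assert res.total == 4.5

    def test_per_item_points_sum_to_total(self, synthetic_cohort_413):
        sc = default_scale()
        for rec in synthetic_cohort_413.records[:50]:
            res = score_patient(sc, rec)
            assert sum(res.per_item.values()) == pytest.approx(res.total)
            assert 0 <= res.total <= sc.max_total
            assert res.total * 2 == pytest.approx(round(res.total * 2))

    def test_missing_symptom_raises_naming_item(self):
        rec = make_record()
        sc = default_scale()
        broken = type(rec)(**{
            **rec.__dict__,
            "symptoms_day1": {"anxiety": False},
            "symptoms_day3": {"anxiety": False},
        })
        with pytest.raises(ScoringError, match="tinnitus|circumrotating|irritability"):
            score_patient(sc, broken)

    def test_monotonicity_raising_one_item_never_lowers_total(self):
        """Moving any single item to a higher-point category never flips poor -> good."""
        sc = default_scale()
        base_kwargs = dict(age=60, dm=False, nihss_d1=4, nihss_d3=4, bi=40,
                           sym_d1=("anxiety",), sym_d3=("anxiety",))
        base_total = score_patient(sc, make_record(**base_kwargs)).total
        upgrades = [
            dict(age=80),
            dict(dm=True),
            dict(nihss_d1=10, nihss_d3=10),
            dict(sym_d1=("anxiety", "irritability"),
                 sym_d3=("anxiety", "irritability")),
            dict(sym_d3=("anxiety", "tinnitus")),  # tinnitus appears
        ]
        for upgrade in upgrades:
            total = score_patient(sc, make_record(**{**base_kwargs, **upgrade})).total
            assert total >= base_total


class TestClassify:
    @pytest.mark.parametrize(
        "total,cutoff,expected",
        [(10.0, 9.5, Outcome.POOR), (9.5, 9.5, Outcome.GOOD), (0.0, 9.5, Outcome.GOOD)],
    )
    def test_strict_cutoff_rule(self, total, cutoff, expected):
        assert classify(total, cutoff) is expected

    @given(st.floats(0, 16.5), st.floats(0.5, 16.0))
    def test_classify_is_threshold_monotone(self, total, cutoff):
        if classify(total, cutoff) is Outcome.POOR:
            assert total > cutoff


class TestPersistence:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "scale.json"
        save_scale(default_scale(), path)
        assert load_scale(path) == default_scale()

    def test_seven_item_definition_rejected_when_strict(self, tmp_path):
        sc = default_scale()
        seven = ScaleDefinition(items=sc.items[:7], cutoff=5.0)
        path = tmp_path / "seven.json"
        save_scale(seven, path)
        with pytest.raises(ScaleError, match="8-item"):
            load_scale(path, strict=True)
        assert load_scale(path, strict=False) == seven

    def test_altered_cutoff_respected(self, tmp_path):
        sc = ScaleDefinition(items=default_scale().items, cutoff=8.0)
        path = tmp_path / "alt.json"
        save_scale(sc, path)
        loaded = load_scale(path)
        assert loaded.cutoff == 8.0
        assert classify(8.5, loaded.cutoff) is Outcome.POOR

    def test_non_half_point_scale_rejected(self):
        from strokescale.scale import ScaleItem

        with pytest.raises(ScaleError, match="0.5"):
            ScaleItem("bad", 0.3, "history", key="dm", points=(0, 0.3))
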