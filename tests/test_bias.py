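"""Radial-maze arm scores: formulas, boundaries, symmetries, conservation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereomet import (
    ArmRoleMap,
    ArmVisit,
    ArmVisitLog,
    ambiguous_arm_score,
    bias_scores,
    entry_summary,
    positive_arm_score,
    reference_arm_score,
    time_in_roles,
)
from stereomet.bias import DEFAULT_TRAIN_ROLES

#: role map with the paired roles swapped (positive<->negative etc.)
SWAPPED = {"positive": "negative", "negative": "positive",
           "near_positive": "near_negative", "near_negative": "near_positive"}

role_times = st.fixed_dictionaries(
    {r: st.one_of(st.just(0.0), st.floats(0.5, 140.0)) for r in
     ("positive", "negative", "near_positive", "near_negative")}
)


class TestTimeInRoles:
    def test_single_visit(self, make_log, test_roles):
        t = time_in_roles(make_log({"positive": 30.0}), test_roles)
        assert t["positive"] == pytest.approx(30.0)
        assert t["negative"] == t["near_positive"] == t["near_negative"] == 0.0
        assert t["centre"] == pytest.approx(570.0)

    def test_empty_log_is_all_centre(self, make_log, test_roles):
        t = time_in_roles(make_log({}), test_roles)
        assert t["centre"] == pytest.approx(600.0)

    def test_closed_arm_visit_rejected(self, test_roles):
        log = ArmVisitLog("s", "train", 600.0,
                          [ArmVisit(arm_id=3, entry_s=0.0, exit_s=5.0)])
        with pytest.raises(ValueError, match="closed"):
            time_in_roles(log, DEFAULT_TRAIN_ROLES)

    @given(times=role_times)
    @settings(derandomize=True)
    def test_time_conservation(self, times, make_log, test_roles):
        log = make_log(times)
        t = time_in_roles(log, test_roles)
        assert sum(t.values()) == pytest.approx(log.duration_s)


class TestScoreFormulas:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ({"positive": 300.0, "negative": 100.0}, 0.5),
            ({"positive": 100.0, "negative": 100.0}, 0.0),
            ({"positive": 50.0, "negative": 0.0}, 1.0),
        ],
    )
    def test_positive_arm_score(self, make_log, test_roles, times, expected):
        assert positive_arm_score(make_log(times), test_roles) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "times, expected",
        [
            ({"positive": 100.0, "negative": 100.0}, 1.0),
            ({"positive": 75.0, "negative": 75.0,
              "near_positive": 75.0, "near_negative": 75.0}, 0.0),
            ({"positive": 150.0, "near_positive": 250.0, "near_negative": 200.0}, -0.5),
        ],
    )
    def test_reference_arm_score(self, make_log, test_roles, times, expected):
        assert reference_arm_score(make_log(times), test_roles) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "times, expected",
        [
            ({"near_positive": 120.0, "near_negative": 40.0}, 0.5),
            ({"near_positive": 80.0, "near_negative": 80.0}, 0.0),
            ({"near_positive": 60.0, "near_negative": 0.0}, 1.0),
        ],
    )
    def test_ambiguous_arm_score(self, make_log, test_roles, times, expected):
        assert ambiguous_arm_score(make_log(times), test_roles) == pytest.approx(expected)

    def test_zero_denominators_are_undefined_not_zero(self, make_log, test_roles):
        only_ambiguous = make_log({"near_positive": 100.0})
        assert math.isnan(positive_arm_score(only_ambiguous, test_roles))
        assert math.isnan(ambiguous_arm_score(make_log({"positive": 10.0}), test_roles))
        assert math.isnan(reference_arm_score(make_log({}), test_roles))

    @given(times=role_times)
    @settings(derandomize=True)
    def test_scores_bounded(self, times, make_log, test_roles):
        s = bias_scores(make_log(times), test_roles)
        for v in (s.positive_arm_score, s.reference_arm_score, s.ambiguous_arm_score):
            assert math.isnan(v) or -1.0 <= v <= 1.0

    @given(times=role_times)
    @settings(derandomize=True)
    def test_antisymmetry_under_role_swap(self, times, make_log, test_roles):
        log = make_log(times)
        swapped = ArmRoleMap({a: SWAPPED.get(r, r) for a, r in test_roles.items()})
        pairs = [
            (positive_arm_score(log, test_roles), positive_arm_score(log, swapped)),
            (ambiguous_arm_score(log, test_roles), ambiguous_arm_score(log, swapped)),
        ]
        for a, b in pairs:
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(-b)
        # reference score is invariant: the swap stays within reference/ambiguous
        a = reference_arm_score(log, test_roles)
        b = reference_arm_score(log, swapped)
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    @given(times=role_times, scale=st.floats(0.1, 10.0))
    @settings(derandomize=True)
    def test_invariance_to_uniform_time_rescaling(self, times, scale,
                                                  make_log, test_roles):
        base = bias_scores(make_log(times), test_roles)
        scaled_log = make_log({r: t * scale for r, t in times.items()},
                              duration_s=600.0 * max(scale, 1.0))
        scaled = bias_scores(scaled_log, test_roles)
        for a, b in [
            (base.positive_arm_score, scaled.positive_arm_score),
            (base.reference_arm_score, scaled.reference_arm_score),
            (base.ambiguous_arm_score, scaled.ambiguous_arm_score),
        ]:
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestEntries:
    def test_relative_entries(self, test_roles):
        visits = [ArmVisit(1, i * 10.0, i * 10.0 + 5.0) for i in range(4)]
        visits += [ArmVisit(5, 100.0 + i * 10.0, 100.0 + i * 10.0 + 5.0)
                   for i in range(6)]
        log = ArmVisitLog("s", "test", 600.0, visits)
        rel, total = entry_summary(log, test_roles)
        assert total == 10
        assert rel["positive"] == pytest.approx(0.4)
        assert rel["negative"] == pytest.approx(0.6)

    def test_no_visits_undefined(self, make_log, test_roles):
        rel, total = entry_summary(make_log({}), test_roles)
        assert total == 0
        assert all(math.isnan(v) for v in rel.values())

    def test_entry_totals_recovered_exactly(self, test_roles):
        for n in (74, 53):
            visits = [ArmVisit(1, i * 8.0, i * 8.0 + 4.0) for i in range(n)]
            log = ArmVisitLog("s", "test", 600.0, visits)
            assert entry_summary(log, test_roles)[1] == n


class TestLogValidation:
    def test_overlapping_visits_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ArmVisitLog("s", "t", 600.0, [ArmVisit(1, 0.0, 30.0),
                                          ArmVisit(2, 20.0, 40.0)])

    def test_visit_past_session_end_rejected(self):
        with pytest.raises(ValueError, match="session end"):
            ArmVisitLog("s", "t", 600.0, [ArmVisit(1, 590.0, 610.0)])

    def test_layout_validation(self, test_roles):
        test_roles.validate_layout("testing")
        DEFAULT_TRAIN_ROLES.validate_layout("training")
        with pytest.raises(ValueError, match="testing layout"):
            DEFAULT_TRAIN_ROLES.validate_layout("testing")
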