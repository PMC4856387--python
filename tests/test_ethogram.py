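"""Bout classification and one-zero interval scoring."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereomet import (
    BehaviourEvent,
    ObservationScheme,
    classify_stereotypic,
    one_zero_sample,
    stereotypy_level,
)

SCHEME = ObservationScheme()
T0 = 3600.0  # start of the first observation block


def ev(behaviour, start, end, rep=None):
    return BehaviourEvent(behaviour, start, end, rep)


class TestBoutClassification:
    def test_short_bar_mouthing_is_not_a_bout(self):
        assert classify_stereotypic([ev("bar_mouthing", 0.0, 2.5)]) == []

    def test_long_bar_mouthing_qualifies(self):
        bouts = classify_stereotypic([ev("bar_mouthing", 1.0, 4.0)])
        assert len(bouts) == 1
        assert (bouts[0].start_s, bouts[0].end_s) == (1.0, 4.0)

    def test_three_flips_with_short_gaps_form_one_bout(self):
        events = [ev("back_flipping", t, t + 0.5) for t in (0.0, 2.5, 5.0)]
        bouts = classify_stereotypic(events)
        assert len(bouts) == 1
        assert (bouts[0].start_s, bouts[0].end_s) == (0.0, 5.5)
        assert bouts[0].n_repeats == 3

    def test_long_pause_breaks_the_run(self):
        # 2 twirls, 4-s pause, 2 twirls: neither run reaches 3 repetitions
        events = [ev("cage_top_twirling", t, t + 0.5)
                  for t in (0.0, 1.0, 5.5, 6.5)]
        assert classify_stereotypic(events) == []

    def test_pause_of_exactly_three_seconds_keeps_the_run(self):
        events = [ev("route_tracing", t, t + 1.0) for t in (0.0, 4.0, 8.0)]
        assert len(classify_stereotypic(events)) == 1

    def test_repeat_index_counts_repetitions(self):
        # one recorded event containing three laps qualifies on its own
        assert len(classify_stereotypic([ev("circling", 0.0, 4.0, rep=3)])) == 1
        assert classify_stereotypic([ev("circling", 0.0, 4.0, rep=2)]) == []

    def test_unknown_behaviour_rejected(self):
        with pytest.raises(ValueError, match="unknown behaviour"):
            BehaviourEvent("hopping", 0.0, 1.0)

    def test_idempotent_on_own_output_spans(self):
        events = [ev("bar_mouthing", 0.0, 5.0), ev("bar_mouthing", 7.0, 12.0)]
        events += [ev("back_flipping", t, t + 0.5) for t in (20.0, 22.0, 24.0)]
        bouts = classify_stereotypic(events)
        again = classify_stereotypic(
            [ev(b.behaviour, b.start_s, b.end_s, rep=b.n_repeats) for b in bouts]
        )
        assert [(b.behaviour, b.start_s, b.end_s) for b in again] == \
            [(b.behaviour, b.start_s, b.end_s) for b in bouts]


class TestOneZeroSampling:
    def test_standard_scheme_yields_480_intervals(self):
        assert SCHEME.n_intervals == 480
        m = one_zero_sample([], SCHEME)
        assert m.n_intervals == 480

    def test_bout_at_block_start_flags_first_two_intervals(self):
        events = [ev("bar_mouthing", T0, T0 + 30.0)]
        m = one_zero_sample(events, SCHEME)
        assert m.data["bar_mouthing"].sum() == 2
        assert list(m.data["bar_mouthing"][:3]) == [1, 1, 0]

    def test_boundary_touch_belongs_to_later_interval(self):
        # [15, 30) bout: flags the second interval only, not the first
        events = [ev("bar_mouthing", T0 + 15.0, T0 + 30.0)]
        m = one_zero_sample(events, SCHEME)
        assert list(m.data["bar_mouthing"][:3]) == [0, 1, 0]

    def test_empty_stream_is_all_inactive(self):
        m = one_zero_sample([], SCHEME)
        assert m.data["inactive"].all()
        assert not m.data["active"].any()

    def test_short_twitch_does_not_break_inactivity(self):
        m = one_zero_sample([ev("active", T0 + 1.0, T0 + 4.0)], SCHEME)
        assert m.data["active"].sum() == 0
        m2 = one_zero_sample([ev("active", T0 + 1.0, T0 + 8.0)], SCHEME)
        assert m2.data["active"].sum() == 1

    def test_events_outside_blocks_ignored(self):
        m = one_zero_sample([ev("bar_mouthing", 0.0, 100.0)], SCHEME)
        assert m.data["bar_mouthing"].sum() == 0

    def test_monotone_in_events(self):
        base = [ev("bar_mouthing", T0 + 10.0, T0 + 20.0)]
        extra = base + [ev("back_flipping", T0 + 100.0 + t, T0 + 100.5 + t)
                        for t in (0.0, 2.0, 4.0)] + [ev("active", T0, T0 + 900.0)]
        a = one_zero_sample(base, SCHEME)
        b = one_zero_sample(extra, SCHEME)
        for col in ("bar_mouthing", "back_flipping", "active"):
            assert (b.data[col] >= a.data[col]).all()


class TestStereotypyLevel:
    def test_proportion_of_active_time(self):
        # 1 h of activity in block 1; a 300-s bar-mouthing bout inside it
        events = [ev("active", T0, T0 + 900.0),
                  ev("bar_mouthing", T0, T0 + 300.0)]
        m = one_zero_sample(events, SCHEME)
        assert m.data["active"].sum() == 60
        assert stereotypy_level(m, "bar_mouthing") == pytest.approx(20 / 60)

    def test_no_flags_gives_zero(self):
        m = one_zero_sample([ev("active", T0, T0 + 900.0)], SCHEME)
        assert stereotypy_level(m, "all") == 0.0

    def test_zero_active_time_is_undefined(self):
        m = one_zero_sample([], SCHEME)
        assert math.isnan(stereotypy_level(m, "all"))

    def test_forms_are_not_additive_in_all(self):
        # bar-mouthing and circling flagged in the same interval count once
        events = [ev("active", T0, T0 + 900.0),
                  ev("bar_mouthing", T0, T0 + 10.0),
                  ev("circling", T0 + 1.0, T0 + 9.0, rep=5)]
        m = one_zero_sample(events, SCHEME)
        lv_all = stereotypy_level(m, "all")
        assert lv_all < stereotypy_level(m, "bar_mouthing") + \
            stereotypy_level(m, "circling")
        assert lv_all == pytest.approx(stereotypy_level(m, "bar_mouthing"))

    @given(
        starts=st.lists(st.floats(0.0, 800.0), min_size=0, max_size=8),
        durations=st.lists(st.floats(0.5, 60.0), min_size=8, max_size=8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_level_ordering_invariant(self, starts, durations):
        events = [ev("active", T0, T0 + 900.0)]
        events += [ev("bar_mouthing", T0 + s, T0 + s + d)
                   for s, d in zip(starts, durations)]
        m = one_zero_sample(events, SCHEME)
        lv_form = stereotypy_level(m, "bar_mouthing")
        lv_all = stereotypy_level(m, "all")
        assert 0.0 <= lv_form <= lv_all <= 1.0


class TestSchemeValidation:
    def test_interval_must_divide_block(self):
        with pytest.raises(ValueError, match="divide"):
            ObservationScheme(interval_s=14.0)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ObservationScheme(block_starts_s=(0.0, 600.0))
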