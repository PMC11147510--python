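"""Behavior encoding, transition detection, and ethogram scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fiberphot as fp
from conftest import random_behavior_track


class TestEncode:
    def test_all_immobile_is_constant_one(self):
        track = fp.generate_behavior_track(
            [("immobile", 0.0, 5.0)], 30.0, fp.SWIM_CATEGORIES
        )
        np.testing.assert_array_equal(fp.encode_behavior_numeric(track), 1.0)

    def test_mean_equals_duration_weighted_average(self):
        track = fp.generate_behavior_track(
            [("climbing", 0.0, 10.0), ("immobile", 10.0, 40.0)],
            30.0,
            fp.SWIM_CATEGORIES,
        )
        series = fp.encode_behavior_numeric(track)
        assert series.mean() == pytest.approx((10 * 4 + 30 * 1) / 40)

    def test_unmapped_label_names_the_label(self):
        track = fp.BehaviorTrack(
            np.array(["grooming"] * 5, dtype=object), 30.0, ("grooming",)
        )
        with pytest.raises(fp.ValidationError, match="grooming"):
            fp.encode_behavior_numeric(track, mapping={"other": 1.0})


class TestMeanSeries:
    def test_identical_tracks_pass_through(self):
        s = np.array([4.0, 3.0, 1.0])
        np.testing.assert_array_equal(fp.mean_behavior_series([s, s, s]), s)

    def test_two_constant_tracks_average(self):
        out = fp.mean_behavior_series([np.full(10, 4.0), np.full(10, 1.0)])
        np.testing.assert_array_equal(out, 2.5)

    def test_cohort_mean_crosses_midpoint_at_scheduled_shift(self):
        """Nine animals shifting active -> passive at t=60 s: the cohort mean
        behavior score crosses 2.5 within one frame of the schedule."""
        rng = np.random.default_rng(0)
        rate, shift_s, total_s = 30.0, 60.0, 120.0
        series = []
        for _ in range(9):
            active = str(rng.choice(["climbing", "swimming"]))
            passive = str(rng.choice(["hindpaw swimming", "immobile"]))
            track = fp.generate_behavior_track(
                [(active, 0.0, shift_s), (passive, shift_s, total_s)],
                rate,
                fp.SWIM_CATEGORIES,
            )
            series.append(fp.encode_behavior_numeric(track))
        mean = fp.mean_behavior_series(series)
        below = np.flatnonzero(mean < 2.5)
        assert abs(below[0] / rate - shift_s) <= 1.0 / rate + 1e-9

    def test_length_mismatch_rejected(self):
        with pytest.raises(fp.ValidationError):
            fp.mean_behavior_series([np.zeros(5), np.zeros(6)])


def brute_force_transitions(track, from_states, to_state, min_bout_s):
    """Independent frame-by-frame scan oracle."""
    labels = track.labels
    onsets = []
    i = 1
    n = labels.size
    while i < n:
        if labels[i] == to_state and labels[i - 1] != to_state:
            j = i
            while j < n and labels[j] == to_state:
                j += 1
            if labels[i - 1] in from_states and (
                (j - i) / track.frame_rate >= min_bout_s - 1e-9
            ):
                onsets.append(i / track.frame_rate)
            i = j
        else:
            i += 1
    return onsets


class TestTransitions:
    def test_single_bout_detected_at_entry(self):
        track = fp.generate_behavior_track(
            [
                ("immobile", 0.0, 10.0),
                ("hindpaw swimming", 10.0, 15.0),
                ("immobile", 15.0, 20.0),
            ],
            30.0,
            fp.SWIM_CATEGORIES,
        )
        ev = fp.detect_transitions(track, {"immobile"}, "hindpaw swimming", 1.0)
        assert len(ev) == 1
        assert ev.events[0].onset_s == pytest.approx(10.0)
        assert ev.events[0].duration_s == pytest.approx(5.0)

    def test_flicker_bout_filtered(self):
        track = fp.generate_behavior_track(
            [
                ("immobile", 0.0, 10.0),
                ("hindpaw swimming", 10.0, 10.1),
                ("immobile", 10.1, 20.0),
            ],
            30.0,
            fp.SWIM_CATEGORIES,
        )
        assert len(fp.detect_transitions(track, {"immobile"}, "hindpaw swimming", 1.0)) == 0

    def test_unknown_target_state_rejected(self):
        track = fp.generate_behavior_track(
            [("immobile", 0.0, 5.0)], 30.0, fp.SWIM_CATEGORIES
        )
        with pytest.raises(fp.ValidationError):
            fp.detect_transitions(track, {"immobile"}, "grooming", 1.0)

    def test_agrees_with_brute_force_scan_on_random_churn(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            track = random_behavior_track(rng)
            min_bout = float(rng.choice([0.0, 0.1, 0.5]))
            got = fp.detect_transitions(track, {"a", "b"}, "c", min_bout)
            expected = brute_force_transitions(track, {"a", "b"}, "c", min_bout)
            np.testing.assert_allclose(got.onsets, expected)


class TestEthogramBins:
    def test_uniform_bin(self):
        track = fp.generate_behavior_track(
            [("immobile", 0.0, 10.0)], 30.0, fp.SWIM_CATEGORIES
        )
        bins = fp.score_ethogram_bins(track)
        assert len(bins) == 1 and bins[0].category == "immobile"
        assert not bins[0].partial

    def test_majority_wins(self):
        track = fp.generate_behavior_track(
            [("swimming", 0.0, 6.0), ("immobile", 6.0, 10.0)],
            30.0,
            fp.SWIM_CATEGORIES,
        )
        assert fp.score_ethogram_bins(track)[0].category == "swimming"

    def test_tie_broken_by_earliest_onset(self):
        track = fp.generate_behavior_track(
            [("swimming", 0.0, 5.0), ("climbing", 5.0, 10.0)],
            30.0,
            fp.SWIM_CATEGORIES,
        )
        assert fp.score_ethogram_bins(track)[0].category == "swimming"
        assert (
            fp.score_ethogram_bins(track, tie_rule="lexicographic")[0].category
            == "climbing"
        )

    def test_partial_trailing_bin_flagged(self):
        track = fp.generate_behavior_track(
            [("immobile", 0.0, 25.0)], 30.0, fp.SWIM_CATEGORIES
        )
        bins = fp.score_ethogram_bins(track)
        assert [b.partial for b in bins] == [False, False, True]
        assert bins[-1].end_s == pytest.approx(25.0)

    def test_bins_partition_the_track(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            track = random_behavior_track(rng)
            bins = fp.score_ethogram_bins(track, bin_s=10.0)
            assert bins[0].start_s == 0.0
            for a, b in zip(bins, bins[1:]):
                assert a.end_s == pytest.approx(b.start_s)
            assert bins[-1].end_s == pytest.approx(track.duration_s)


class TestPeriodSummaries:
    @pytest.fixture
    def nine_cat_track(self):
        cats = (
            "grooming", "immobile", "walking", "chewing", "rearing",
            "rapid locomotion", "digging", "treading", "jumping",
        )
        schedule = [
            ("walking", 0.0, 280.0),
            ("grooming", 280.0, 310.0),
            ("treading", 310.0, 400.0),
            ("digging", 400.0, 500.0),
            ("rearing", 500.0, 600.0),
            ("immobile", 600.0, 900.0),
        ]
        return fp.generate_behavior_track(schedule, 30.0, cats)

    def test_grooming_duration_lands_in_one_period(self, nine_cat_track):
        periods = [("pre", 0.0, 300.0), ("stim", 300.0, 600.0), ("post", 600.0, 900.0)]
        out = fp.period_summaries(nine_cat_track, fp.EventSet(), periods)
        groom = [p.durations_s.get("grooming", 0.0) for p in out]
        assert groom[0] == pytest.approx(20.0, abs=0.1)
        assert groom[1] == pytest.approx(10.0, abs=0.1)
        assert groom[2] == 0.0

    def test_treading_and_digging_merge(self, nine_cat_track):
        out = fp.period_summaries(
            nine_cat_track, fp.EventSet(), [("stim", 300.0, 600.0)]
        )
        assert out[0].durations_s["treading/digging"] == pytest.approx(190.0, abs=0.1)
        assert "treading" not in out[0].durations_s

    def test_jump_counts_per_period(self, nine_cat_track):
        jumps = fp.EventSet.from_onsets([310, 320, 330, 340, 350, 360, 370], label="jump")
        out = fp.period_summaries(
            nine_cat_track, jumps, [("pre", 0.0, 300.0), ("stim", 300.0, 600.0)]
        )
        assert [p.jump_count for p in out] == [0, 7]

    def test_durations_conserve_period_length(self, nine_cat_track):
        periods = [("pre", 0.0, 300.0), ("stim", 300.0, 600.0), ("post", 600.0, 900.0)]
        for p in fp.period_summaries(nine_cat_track, fp.EventSet(), periods):
            assert sum(p.durations_s.values()) == pytest.approx(p.end_s - p.start_s)

    def test_overlapping_periods_rejected(self, nine_cat_track):
        with pytest.raises(fp.ValidationError, match="overlap"):
            fp.period_summaries(
                nine_cat_track, fp.EventSet(), [("a", 0.0, 400.0), ("b", 300.0, 600.0)]
            )


@given(st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_category_durations_always_sum_to_track_duration(seed):
    rng = np.random.default_rng(seed)
    track = random_behavior_track(rng)
    out = fp.period_summaries(
        track, fp.EventSet(), [("all", 0.0, track.duration_s)], merge_map={}
    )
    assert sum(out[0].durations_s.values()) == pytest.approx(track.duration_s)
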