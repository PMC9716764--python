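import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actcomp import (
    DataError,
    DayWearRecord,
    EpochSeries,
    NonwearParams,
    WearMask,
    day_wear_summary,
    detect_nonwear,
    validate_participant,
)
from oracles import brute_force_nonwear_cubic, brute_force_nonwear_scan

MONDAY = dt.datetime(2018, 10, 1, 0, 0)
SATURDAY = dt.datetime(2018, 10, 6, 0, 0)


def _series(counts, start=MONDAY):
    return EpochSeries("P1", start, 60, np.asarray(counts))


def _nonwear(counts):
    return ~detect_nonwear(_series(counts)).worn


class TestDetectNonwear:
    def test_ninety_zero_minutes_flagged(self):
        counts = [500] * 10 + [0] * 90 + [500] * 10
        nw = _nonwear(counts)
        assert list(np.flatnonzero(nw)) == list(range(10, 100))

    def test_eighty_nine_zeros_stay_wear(self):
        counts = [500] * 10 + [0] * 89 + [500] * 10
        assert not _nonwear(counts).any()

    def test_two_tolerated_interruption_minutes(self):
        counts = [500] * 5 + [0] * 45 + [50, 50] + [0] * 45 + [500] * 5
        nw = _nonwear(counts)
        # full 92-minute block including the interruption is non-wear
        assert list(np.flatnonzero(nw)) == list(range(5, 97))

    def test_three_interruption_minutes_break_the_bout(self):
        counts = [500] * 5 + [0] * 45 + [50, 50, 50] + [0] * 45 + [500] * 5
        assert not _nonwear(counts).any()

    def test_interruption_needs_thirty_zero_flanks(self):
        # 20-minute left flank < 30: the combined 111-minute stretch does not
        # qualify, but the trailing 90 zeros alone do
        counts = [500] * 5 + [0] * 20 + [50] + [0] * 90 + [500] * 5
        nw = _nonwear(counts)
        assert list(np.flatnonzero(nw)) == list(range(26, 116))

    def test_hundred_cpm_always_terminates(self):
        counts = [0] * 60 + [100] + [0] * 60
        assert not _nonwear(counts).any()

    def test_requires_minute_epochs(self):
        with pytest.raises(DataError):
            detect_nonwear(EpochSeries("P1", MONDAY, 1, np.zeros(120, dtype=int)))

    def test_configurable_window(self):
        counts = [500] * 5 + [0] * 60 + [500] * 5
        nw = ~detect_nonwear(_series(counts), NonwearParams(window_min=60)).worn
        assert nw.sum() == 60

    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(st.data())
    def test_agrees_with_bruteforce_oracles(self, data):
        blocks = data.draw(
            st.lists(
                st.tuples(st.sampled_from([0, 50, 150]), st.integers(1, 60)),
                min_size=1,
                max_size=8,
            )
        )
        counts = np.concatenate([[v] * n for v, n in blocks])[:200]
        nw = _nonwear(counts)
        assert np.array_equal(nw, brute_force_nonwear_cubic(counts))
        assert np.array_equal(nw, brute_force_nonwear_scan(counts))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_activity_never_increases_nonwear(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        counts = np.concatenate(
            [[v] * int(rng.integers(1, 50)) for v in rng.choice([0, 0, 50, 150], size=8)]
        )[:200]
        zero_idx = np.flatnonzero(counts == 0)
        if zero_idx.size == 0:
            return
        before = _nonwear(counts).sum()
        counts[zero_idx[int(rng.integers(zero_idx.size))]] = 150
        assert _nonwear(counts).sum() <= before


class TestDayWearSummary:
    def test_full_weekend_window_wear(self):
        counts = np.full(1440, 300)
        series = _series(counts, start=SATURDAY)
        worn = np.zeros(1440, dtype=bool)
        worn[7 * 60 : 21 * 60] = True
        rec = day_wear_summary(series, WearMask("P1", 60, worn))[0]
        assert rec.day_type == "weekend"
        assert rec.wear_minutes_total == 840
        assert rec.wear_minutes_by_window == {"weekend_day": 840}

    def test_all_nonwear_day(self):
        series = _series(np.zeros(1440, dtype=int))
        rec = day_wear_summary(series, WearMask("P1", 60, np.zeros(1440, dtype=bool)))[0]
        assert rec.wear_minutes_total == 0
        assert rec.wear_minutes_by_window == {"morning": 0, "afternoon": 0}

    def test_early_wear_clips_to_morning_window(self):
        # wear 06:00-08:00 on a Monday: only 07:00-08:00 falls in a window
        series = _series(np.full(1440, 300))
        worn = np.zeros(1440, dtype=bool)
        worn[6 * 60 : 8 * 60] = True
        rec = day_wear_summary(series, WearMask("P1", 60, worn))[0]
        assert rec.day_type == "weekday"
        assert rec.wear_minutes_total == 120
        assert rec.wear_minutes_by_window == {"morning": 60, "afternoon": 0}

    def test_detected_mask_splits_across_midnight(self):
        # 23:00-01:00 zeros: the bout spans midnight, minutes attributed per date
        counts = np.concatenate([np.full(1380, 300), np.zeros(120, int), np.full(1380, 300)])
        series = _series(counts)
        mask = detect_nonwear(series)
        recs = day_wear_summary(series, mask)
        assert [r.wear_minutes_total for r in recs] == [1380, 1380]


def _rec(date, minutes):
    d = dt.date.fromisoformat(date)
    return DayWearRecord("P1", d, "weekend" if d.weekday() >= 5 else "weekday", minutes, {})


class TestValidateParticipant:
    def test_minimum_valid_week(self):
        recs = [_rec(f"2018-10-0{d}", 480) for d in (1, 2, 3, 6)]
        verdict = validate_participant(recs)
        assert verdict.valid and verdict.reason is None

    def test_no_weekend_day(self):
        recs = [_rec(f"2018-10-0{d}", 600) for d in (1, 2, 3, 4, 5)]
        verdict = validate_participant(recs)
        assert not verdict.valid and verdict.reason == "weekend days < 1"

    def test_too_few_weekdays(self):
        recs = [_rec(d, 700) for d in ("2018-10-01", "2018-10-02", "2018-10-06", "2018-10-07")]
        verdict = validate_participant(recs)
        assert not verdict.valid and verdict.reason == "weekdays < 3"

    def test_sub_eight_hour_days_do_not_count(self):
        recs = [_rec(f"2018-10-0{d}", 479) for d in (1, 2, 3, 6)]
        verdict = validate_participant(recs)
        assert not verdict.valid

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.integers(1, 7), st.integers(0, 1440)), min_size=1, max_size=10),
           st.integers(0, 500))
    def test_adding_wear_never_invalidates(self, spec, extra):
        recs = [_rec(f"2018-10-0{day}", minutes) for day, minutes in spec]
        before = validate_participant(recs).valid
        recs[0].wear_minutes_total = min(1440, recs[0].wear_minutes_total + extra)
        after = validate_participant(recs).valid
        assert after or not before
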