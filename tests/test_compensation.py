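import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actcomp import (
    DataError,
    GirlWeekSummary,
    ObservationPoint,
    SegmentExposure,
    ThresholdSpec,
    ValidityVerdict,
    build_units,
    classify_observation,
    classify_week,
    exposures_to_frame,
    reference_sd,
)
from actcomp.compensation import _classify_pair

D = dt.date(2018, 10, 1)


def _obs(st_m, pa_m, st_a, pa_a, mvpa_frac=0.5):
    """ObservationPoint from (ST, PA) pairs, splitting PA into LPA/MVPA."""
    return ObservationPoint(
        "P1", D,
        st_m, pa_m * (1 - mvpa_frac), pa_m * mvpa_frac,
        st_a, pa_a * (1 - mvpa_frac), pa_a * mvpa_frac,
    )


class TestReferenceSd:
    def test_constant_input_gives_zero(self):
        assert reference_sd([0.3, 0.3, 0.3]) == 0.0

    def test_two_point_sample_sd(self):
        assert reference_sd([0.2, 0.4]) == pytest.approx(math.sqrt(0.02), abs=1e-12)

    def test_needs_two_values(self):
        with pytest.raises(DataError):
            reference_sd([0.5])

    def test_recovers_generating_sigma(self):
        rng = np.random.default_rng(17)
        draws = rng.normal(0.3, 0.04, size=1000)
        assert reference_sd(draws) == pytest.approx(0.04, rel=0.1)


class TestClassifyObservation:
    def test_positive_above_threshold(self):
        label = classify_observation(_obs(0.70, 0.30, 0.50, 0.50), sd_ref=0.05)
        assert (label.eligibility, label.label) == ("eligible_positive", "positive")
        assert label.delta == pytest.approx(0.20)
        assert label.threshold == pytest.approx(0.08225)

    def test_negative_under_literal_inequality(self):
        label = classify_observation(_obs(0.60, 0.40, 0.70, 0.30), sd_ref=0.05)
        assert (label.eligibility, label.label) == ("eligible_negative", "negative")
        assert label.delta == pytest.approx(-0.10)

    def test_sub_threshold_positive_is_none(self):
        label = classify_observation(_obs(0.70, 0.30, 0.69, 0.31), sd_ref=0.05)
        assert (label.eligibility, label.label) == ("eligible_positive", "none")

    def test_identical_periods_tie_to_none(self):
        label = classify_observation(_obs(0.70, 0.30, 0.70, 0.30), sd_ref=0.05)
        assert (label.eligibility, label.label) == ("tie", "none")

    def test_literal_vs_symmetric_on_small_negative_change(self):
        # eligible-negative with |delta| below threshold: literal says negative,
        # symmetric says none
        obs = _obs(0.60, 0.40, 0.61, 0.39)
        literal = classify_observation(obs, 0.05, ThresholdSpec(variant="paper_literal"))
        symmetric = classify_observation(obs, 0.05, ThresholdSpec(variant="symmetric"))
        assert literal.label == "negative"
        assert symmetric.label == "none"

    def test_symmetric_agrees_on_large_negative_change(self):
        obs = _obs(0.60, 0.40, 0.75, 0.25)
        for variant in ("paper_literal", "symmetric"):
            assert classify_observation(obs, 0.05, ThresholdSpec(variant=variant)).label == "negative"


class TestClassifyWeek:
    def _week(self, st_wd, pa_wd, st_we, pa_we):
        return GirlWeekSummary("P1", st_wd, pa_wd / 2, pa_wd / 2, st_we, pa_we / 2, pa_we / 2)

    def test_positive(self):
        label = classify_week(self._week(0.66, 0.34, 0.50, 0.50), sd_ref=0.05)
        assert label.label == "positive"

    def test_negative_literal(self):
        label = classify_week(self._week(0.60, 0.40, 0.75, 0.25), sd_ref=0.05)
        assert label.label == "negative"

    def test_identical_weeks_none(self):
        label = classify_week(self._week(0.66, 0.34, 0.66, 0.34), sd_ref=0.05)
        assert (label.eligibility, label.label) == ("tie", "none")


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    st_ref=st.floats(0.01, 0.99),
    st_resp=st.floats(0.01, 0.99),
    sd_ref=st.floats(0.0, 0.3),
    z=st.floats(0.1, 3.0),
)
def test_classification_is_scale_invariant(st_ref, st_resp, sd_ref, z):
    """The rule is homogeneous of degree 1: proportions -> percentages with a
    matching sd rescale leaves eligibility and label unchanged."""
    pa_ref, pa_resp = 1 - st_ref, 1 - st_resp
    spec = ThresholdSpec(z=z)
    base = _classify_pair(st_ref, pa_ref, st_resp, pa_resp, sd_ref, spec)
    scaled = _classify_pair(
        100 * st_ref, 100 * pa_ref, 100 * st_resp, 100 * pa_resp, 100 * sd_ref, spec
    )
    assert base[:2] == scaled[:2]


def _seg(pid, date, segment, wear, st_m, lpa_m, mvpa_m):
    return SegmentExposure(
        pid, dt.date.fromisoformat(date), segment, wear, st_m, lpa_m, mvpa_m,
        st_m / wear, lpa_m / wear, mvpa_m / wear, valid=True,
    )


class TestBuildUnits:
    def _frame(self, segs):
        return exposures_to_frame(segs)

    def test_unit_counting(self):
        segs = []
        for day in (1, 2, 3, 4):  # four weekdays, both segments
            segs.append(_seg("P1", f"2018-10-0{day}", "morning", 360, 240, 80, 40))
            segs.append(_seg("P1", f"2018-10-0{day}", "afternoon", 480, 320, 100, 60))
        for day in (6, 7):  # two weekend days
            segs.append(_seg("P1", f"2018-10-0{day}", "weekend_day", 840, 560, 200, 80))
        verdict = ValidityVerdict("P1", True, None, 4, 2)
        obs, weeks = build_units(self._frame(segs), [verdict])
        assert len(obs) == 4 and len(weeks) == 1

    def test_unpaired_weekday_yields_no_observation(self):
        segs = [_seg("P1", "2018-10-01", "morning", 360, 240, 80, 40)]
        for day in (2, 3, 4):
            segs.append(_seg("P1", f"2018-10-0{day}", "morning", 360, 240, 80, 40))
            segs.append(_seg("P1", f"2018-10-0{day}", "afternoon", 480, 320, 100, 60))
        segs.append(_seg("P1", "2018-10-06", "weekend_day", 840, 560, 200, 80))
        obs, weeks = build_units(self._frame(segs), [ValidityVerdict("P1", True, None, 4, 1)])
        assert len(obs) == 3  # the unpaired 10-01 morning produces no unit
        assert len(weeks) == 1

    def test_weekend_pooling_is_wear_weighted(self):
        segs = []
        for day in (1, 2, 3):
            segs.append(_seg("P1", f"2018-10-0{day}", "morning", 360, 240, 80, 40))
            segs.append(_seg("P1", f"2018-10-0{day}", "afternoon", 480, 320, 100, 60))
        # two weekend days with different wear and proportions
        segs.append(_seg("P1", "2018-10-06", "weekend_day", 400, 300, 60, 40))
        segs.append(_seg("P1", "2018-10-07", "weekend_day", 440, 220, 160, 60))
        obs, weeks = build_units(self._frame(segs), [ValidityVerdict("P1", True, None, 3, 2)])
        week = weeks[0]
        assert week.st_weekend == pytest.approx((300 + 220) / 840)
        assert week.lpa_weekend == pytest.approx((60 + 160) / 840)
        assert week.mvpa_weekend == pytest.approx((40 + 60) / 840)

    def test_invalid_participants_are_excluded(self):
        segs = [_seg("P1", "2018-10-01", "morning", 360, 240, 80, 40),
                _seg("P1", "2018-10-01", "afternoon", 480, 320, 100, 60)]
        obs, weeks = build_units(self._frame(segs), [ValidityVerdict("P1", False, "weekend days < 1", 5, 0)])
        assert obs == [] and weeks == []

    def test_no_weekend_day_means_no_week_summary(self):
        segs = []
        for day in (1, 2, 3):
            segs.append(_seg("P1", f"2018-10-0{day}", "morning", 360, 240, 80, 40))
            segs.append(_seg("P1", f"2018-10-0{day}", "afternoon", 480, 320, 100, 60))
        obs, weeks = build_units(self._frame(segs), [ValidityVerdict("P1", True, None, 3, 1)])
        assert len(obs) == 3 and weeks == []


class TestCohortLabelInvariants:
    def test_every_unit_gets_exactly_one_label(self, run10):
        _, _, out = run10
        labels = out["labels"]
        assert labels["label"].isin(["positive", "negative", "none"]).all()
        assert len(labels) == len(out["obs_labels"]) + len(out["week_labels"])

    def test_literal_rule_labels_nonpositive_deltas_negative(self, run10):
        _, _, out = run10
        labels = out["labels"]
        en = labels[(labels["eligibility"] == "eligible_negative") & (labels["delta"] <= 0)]
        assert (en["label"] == "negative").all()

    def test_positive_only_if_eligible_positive(self, run10):
        _, _, out = run10
        labels = out["labels"]
        assert (labels.loc[labels["label"] == "positive", "eligibility"] == "eligible_positive").all()
        assert (labels.loc[labels["label"] == "negative", "eligibility"] == "eligible_negative").all()
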