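"""Compensatory physical-activity-behaviour (CPB) classification.

Two comparison designs are supported:

* **observation points** — one unit per weekday on which a girl has a valid
  morning and afternoon segment (reference period: morning; response period:
  afternoon);
* **girl weeks** — one unit per girl, pooling worn minutes over her valid
  weekdays (reference) and valid weekend days (response).

With active behaviour PA = LPA + MVPA expressed as proportions of worn time,
a unit with lower sedentary time in the response period is *eligible for
positive* compensation and is labelled positive when

    (PA_response - PA_reference) > z * sd_ref

with z = 1.645 (a 90% band) and sd_ref the pooled sample standard deviation
of PA_reference across all valid units of the analysis.  A unit with higher
sedentary time in the response period is *eligible for negative*
compensation; the default ``paper_literal`` variant labels it negative when

    (PA_response - PA_reference) < z * sd_ref

i.e. with the threshold on the same (positive) side — the inequality exactly
as published, under which any eligible-negative unit with a non-positive PA
change is always negative.  The ``symmetric`` variant instead requires the
change to fall below ``-z * sd_ref``.  Equal sedentary proportions are a tie
and yield no compensation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocessing import ValidityVerdict

logger = logging.getLogger(__name__)

_PROP_TOL = 1e-9

ELIGIBLE_POSITIVE = "eligible_positive"
ELIGIBLE_NEGATIVE = "eligible_negative"
TIE = "tie"

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"


def _check_triplet(st: float, lpa: float, mvpa: float, what: str) -> None:
    for name, v in (("st", st), ("lpa", lpa), ("mvpa", mvpa)):
        if not (0.0 - _PROP_TOL <= v <= 1.0 + _PROP_TOL):
            raise DataError(f"{what}: {name} proportion {v} outside [0, 1]")
    if abs(st + lpa + mvpa - 1.0) > _PROP_TOL:
        raise DataError(f"{what}: proportions sum to {st + lpa + mvpa}, not 1")


@dataclasses.dataclass(frozen=True)
class ObservationPoint:
    """Morning vs afternoon proportions of one girl's weekday."""

    participant_id: str
    date: dt.date
    st_morning: float
    lpa_morning: float
    mvpa_morning: float
    st_afternoon: float
    lpa_afternoon: float
    mvpa_afternoon: float

    def __post_init__(self) -> None:
        _check_triplet(self.st_morning, self.lpa_morning, self.mvpa_morning, "morning")
        _check_triplet(self.st_afternoon, self.lpa_afternoon, self.mvpa_afternoon, "afternoon")

    @property
    def pa_morning(self) -> float:
        return self.lpa_morning + self.mvpa_morning

    @property
    def pa_afternoon(self) -> float:
        return self.lpa_afternoon + self.mvpa_afternoon


@dataclasses.dataclass(frozen=True)
class GirlWeekSummary:
    """Pooled weekday vs weekend proportions of one girl."""

    participant_id: str
    st_weekday: float
    lpa_weekday: float
    mvpa_weekday: float
    st_weekend: float
    lpa_weekend: float
    mvpa_weekend: float
    n_weekdays: int = 0
    n_weekend_days: int = 0

    def __post_init__(self) -> None:
        _check_triplet(self.st_weekday, self.lpa_weekday, self.mvpa_weekday, "weekday")
        _check_triplet(self.st_weekend, self.lpa_weekend, self.mvpa_weekend, "weekend")

    @property
    def pa_weekday(self) -> float:
        return self.lpa_weekday + self.mvpa_weekday

    @property
    def pa_weekend(self) -> float:
        return self.lpa_weekend + self.mvpa_weekend


@dataclasses.dataclass(frozen=True)
class ThresholdSpec:
    """Threshold multiplier and inequality variant of the CPB rule."""

    z: float = 1.645
    sd_scope: str = "cohort_reference_period"
    variant: str = "paper_literal"  # or "symmetric"

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise DataError("threshold multiplier z must be positive")
        if self.variant not in ("paper_literal", "symmetric"):
            raise DataError(f"unknown variant {self.variant!r}")
        if self.sd_scope != "cohort_reference_period":
            raise DataError(f"unknown sd scope {self.sd_scope!r}")


@dataclasses.dataclass(frozen=True)
class CompensationLabel:
    unit_id: str
    analysis: str  # "observation" | "week"
    participant_id: str
    date: dt.date | None
    eligibility: str  # eligible_positive | eligible_negative | tie
    label: str  # positive | negative | none
    delta: float
    threshold: float


def reference_sd(values) -> float:
    """Pooled sample standard deviation (n-1 denominator) of the reference PA."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise DataError(f"reference sd needs at least 2 values, got {values.size}")
    return float(np.std(values, ddof=1))


def _classify_pair(
    st_ref: float,
    pa_ref: float,
    st_resp: float,
    pa_resp: float,
    sd_ref: float,
    spec: ThresholdSpec,
) -> tuple[str, str, float, float]:
    if sd_ref < 0:
        raise DataError("reference sd must be non-negative")
    delta = pa_resp - pa_ref
    threshold = spec.z * sd_ref
    if st_resp < st_ref:
        eligibility = ELIGIBLE_POSITIVE
        label = POSITIVE if delta > threshold else NONE
    elif st_resp > st_ref:
        eligibility = ELIGIBLE_NEGATIVE
        if spec.variant == "paper_literal":
            label = NEGATIVE if delta < threshold else NONE
        else:
            label = NEGATIVE if delta < -threshold else NONE
    else:
        eligibility = TIE
        label = NONE
    return eligibility, label, delta, threshold


def classify_observation(
    obs: ObservationPoint, sd_ref: float, spec: ThresholdSpec | None = None
) -> CompensationLabel:
    """Classify a morning-vs-afternoon observation point."""
    spec = spec or ThresholdSpec()
    eligibility, label, delta, threshold = _classify_pair(
        obs.st_morning, obs.pa_morning, obs.st_afternoon, obs.pa_afternoon, sd_ref, spec
    )
    return CompensationLabel(
        unit_id=f"{obs.participant_id}:{obs.date.isoformat()}",
        analysis="observation",
        participant_id=obs.participant_id,
        date=obs.date,
        eligibility=eligibility,
        label=label,
        delta=delta,
        threshold=threshold,
    )


def classify_week(
    girl: GirlWeekSummary, sd_ref: float, spec: ThresholdSpec | None = None
) -> CompensationLabel:
    """Classify a girl's weekday-vs-weekend week."""
    spec = spec or ThresholdSpec()
    eligibility, label, delta, threshold = _classify_pair(
        girl.st_weekday, girl.pa_weekday, girl.st_weekend, girl.pa_weekend, sd_ref, spec
    )
    return CompensationLabel(
        unit_id=f"{girl.participant_id}:week",
        analysis="week",
        participant_id=girl.participant_id,
        date=None,
        eligibility=eligibility,
        label=label,
        delta=delta,
        threshold=threshold,
    )


def build_units(
    exposures: pd.DataFrame,
    validity: dict[str, ValidityVerdict] | list[ValidityVerdict],
    min_weekdays: int = 3,
    min_weekend_days: int = 1,
) -> tuple[list[ObservationPoint], list[GirlWeekSummary]]:
    """Construct comparison units from the tidy per-segment exposure table.

    Only participants whose validity verdict is positive contribute.  An
    observation point requires both the morning and afternoon segment of a
    weekday date to be valid.  A girl-week summary pools worn minutes over
    all her valid weekday segments and all her valid weekend segments, then
    recomputes proportions (wear-time-weighted pooling); girls lacking the
    required number of contributing days are logged and skipped.
    """
    if isinstance(validity, list):
        validity = {v.participant_id: v for v in validity}
    valid_pids = {pid for pid, v in validity.items() if v.valid}
    obs_points: list[ObservationPoint] = []
    week_summaries: list[GirlWeekSummary] = []
    if exposures.empty:
        return obs_points, week_summaries
    usable = exposures[exposures["participant_id"].isin(valid_pids) & exposures["valid"]]
    for pid, girl in usable.groupby("participant_id", sort=True):
        # morning/afternoon pairing per weekday date
        weekday_rows = girl[girl["day_type"] == "weekday"]
        by_date = {
            date: dict(zip(rows["segment"], rows.index))
            for date, rows in weekday_rows.groupby("date", sort=True)
        }
        for date, segs in by_date.items():
            if "morning" in segs and "afternoon" in segs:
                m = girl.loc[segs["morning"]]
                a = girl.loc[segs["afternoon"]]
                obs_points.append(
                    ObservationPoint(
                        participant_id=pid,
                        date=dt.date.fromisoformat(date),
                        st_morning=m["st_prop"],
                        lpa_morning=m["lpa_prop"],
                        mvpa_morning=m["mvpa_prop"],
                        st_afternoon=a["st_prop"],
                        lpa_afternoon=a["lpa_prop"],
                        mvpa_afternoon=a["mvpa_prop"],
                    )
                )
        weekend_rows = girl[girl["day_type"] == "weekend"]
        n_wd = weekday_rows["date"].nunique()
        n_we = weekend_rows["date"].nunique()
        if n_wd < min_weekdays or n_we < min_weekend_days:
            logger.info(
                "participant %s: no week summary (%d weekday dates, %d weekend dates)",
                pid,
                n_wd,
                n_we,
            )
            continue
        week_summaries.append(
            GirlWeekSummary(
                participant_id=pid,
                **_pooled_props(weekday_rows, "weekday"),
                **_pooled_props(weekend_rows, "weekend"),
                n_weekdays=n_wd,
                n_weekend_days=n_we,
            )
        )
    return obs_points, week_summaries


def _pooled_props(rows: pd.DataFrame, suffix: str) -> dict[str, float]:
    wear = int(rows["wear_minutes"].sum())
    st = int(rows["st_minutes"].sum())
    lpa = int(rows["lpa_minutes"].sum())
    mvpa = int(rows["mvpa_minutes"].sum())
    return {
        f"st_{suffix}": st / wear,
        f"lpa_{suffix}": lpa / wear,
        f"mvpa_{suffix}": mvpa / wear,
    }


def classify_cohort(
    obs_points: list[ObservationPoint],
    week_summaries: list[GirlWeekSummary],
    spec: ThresholdSpec | None = None,
) -> tuple[list[CompensationLabel], list[CompensationLabel], float, float]:
    """Classify all units; returns (obs labels, week labels, sd_obs, sd_week).

    The reference sd of each analysis is pooled across that analysis's valid
    units (morning PA for observation points, weekday PA for weeks).
    """
    spec = spec or ThresholdSpec()
    sd_obs = sd_week = float("nan")
    obs_labels: list[CompensationLabel] = []
    week_labels: list[CompensationLabel] = []
    if len(obs_points) >= 2:
        sd_obs = reference_sd([o.pa_morning for o in obs_points])
        obs_labels = [classify_observation(o, sd_obs, spec) for o in obs_points]
    elif obs_points:
        logger.warning("observation analysis skipped: %d unit(s) cannot yield a reference sd",
                       len(obs_points))
    if len(week_summaries) >= 2:
        sd_week = reference_sd([w.pa_weekday for w in week_summaries])
        week_labels = [classify_week(w, sd_week, spec) for w in week_summaries]
    elif week_summaries:
        logger.warning("week analysis skipped: %d unit(s) cannot yield a reference sd",
                       len(week_summaries))
    return obs_labels, week_labels, sd_obs, sd_week


def labels_to_frame(labels: list[CompensationLabel]) -> pd.DataFrame:
    rows = []
    for lb in labels:
        row = dataclasses.asdict(lb)
        row["date"] = lb.date.isoformat() if lb.date else ""
        rows.append(row)
    return pd.DataFrame(rows)
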