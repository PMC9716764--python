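"""Time-window segmentation, cut-point intensity classification and exposures.

Weekdays split into a morning window [07:00, 13:00) and an afternoon window
[13:00, 21:00); weekend days carry a single [07:00, 21:00) window.  Intervals
are half-open in local wall-clock time.  Worn minutes inside a window are
classified into sedentary time (ST), light physical activity (LPA) and
moderate-to-vigorous physical activity (MVPA) by counts-per-minute
cut-points; exposures are reported both as minutes and as proportions of
worn time ("relative wear time").

The default cut-points are the hip-worn youth calibration: ST <= 180 cpm,
LPA 181-3360 cpm, MVPA >= 3361 cpm (cpm = 180 itself is assigned to ST,
closing the published ranges' one-integer gap conservatively toward ST).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np
import pandas as pd

from .accel_io import EpochSeries
from .errors import DataError
from .preprocessing import WearMask, _minute_axes, day_type

ST, LPA, MVPA = "ST", "LPA", "MVPA"
_CATEGORIES = (ST, LPA, MVPA)


@dataclasses.dataclass(frozen=True)
class CutPointSpec:
    """Contiguous cpm cut-points; every non-negative cpm maps to one category."""

    sedentary_max: int = 180
    light_min: int = 181
    light_max: int = 3360
    mvpa_min: int = 3361

    def __post_init__(self) -> None:
        ok = (
            0 <= self.sedentary_max < self.light_min <= self.light_max < self.mvpa_min
            and self.light_min == self.sedentary_max + 1
            and self.mvpa_min == self.light_max + 1
        )
        if not ok:
            raise DataError(f"cut-points do not partition the non-negative integers: {self}")


@dataclasses.dataclass(frozen=True)
class Window:
    name: str
    start_min: int  # minutes from midnight, inclusive
    end_min: int  # exclusive

    @property
    def length(self) -> int:
        return self.end_min - self.start_min


_WEEKDAY_WINDOWS = (Window("morning", 7 * 60, 13 * 60), Window("afternoon", 13 * 60, 21 * 60))
_WEEKEND_WINDOWS = (Window("weekend_day", 7 * 60, 21 * 60),)


def segment_windows(date: dt.date) -> tuple[Window, ...]:
    """Analysis windows for a calendar date (weekday vs weekend)."""
    return _WEEKEND_WINDOWS if day_type(date) == "weekend" else _WEEKDAY_WINDOWS


def classify_minute(cpm: int, cuts: CutPointSpec | None = None) -> str:
    """Intensity category of a single counts-per-minute value."""
    cuts = cuts or CutPointSpec()
    if cpm < 0:
        raise DataError(f"negative cpm {cpm}")
    if cpm <= cuts.sedentary_max:
        return ST
    if cpm <= cuts.light_max:
        return LPA
    return MVPA


def classify_counts(counts: np.ndarray, cuts: CutPointSpec | None = None) -> np.ndarray:
    """Vectorised category codes (0 = ST, 1 = LPA, 2 = MVPA)."""
    cuts = cuts or CutPointSpec()
    codes = np.zeros(counts.shape, dtype=np.int8)
    codes[counts > cuts.sedentary_max] = 1
    codes[counts > cuts.light_max] = 2
    return codes


@dataclasses.dataclass
class SegmentExposure:
    """Worn-minute exposure of one (participant, date, window)."""

    participant_id: str
    date: dt.date
    segment: str  # morning | afternoon | weekend_day
    wear_minutes: int
    st_minutes: int
    lpa_minutes: int
    mvpa_minutes: int
    st_prop: float
    lpa_prop: float
    mvpa_prop: float
    valid: bool

    @property
    def day_type(self) -> str:
        return day_type(self.date)


def compute_exposure(
    series: EpochSeries,
    mask: WearMask,
    date: dt.date,
    window: Window,
    cuts: CutPointSpec | None = None,
    min_segment_wear_min: int = 60,
) -> SegmentExposure:
    """Exposure of a single window on a single date."""
    cuts = cuts or CutPointSpec()
    if len(series) != mask.worn.size:
        raise DataError("series and wear mask are not aligned")
    day_ord, tod = _minute_axes(series)
    sel = (
        (day_ord == date.toordinal())
        & (tod >= window.start_min)
        & (tod < window.end_min)
        & mask.worn
    )
    return _exposure_from_selection(series, cuts, min_segment_wear_min, date, window.name, sel)


def _exposure_from_selection(series, cuts, min_wear, date, segment, sel) -> SegmentExposure:
    codes = classify_counts(series.counts[sel], cuts)
    wear = int(sel.sum())
    st = int((codes == 0).sum())
    lpa = int((codes == 1).sum())
    mvpa = int((codes == 2).sum())
    if wear > 0:
        props = (st / wear, lpa / wear, mvpa / wear)
    else:
        props = (math.nan, math.nan, math.nan)
    return SegmentExposure(
        participant_id=series.participant_id,
        date=date,
        segment=segment,
        wear_minutes=wear,
        st_minutes=st,
        lpa_minutes=lpa,
        mvpa_minutes=mvpa,
        st_prop=props[0],
        lpa_prop=props[1],
        mvpa_prop=props[2],
        valid=wear >= max(min_wear, 1),
    )


def compute_exposures(
    series: EpochSeries,
    mask: WearMask,
    cuts: CutPointSpec | None = None,
    min_segment_wear_min: int = 60,
) -> list[SegmentExposure]:
    """Exposures for every (date, window) covered by the series."""
    cuts = cuts or CutPointSpec()
    if len(series) != mask.worn.size:
        raise DataError("series and wear mask are not aligned")
    day_ord, tod = _minute_axes(series)
    out: list[SegmentExposure] = []
    for day in np.unique(day_ord):
        date = dt.date.fromordinal(int(day))
        in_day = day_ord == day
        for w in segment_windows(date):
            sel = in_day & (tod >= w.start_min) & (tod < w.end_min) & mask.worn
            out.append(
                _exposure_from_selection(series, cuts, min_segment_wear_min, date, w.name, sel)
            )
    return out


def exposures_to_frame(exposures: list[SegmentExposure]) -> pd.DataFrame:
    """Tidy per-segment table (one row per participant/date/segment)."""
    rows = [dataclasses.asdict(e) | {"day_type": e.day_type} for e in exposures]
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["date"] = frame["date"].astype(str)
    return frame
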