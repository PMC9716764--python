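"""Non-wear detection and participant-level validity filtering.

The non-wear rule follows the Choi-style definition used for hip-worn
ActiGraph data in youth studies: a non-wear bout is at least 90 consecutive
minutes of zero counts per minute, tolerating up to 2 interruption minutes of
1-99 cpm in total per bout, provided every interruption is flanked by at
least 30 consecutive zero-cpm minutes on both sides.  A minute at or above
100 cpm is always wear and terminates any bout.  Tolerated interruption
minutes inside an accepted bout are themselves marked non-wear.

A participant's week is valid when at least 8 h (480 min) of wear were
recorded on at least three weekdays and one weekend day; wear anywhere in the
24 h day counts toward the 8 h, not only wear inside the analysis windows.
Bouts may span midnight — minutes are attributed to calendar dates only after
masking.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np

from .accel_io import EpochSeries
from .errors import DataError

#: cpm at or above which a minute is unconditionally wear.
ACTIVITY_CPM = 100


@dataclasses.dataclass(frozen=True)
class NonwearParams:
    """Tunable constants of the non-wear rule (minutes)."""

    window_min: int = 90
    tolerance_min: int = 2
    flank_min: int = 30

    def __post_init__(self) -> None:
        if self.window_min < 1 or self.tolerance_min < 0 or self.flank_min < 0:
            raise DataError("non-wear parameters out of range")


@dataclasses.dataclass(frozen=True, eq=False)
class WearMask:
    """Per-minute wear flags aligned 1:1 with a 60 s EpochSeries."""

    participant_id: str
    epoch_length: int
    worn: np.ndarray  # bool, True = worn

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WearMask):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.epoch_length == other.epoch_length
            and np.array_equal(self.worn, other.worn)
        )

    def nonwear_minutes(self) -> int:
        return int((~self.worn).sum())


@dataclasses.dataclass(frozen=True)
class ValidityParams:
    min_wear_min: int = 480
    min_weekdays: int = 3
    min_weekend_days: int = 1


@dataclasses.dataclass
class DayWearRecord:
    participant_id: str
    date: dt.date
    day_type: str  # "weekday" | "weekend"
    wear_minutes_total: int
    wear_minutes_by_window: dict[str, int]


@dataclasses.dataclass
class ValidityVerdict:
    participant_id: str
    valid: bool
    reason: str | None
    n_valid_weekdays: int
    n_valid_weekend_days: int


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def detect_nonwear(series: EpochSeries, params: NonwearParams | None = None) -> WearMask:
    """Flag non-wear minutes of a 60 s series.

    Within each maximal run of sub-100 cpm minutes, the run decomposes into
    zero-cpm segments separated by interruption groups (maximal runs of
    1-99 cpm).  A bout is any zero segment of >= ``window_min`` minutes, or a
    stretch spanning one or more consecutive interruption groups whose total
    interruption minutes do not exceed ``tolerance_min`` and whose every
    flanking zero segment (including both ends) is >= ``flank_min`` minutes,
    provided the stretch reaches ``window_min`` minutes.  The union of all
    such bouts is marked non-wear.
    """
    params = params or NonwearParams()
    if series.epoch_length != 60:
        raise DataError(f"non-wear detection requires 60 s epochs, got {series.epoch_length} s")
    counts = series.counts
    nonwear = np.zeros(len(counts), dtype=bool)
    for run_start, run_end in _bool_runs(counts < ACTIVITY_CPM):
        _mark_run(counts, run_start, run_end, nonwear, params)
    return WearMask(series.participant_id, 60, ~nonwear)


def _mark_run(
    counts: np.ndarray, start: int, end: int, nonwear: np.ndarray, p: NonwearParams
) -> None:
    # Decompose [start, end) into alternating zero segments z[0..k] and
    # interruption groups g[1..k]; z segments at the edges may be empty.
    seg = counts[start:end]
    nz_runs = _bool_runs(seg > 0)
    # zero segment m sits before group m+1; z[k] trails the last group
    z_bounds: list[tuple[int, int]] = []
    groups: list[tuple[int, int]] = []
    pos = 0
    for gs, ge in nz_runs:
        z_bounds.append((pos, gs))
        groups.append((gs, ge))
        pos = ge
    z_bounds.append((pos, len(seg)))

    # zero-only bouts
    for zs, ze in z_bounds:
        if ze - zs >= p.window_min:
            nonwear[start + zs : start + ze] = True

    z_len = [ze - zs for zs, ze in z_bounds]
    g_len = [ge - gs for gs, ge in groups]
    k = len(groups)
    for i in range(k):
        if z_len[i] < p.flank_min:
            continue  # left flank of g[i] insufficient for any range starting here
        total = 0
        for j in range(i, k):
            total += g_len[j]
            if total > p.tolerance_min:
                break
            if z_len[j + 1] < p.flank_min:
                # z[j+1] fails as trailing flank now and as interior flank later
                break
            bout_start = z_bounds[i][0]
            bout_end = z_bounds[j + 1][1]
            if bout_end - bout_start >= p.window_min:
                nonwear[start + bout_start : start + bout_end] = True


def _minute_axes(series: EpochSeries) -> tuple[np.ndarray, np.ndarray]:
    """(day ordinal, minute-of-day) per epoch of a minute-aligned 60 s series."""
    if series.epoch_length != 60:
        raise DataError("per-day accounting requires 60 s epochs")
    if series.start.second != 0:
        raise DataError("60 s series must start on a minute boundary")
    start_abs = series.start.date().toordinal() * 1440 + series.start.hour * 60 + series.start.minute
    abs_minute = start_abs + np.arange(len(series))
    return abs_minute // 1440, abs_minute % 1440


def day_type(date: dt.date) -> str:
    return "weekend" if date.weekday() >= 5 else "weekday"


def day_wear_summary(
    series: EpochSeries,
    mask: WearMask,
    windows=None,
) -> list[DayWearRecord]:
    """Per calendar date: total worn minutes and worn minutes per analysis window.

    ``windows`` maps a date to a sequence of window objects with ``name``,
    ``start_min`` and ``end_min`` attributes (minutes from midnight); defaults
    to the study's morning/afternoon/weekend windows.
    """
    if windows is None:
        from .exposure import segment_windows as windows  # default window set
    if len(series) != mask.worn.size:
        raise DataError("series and wear mask are not aligned")
    day_ord, tod = _minute_axes(series)
    records: list[DayWearRecord] = []
    for day in np.unique(day_ord):
        date = dt.date.fromordinal(int(day))
        in_day = day_ord == day
        worn_day = mask.worn & in_day
        by_window: dict[str, int] = {}
        for w in windows(date):
            in_win = worn_day & (tod >= w.start_min) & (tod < w.end_min)
            by_window[w.name] = int(in_win.sum())
        records.append(
            DayWearRecord(
                participant_id=series.participant_id,
                date=date,
                day_type=day_type(date),
                wear_minutes_total=int(worn_day.sum()),
                wear_minutes_by_window=by_window,
            )
        )
    return records


def validate_participant(
    records: list[DayWearRecord], params: ValidityParams | None = None
) -> ValidityVerdict:
    """Apply the >=8 h on >=3 weekdays + >=1 weekend day rule."""
    params = params or ValidityParams()
    if not records:
        return ValidityVerdict("", False, "no wear records", 0, 0)
    pid = records[0].participant_id
    n_wd = sum(
        1
        for r in records
        if r.day_type == "weekday" and r.wear_minutes_total >= params.min_wear_min
    )
    n_we = sum(
        1
        for r in records
        if r.day_type == "weekend" and r.wear_minutes_total >= params.min_wear_min
    )
    reasons = []
    if n_wd < params.min_weekdays:
        reasons.append(f"weekdays < {params.min_weekdays}")
    if n_we < params.min_weekend_days:
        reasons.append(f"weekend days < {params.min_weekend_days}")
    return ValidityVerdict(pid, not reasons, "; ".join(reasons) or None, n_wd, n_we)
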