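"""Synthetic accelerometer cohorts with planted compensation phenotypes.

The generator emulates the structure the analysis assumes: each girl wears
the device for seven consecutive days from ``wear_start`` to ``wear_end``
local time (zero counts overnight, which the non-wear detector picks up as
long non-wear bouts), with diurnal activity inside the 07:00-21:00 analysis
windows and a configurable chance of an extra planted non-wear bout in the
late evening, outside the analysis windows.

Phenotypes are planted on *proportions*: all planted proportions live on a
1/120 grid, which the 360-, 480- and 840-minute analysis windows realise
exactly as whole-minute schedules, so the ground truth is exact at the level
the classifier consumes.  Day-to-day jitter is applied to the reference
period (weekday mornings); afternoons carry the planted morning-to-afternoon
shift exactly, and the two weekend days receive antithetic (mean-preserving)
jitter around the planted weekly target so the pooled weekend aggregate
carries the planted weekday-to-weekend shift exactly (up to grid
quantisation, below half a grid step).

A "none" phenotype is realised as an exact morning/afternoon tie for the
observation analysis; for the week analysis an exact tie is unattainable
(the weekday and weekend aggregates have incompatible minute denominators),
so "none" is planted as a small sub-threshold activity increase, which the
classifier must also label none.

Per-minute counts are drawn from ranges strictly inside the cut-point
categories (ST 0-150, LPA 300-3000, MVPA 3600-8000 cpm) so boundary
conventions can never flip a synthetic classification.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .accel_io import EpochSeries, write_epoch_csv
from .compensation import ObservationPoint
from .errors import ConfigError, DataError

#: planted proportions live on this grid; 360/480/840-minute windows are
#: exact multiples, so grid proportions realise as whole minutes everywhere.
GRID = 120

_CPM_RANGES = {"ST": (0, 150), "LPA": (300, 3000), "MVPA": (3600, 8000)}
_MORNING = (7 * 60, 13 * 60)
_AFTERNOON = (13 * 60, 21 * 60)
_WEEKEND = (7 * 60, 21 * 60)

PHENOTYPES = ("positive", "negative", "none")


@dataclasses.dataclass(frozen=True)
class PhenotypeMix:
    positive: float = 0.15
    negative: float = 0.55
    none: float = 0.30

    def __post_init__(self) -> None:
        probs = (self.positive, self.negative, self.none)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(f"phenotype mix must be non-negative and sum to 1: {probs}")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.positive, self.negative, self.none)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    ``noise_sd`` is the day-to-day jitter of the active-time proportion of
    the reference period and therefore the implied reference sd of the
    observation analysis.  ``effect_size`` is the planted |PA shift| in units
    of each analysis's implied reference sd.
    """

    n_girls: int
    seed: int
    start_date: dt.date = dt.date(2018, 10, 1)
    epoch_length: int = 60
    weekday_mix: PhenotypeMix = PhenotypeMix()
    weekend_mix: PhenotypeMix = PhenotypeMix()
    effect_size: float = 3.0
    noise_sd: float = 0.02
    nonwear_bouts_per_day: float = 0.3
    profiles: dict = dataclasses.field(
        default_factory=lambda: {
            "morning": (0.66, 0.24, 0.10),
            "afternoon": (0.66, 0.24, 0.10),
            "weekend_day": (0.66, 0.24, 0.10),
        }
    )
    mvpa_share: float = 0.30
    wear_start_min: int = 6 * 60
    wear_end_min: int = 23 * 60
    none_shift_frac: float = 0.5  # weekend "none" shift, as a fraction of z*sd
    plan_z: float = 1.645

    def __post_init__(self) -> None:
        if self.n_girls < 1:
            raise ConfigError("n_girls must be >= 1")
        if self.epoch_length not in (1, 60):
            raise ConfigError("epoch_length must be 1 or 60 s")
        if not 0.0 <= self.nonwear_bouts_per_day <= 1.0:
            raise ConfigError("nonwear_bouts_per_day is a per-day probability in [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ConfigError("noise_sd and effect_size must be non-negative")
        for name, triplet in self.profiles.items():
            if len(triplet) != 3 or abs(sum(triplet) - 1.0) > 1e-9 or min(triplet) < 0:
                raise ConfigError(f"profile {name!r} must be a (st, lpa, mvpa) triplet summing to 1")
        if not self.wear_start_min < _MORNING[0] < _WEEKEND[1] < self.wear_end_min:
            raise ConfigError("wear schedule must enclose the 07:00-21:00 analysis windows")

    @property
    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(7)]

    @property
    def weekday_dates(self) -> list[dt.date]:
        return [d for d in self.dates if d.weekday() < 5]

    @property
    def weekend_dates(self) -> list[dt.date]:
        return [d for d in self.dates if d.weekday() >= 5]


def implied_reference_sd_observation(cfg: CohortConfig) -> float:
    """Expected cohort sd of morning PA proportions (= the planted jitter)."""
    return cfg.noise_sd


def _weekday_shift_units(cfg: CohortConfig) -> int:
    return round(cfg.effect_size * cfg.noise_sd * GRID)


def implied_reference_sd_week(cfg: CohortConfig) -> float:
    """Expected cohort sd of pooled weekday PA proportions.

    Weekday PA pools five days of morning (360 min) + afternoon (480 min)
    windows; afternoons carry the weekday phenotype shift, so the mix itself
    contributes between-girl variance on top of the averaged-down jitter.
    """
    n_wd = 5
    s = _weekday_shift_units(cfg) / GRID
    offset = _profile_pa(cfg, "afternoon") - _profile_pa(cfg, "morning")
    p_pos, p_neg, p_none = cfg.weekday_mix.probs
    values = np.array([offset + s, offset - s, offset])
    probs = np.array([p_pos, p_neg, p_none])
    var_mix = float(np.sum(probs * values**2) - np.sum(probs * values) ** 2)
    w_afternoon = _AFTERNOON[1] - _AFTERNOON[0]
    w_day = w_afternoon + (_MORNING[1] - _MORNING[0])
    return math.sqrt(cfg.noise_sd**2 / n_wd + (w_afternoon / w_day) ** 2 * var_mix)


def _profile_pa(cfg: CohortConfig, segment: str) -> float:
    st, lpa, mvpa = cfg.profiles[segment]
    return lpa + mvpa


@dataclasses.dataclass
class CohortResult:
    out_dir: Path
    files: list[Path]
    manifest: pd.DataFrame
    participants: pd.DataFrame


def generate_cohort(cfg: CohortConfig, out_dir: str | Path) -> CohortResult:
    """Write one epoch CSV per girl plus ground-truth and participant tables.

    All randomness flows from ``cfg.seed``; the same config produces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    files: list[Path] = []
    manifest_rows: list[dict] = []
    participant_rows: list[dict] = []
    for g in range(cfg.n_girls):
        pid = f"P{g + 1:04d}"
        series, truth = _generate_girl(cfg, rng, pid)
        path = out_dir / f"{pid}.csv"
        write_epoch_csv(series, path)
        files.append(path)
        manifest_rows.extend(truth["units"])
        participant_rows.append(truth["participant"])
    manifest = pd.DataFrame(manifest_rows)
    participants = pd.DataFrame(participant_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    participants.to_csv(out_dir / "participants.csv", index=False)
    (out_dir / "generation_log.txt").write_text(
        f"seed,{cfg.seed}\nn_girls,{cfg.n_girls}\nstart_date,{cfg.start_date}\n"
        f"epoch_length,{cfg.epoch_length}\neffect_size,{cfg.effect_size}\n"
        f"noise_sd,{cfg.noise_sd}\n",
        encoding="utf-8",
    )
    return CohortResult(out_dir, files, manifest, participants)


def _grid_units(p: float) -> int:
    return int(round(p * GRID))


def _split_units(cfg: CohortConfig, pa_units: int) -> tuple[int, int, int]:
    """(st, lpa, mvpa) grid units of a window given its PA composite units."""
    mvpa = int(round(cfg.mvpa_share * pa_units))
    lpa = pa_units - mvpa
    st = GRID - pa_units
    return st, lpa, mvpa


def _clip_units(units: int, lo: int = 1, hi: int = GRID - 1) -> int:
    return max(lo, min(hi, units))


def _generate_girl(cfg: CohortConfig, rng: np.random.Generator, pid: str):
    age = round(float(np.clip(rng.normal(11.6, 0.5), 9.0, 14.0)), 1)
    bmi = round(float(np.clip(rng.normal(19.5, 3.7), 12.0, 40.0)), 1)
    phen_wd = rng.choice(PHENOTYPES, p=cfg.weekday_mix.probs)
    phen_we = rng.choice(PHENOTYPES, p=cfg.weekend_mix.probs)

    s_units = _weekday_shift_units(cfg)
    sign_wd = {"positive": 1, "negative": -1, "none": 0}[phen_wd]
    base_pa = _profile_pa(cfg, "morning")
    offset_units = _grid_units(_profile_pa(cfg, "afternoon")) - _grid_units(base_pa)
    planted_aft = base_pa + (offset_units + sign_wd * s_units) / GRID
    if not (1 / GRID <= planted_aft <= 1 - 1 / GRID):
        raise DataError(
            f"infeasible config: planted afternoon PA proportion {planted_aft:.3f} "
            f"outside (0, 1)"
        )

    # per-(date, window) category minutes, keyed by (date, (start, end))
    schedule: dict[tuple[dt.date, tuple[int, int]], tuple[int, int, int]] = {}
    units: list[dict] = []
    wd_pa_minutes = 0
    wd_total_minutes = 0
    shift_total = offset_units + sign_wd * s_units
    lo = _clip_units(1 - min(0, shift_total))
    hi = _clip_units(GRID - 1 - max(0, shift_total))
    for date in cfg.weekday_dates:
        eps = rng.normal(0.0, cfg.noise_sd)
        m_units = _clip_units(_grid_units(base_pa + eps), lo, hi)
        a_units = m_units + shift_total
        m_len = _MORNING[1] - _MORNING[0]
        a_len = _AFTERNOON[1] - _AFTERNOON[0]
        schedule[(date, _MORNING)] = tuple(
            u * (m_len // GRID) for u in _split_units(cfg, m_units)
        )
        schedule[(date, _AFTERNOON)] = tuple(
            u * (a_len // GRID) for u in _split_units(cfg, a_units)
        )
        wd_pa_minutes += m_units * (m_len // GRID) + a_units * (a_len // GRID)
        wd_total_minutes += m_len + a_len
        units.append(
            {"analysis": "observation", "participant_id": pid, "date": date.isoformat(), "planted": phen_wd}
        )

    # weekend: shift relative to the girl's realised pooled weekday PA
    p_wd = wd_pa_minutes / wd_total_minutes
    sd_week = implied_reference_sd_week(cfg)
    if phen_we == "positive":
        shift_we = cfg.effect_size * sd_week
    elif phen_we == "negative":
        shift_we = -cfg.effect_size * sd_week
    else:
        shift_we = cfg.none_shift_frac * cfg.plan_z * sd_week
    target = p_wd + shift_we
    if not (1 / GRID <= target <= 1 - 1 / GRID):
        raise DataError(
            f"infeasible config: planted weekend PA proportion {target:.3f} outside (0, 1)"
        )
    eps_we = rng.normal(0.0, cfg.noise_sd)
    we_len = _WEEKEND[1] - _WEEKEND[0]
    for date, eps in zip(cfg.weekend_dates, (eps_we, -eps_we)):
        d_units = _clip_units(_grid_units(target + eps))
        schedule[(date, _WEEKEND)] = tuple(
            u * (we_len // GRID) for u in _split_units(cfg, d_units)
        )
    units.append(
        {"analysis": "week", "participant_id": pid, "date": "", "planted": phen_we}
    )

    series = _realise_series(cfg, rng, pid, schedule)
    return series, {
        "units": units,
        "participant": {
            "participant_id": pid,
            "age": age,
            "bmi": bmi,
            "weekday_phenotype": phen_wd,
            "weekend_phenotype": phen_we,
        },
    }


def _window_minutes(cfg, rng, st_min: int, lpa_min: int, mvpa_min: int) -> np.ndarray:
    """Random per-minute cpm schedule realising the given category minutes."""
    labels = np.repeat(np.arange(3), [st_min, lpa_min, mvpa_min])
    labels = rng.permutation(labels)
    cpm = np.empty(labels.size, dtype=np.int64)
    for code, cat in enumerate(("ST", "LPA", "MVPA")):
        lo, hi = _CPM_RANGES[cat]
        sel = labels == code
        cpm[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))
    return cpm


def _realise_series(cfg, rng, pid, schedule) -> EpochSeries:
    start = dt.datetime.combine(cfg.start_date, dt.time(cfg.wear_start_min // 60, cfg.wear_start_min % 60))
    n_min = 6 * 1440 + (cfg.wear_end_min - cfg.wear_start_min)
    counts = np.zeros(n_min, dtype=np.int64)

    def idx(day: int, tod: int) -> int:
        return day * 1440 + tod - cfg.wear_start_min

    # analysis windows first (fixed rng order), then daily buffers and bouts
    for (date, (w_start, w_end)), (st_m, lpa_m, mvpa_m) in schedule.items():
        day = (date - cfg.start_date).days
        counts[idx(day, w_start) : idx(day, w_end)] = _window_minutes(
            cfg, rng, st_m, lpa_m, mvpa_m
        )
    for day in range(7):
        for b_start, b_end in (
            (cfg.wear_start_min, _WEEKEND[0]),
            (_WEEKEND[1], cfg.wear_end_min),
        ):
            counts[idx(day, b_start) : idx(day, b_end)] = rng.integers(
                200, 601, size=b_end - b_start
            )
        if rng.random() < cfg.nonwear_bouts_per_day:
            bout_start, bout_end = _WEEKEND[1] + 5, _WEEKEND[1] + 100  # 95 zero minutes
            if bout_end < cfg.wear_end_min:
                counts[idx(day, bout_start) : idx(day, bout_end)] = 0

    if cfg.epoch_length == 60:
        return EpochSeries(pid, start, 60, counts)
    # expand each minute's cpm into 60 one-second epochs summing back exactly
    q, r = np.divmod(counts, 60)
    seconds = np.repeat(q, 60).reshape(-1, 60)
    ramp = np.arange(60)[None, :]
    seconds += (ramp < r[:, None]).astype(np.int64)
    return EpochSeries(pid, start, 1, seconds.ravel())


def generate_worked_example() -> tuple[list[ObservationPoint], list[str], float]:
    """Three canonical morning/afternoon units: positive, negative, none.

    Returns ``(units, expected_labels, sd_ref)``; with the default threshold
    (z = 1.645, sd_ref = 0.05, so t = 0.08225) the units are built to land on
    the three outcomes.
    """
    sd_ref = 0.05
    units = [
        # less ST in the afternoon, PA up by 0.20 > t -> positive
        ObservationPoint("example_positive", dt.date(2018, 10, 1), 0.70, 0.20, 0.10, 0.50, 0.35, 0.15),
        # more ST in the afternoon, PA down by 0.15 < t -> negative
        ObservationPoint("example_negative", dt.date(2018, 10, 2), 0.60, 0.30, 0.10, 0.75, 0.18, 0.07),
        # less ST in the afternoon but PA up only 0.01 <= t -> none
        ObservationPoint("example_none", dt.date(2018, 10, 3), 0.70, 0.20, 0.10, 0.69, 0.205, 0.105),
    ]
    return units, ["positive", "negative", "none"], sd_ref
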