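"""Reading, writing and re-integrating epoch-level accelerometer count series.

An :class:`EpochSeries` is a gap-free stream of non-negative vertical-axis
activity counts at a fixed epoch length (1 s or 60 s in practice).  Two plain
CSV dialects are supported:

``headered``
    A small key/value header block followed by one count per line::

        participant,P001
        start,2018-10-01 07:00:00
        epoch,60
        counts
        0
        120
        4000

``timestamped``
    Two columns, one row per epoch::

        2018-10-01 07:00:00,0
        2018-10-01 07:01:00,120

Timestamps are naive local wall-clock time at second resolution
(``YYYY-MM-DD HH:MM:SS``); a calendar day is a date in that local clock.
Anything that does not match one of the two dialects is rejected rather than
guessed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np

from .errors import AccelParseError, DataError

TIME_FORMAT = "%Y-%m-%d %H:%M:%S"

_HEADER_KEYS = ("participant", "start", "epoch")


@dataclasses.dataclass(frozen=True, eq=False)
class EpochSeries:
    """One participant's gap-free activity-count stream.

    Epoch ``i`` covers ``[start + i*epoch_length, start + (i+1)*epoch_length)``.
    Counts are non-negative integers; the epoch length must divide 60 or be a
    multiple of 60 so that counts can always be bridged to counts per minute.
    """

    participant_id: str
    start: dt.datetime
    epoch_length: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        el = self.epoch_length
        if not isinstance(el, (int, np.integer)) or el <= 0:
            raise DataError(f"epoch_length must be a positive integer, got {el!r}")
        if 60 % el != 0 and el % 60 != 0:
            raise DataError(f"epoch_length must divide 60 or be a multiple of 60, got {el}")
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise DataError("counts must be one-dimensional")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise DataError("counts must be integers")
            counts = as_int
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise DataError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "epoch_length", int(el))

    def __len__(self) -> int:
        return int(self.counts.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.start == other.start
            and self.epoch_length == other.epoch_length
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(seconds=self.epoch_length * len(self))

    def total_count(self) -> int:
        return int(self.counts.sum())


def read_epoch_csv(
    path: str | Path,
    dialect: str = "auto",
    participant_id: str | None = None,
    epoch_length: int | None = None,
) -> EpochSeries:
    """Parse an epoch CSV file into an :class:`EpochSeries`.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"headered"``, ``"timestamped"`` or ``"auto"`` (inspect the first
        line; reject when neither candidate matches).
    participant_id:
        Overrides the participant id (defaults to the header value or, for the
        timestamped dialect, the file stem).
    epoch_length:
        Expected epoch length in seconds for the timestamped dialect.  When
        omitted it is inferred from the first two rows, which means a gap at
        row 2 can only be detected if a hint is supplied.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln.strip() for ln in lines if ln.strip()]
    if not lines:
        raise AccelParseError(f"{path}: empty file")

    if dialect == "auto":
        first_key = lines[0].split(",", 1)[0].strip().lower()
        if first_key in _HEADER_KEYS:
            dialect = "headered"
        elif _try_timestamp(lines[0].split(",", 1)[0]) is not None:
            dialect = "timestamped"
        else:
            raise AccelParseError(
                f"{path}: ambiguous or unknown dialect; first line matches neither the "
                f"'headered' dialect (key/value header block) nor the 'timestamped' "
                f"dialect (ISO timestamp, count)"
            )
    if dialect == "headered":
        return _read_headered(path, lines, participant_id)
    if dialect == "timestamped":
        return _read_timestamped(path, lines, participant_id, epoch_length)
    raise AccelParseError(f"unknown dialect {dialect!r}")


def _try_timestamp(text: str) -> dt.datetime | None:
    try:
        return dt.datetime.strptime(text.strip(), TIME_FORMAT)
    except ValueError:
        return None


def _read_headered(path: Path, lines: list[str], participant_id: str | None) -> EpochSeries:
    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].lower() != "counts":
        parts = lines[i].split(",", 1)
        if len(parts) != 2 or parts[0].strip().lower() not in _HEADER_KEYS:
            raise AccelParseError(f"{path}: line {i + 1}: malformed header line {lines[i]!r}")
        header[parts[0].strip().lower()] = parts[1].strip()
        i += 1
    if i == len(lines):
        raise AccelParseError(f"{path}: missing 'counts' marker line")
    for key in ("start", "epoch"):
        if key not in header:
            raise AccelParseError(f"{path}: header missing required key {key!r}")
    start = _try_timestamp(header["start"])
    if start is None:
        raise AccelParseError(f"{path}: malformed start timestamp {header['start']!r}")
    try:
        epoch = int(header["epoch"])
    except ValueError:
        raise AccelParseError(f"{path}: malformed epoch length {header['epoch']!r}") from None
    counts = np.empty(len(lines) - i - 1, dtype=np.int64)
    for row, line in enumerate(lines[i + 1 :], start=1):
        try:
            value = int(line)
        except ValueError:
            raise AccelParseError(f"{path}: count row {row}: not an integer: {line!r}") from None
        if value < 0:
            raise AccelParseError(f"{path}: count row {row}: negative count {value}")
        counts[row - 1] = value
    pid = participant_id or header.get("participant") or path.stem
    return EpochSeries(pid, start, epoch, counts)


def _read_timestamped(
    path: Path,
    lines: list[str],
    participant_id: str | None,
    epoch_length: int | None,
) -> EpochSeries:
    stamps: list[dt.datetime] = []
    counts = np.empty(len(lines), dtype=np.int64)
    for row, line in enumerate(lines, start=1):
        parts = line.split(",")
        if len(parts) != 2:
            raise AccelParseError(f"{path}: row {row}: expected 'timestamp,count', got {line!r}")
        ts = _try_timestamp(parts[0])
        if ts is None:
            raise AccelParseError(f"{path}: row {row}: malformed timestamp {parts[0]!r}")
        try:
            value = int(parts[1])
        except ValueError:
            raise AccelParseError(f"{path}: row {row}: not an integer count: {parts[1]!r}") from None
        if value < 0:
            raise AccelParseError(f"{path}: row {row}: negative count {value}")
        stamps.append(ts)
        counts[row - 1] = value

    if epoch_length is None:
        if len(stamps) < 2:
            raise AccelParseError(
                f"{path}: cannot infer epoch length from a single timestamped row; "
                f"pass epoch_length explicitly"
            )
        delta = (stamps[1] - stamps[0]).total_seconds()
        if delta <= 0 or delta != int(delta):
            raise AccelParseError(f"{path}: row 2: non-positive or fractional timestamp step")
        epoch_length = int(delta)
    start = stamps[0]
    for row, ts in enumerate(stamps, start=1):
        expected = start + dt.timedelta(seconds=(row - 1) * epoch_length)
        if ts != expected:
            raise AccelParseError(
                f"{path}: row {row}: timestamp gap; expected {expected:{TIME_FORMAT}}, "
                f"got {ts:{TIME_FORMAT}}"
            )
    pid = participant_id or path.stem
    return EpochSeries(pid, start, epoch_length, counts)


def write_epoch_csv(series: EpochSeries, path: str | Path, dialect: str = "headered") -> Path:
    """Write ``series`` to ``path``; ``read_epoch_csv`` round-trips the result.

    The output is byte-stable for a given series and dialect.  An empty series
    is not writable.
    """
    path = Path(path)
    if len(series) == 0:
        raise DataError("refusing to write an empty epoch series")
    if dialect == "headered":
        head = (
            f"participant,{series.participant_id}\n"
            f"start,{series.start:{TIME_FORMAT}}\n"
            f"epoch,{series.epoch_length}\n"
            "counts\n"
        )
        body = "\n".join(str(int(c)) for c in series.counts)
        text = head + body + "\n"
    elif dialect == "timestamped":
        rows = []
        for i, c in enumerate(series.counts):
            ts = series.start + dt.timedelta(seconds=i * series.epoch_length)
            rows.append(f"{ts:{TIME_FORMAT}},{int(c)}")
        text = "\n".join(rows) + "\n"
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    path.write_text(text, encoding="utf-8", newline="\n")
    return path


def reintegrate(series: EpochSeries, target_epoch: int) -> EpochSeries:
    """Sum blocks of epochs into coarser epochs (e.g. 1 s -> 60 s).

    ``target_epoch`` must be a positive multiple of the input epoch length and
    the series length must be a whole number of blocks; integer arithmetic
    throughout, so the total count is conserved exactly.
    """
    if target_epoch <= 0 or target_epoch % series.epoch_length != 0:
        raise DataError(
            f"target epoch {target_epoch} is not a positive multiple of "
            f"{series.epoch_length}"
        )
    ratio = target_epoch // series.epoch_length
    if ratio == 1:
        return EpochSeries(series.participant_id, series.start, target_epoch, series.counts.copy())
    if len(series) % ratio != 0:
        raise DataError(
            f"series length {len(series)} leaves a trailing partial block at "
            f"target epoch {target_epoch}"
        )
    summed = series.counts.reshape(-1, ratio).sum(axis=1)
    return EpochSeries(series.participant_id, series.start, target_epoch, summed)


def to_minutes(series: EpochSeries) -> EpochSeries:
    """Bridge a series to 60 s epochs (counts per minute) by summation."""
    if series.epoch_length == 60:
        return series
    if series.epoch_length > 60:
        raise DataError(f"cannot refine {series.epoch_length} s epochs to 60 s")
    return reintegrate(series, 60)
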