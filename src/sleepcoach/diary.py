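"""Electronic sleep diary: validation, nightly indicators, aggregation.

One diary entry describes a single night: the calendar date anchoring the
evening, the clock time at which the user intended to fall asleep, the
reported sleep onset latency (SOL, min), the number of awakenings (NWAK),
the reported wake after sleep onset (WASO, min, excluding SOL and terminal
wakefulness), the final wake-up clock time and the time of getting out of
bed.  From these the seven nocturnal indicators are derived:

    TIB  = arise - try_sleep            (time in bed, min)
    TWAK = arise - final_wake           (terminal wakefulness, min)
    TST  = TIB - SOL - WASO - TWAK      (total sleep time, min)
    SE   = 100 * TST / TIB              (sleep efficiency, %)

TST and SE are *always* derived, never user-entered, so the identity above
holds exactly for every accepted entry.  Entries whose reported wakefulness
exceeds the in-bed interval are rejected, not clamped.

Clock times carry no date; the noon-anchored convention resolves them:
times at or after 12:00 belong to the evening of ``night_date``, times
before 12:00 to the following morning.  This parses both early-evening and
post-midnight bedtimes without extra flags.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, fields as dc_fields
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

__all__ = [
    "DiaryError",
    "DiaryEntry",
    "NightIndicators",
    "FeedbackSummary",
    "resolve_timeline",
    "derive_night",
    "window_mean",
    "make_feedback",
    "diary_complete",
    "read_diary_csv",
    "write_diary_csv",
    "DIARY_CSV_COLUMNS",
]

NOON = time(12, 0)

DIARY_CSV_COLUMNS = (
    "night_date",
    "try_sleep_time",
    "reported_sol_min",
    "nwak",
    "reported_waso_min",
    "final_wake_time",
    "arise_time",
)


class DiaryError(ValueError):
    """An inconsistent or out-of-range diary entry."""


@dataclass(frozen=True)
class DiaryEntry:
    """One night's raw diary report (times are naive clock times)."""

    night_date: date
    try_sleep_time: time
    reported_sol_min: float
    nwak: int
    reported_waso_min: float
    final_wake_time: time
    arise_time: time

    def __post_init__(self) -> None:
        if self.reported_sol_min < 0:
            raise DiaryError(f"negative SOL ({self.reported_sol_min} min)")
        if self.reported_waso_min < 0:
            raise DiaryError(f"negative WASO ({self.reported_waso_min} min)")
        if self.nwak < 0:
            raise DiaryError(f"negative awakening count ({self.nwak})")


@dataclass(frozen=True)
class NightIndicators:
    """Derived nocturnal sleep indicators for one night (minutes / %)."""

    sol: float
    nwak: float  # fractional in window aggregates
    twak: float
    waso: float
    tib: float
    tst: float
    se: float


@dataclass(frozen=True)
class FeedbackSummary:
    """Morning feedback shown to the user (values copied, not re-derived)."""

    tib: float
    tst: float
    se: float
    tib_hhmm: str
    tst_hhmm: str
    se_text: str


def _anchor(clock: time, night: date) -> datetime:
    """Noon-anchored resolution: >= 12:00 is the evening of ``night``,
    < 12:00 the following morning."""
    day = night if clock >= NOON else night + timedelta(days=1)
    return datetime.combine(day, clock)


def resolve_timeline(entry: DiaryEntry) -> Tuple[datetime, datetime, datetime]:
    """Resolve the entry's clock times to ordered absolute instants.

    Returns ``(try_sleep, final_wake, arise)``.  Raises :class:`DiaryError`
    when the resolved instants are out of order or the in-bed interval is
    empty or spans a full day or more.
    """
    try_sleep = _anchor(entry.try_sleep_time, entry.night_date)
    final_wake = _anchor(entry.final_wake_time, entry.night_date)
    arise = _anchor(entry.arise_time, entry.night_date)
    if arise < final_wake:
        raise DiaryError(
            f"arise time {entry.arise_time} before final wake {entry.final_wake_time}"
        )
    if final_wake < try_sleep:
        raise DiaryError(
            f"final wake {entry.final_wake_time} before bedtime {entry.try_sleep_time}"
        )
    span = arise - try_sleep
    if not (timedelta(0) < span < timedelta(hours=24)):
        raise DiaryError(f"in-bed interval of {span} is not within (0, 24h)")
    return try_sleep, final_wake, arise


def derive_night(entry: DiaryEntry) -> NightIndicators:
    """Derive the seven indicators of one night from a raw entry.

    Rejects entries whose reported wakefulness (SOL + WASO + TWAK) exceeds
    the in-bed interval, which would make TST negative.
    """
    try_sleep, final_wake, arise = resolve_timeline(entry)
    tib = (arise - try_sleep).total_seconds() / 60.0
    twak = (arise - final_wake).total_seconds() / 60.0
    wake = entry.reported_sol_min + entry.reported_waso_min + twak
    if wake > tib:
        raise DiaryError(
            f"reported wakefulness ({wake:.0f} min: SOL {entry.reported_sol_min:.0f}"
            f" + WASO {entry.reported_waso_min:.0f} + TWAK {twak:.0f})"
            f" exceeds time in bed ({tib:.0f} min)"
        )
    tst = tib - entry.reported_sol_min - entry.reported_waso_min - twak
    return NightIndicators(
        sol=float(entry.reported_sol_min),
        nwak=float(entry.nwak),
        twak=twak,
        waso=float(entry.reported_waso_min),
        tib=tib,
        tst=tst,
        se=100.0 * tst / tib,
    )


Selector = Union[str, slice, Tuple[int, int]]


def window_mean(nights: Sequence[NightIndicators], selector: Selector = "all") -> NightIndicators:
    """Componentwise arithmetic mean over a window of nights.

    ``selector`` is ``"first2"``, ``"last2"``, ``"all"`` (alias ``"all7"``),
    a slice, or an ``(start, stop)`` index pair.  Nights are assumed to be
    in chronological order of completion.  NWAK may be fractional in the
    aggregate.  Raises :class:`DiaryError` on an empty or unsatisfiable
    selection.
    """
    if isinstance(selector, str):
        if selector == "first2":
            if len(nights) < 2:
                raise DiaryError("first2 window requires at least 2 nights")
            chosen = nights[:2]
        elif selector == "last2":
            if len(nights) < 2:
                raise DiaryError("last2 window requires at least 2 nights")
            chosen = nights[-2:]
        elif selector in ("all", "all7"):
            chosen = nights
        else:
            raise DiaryError(f"unknown window selector {selector!r}")
    elif isinstance(selector, slice):
        chosen = nights[selector]
    else:
        start, stop = selector
        chosen = nights[start:stop]
    if not chosen:
        raise DiaryError("empty night selection")
    n = len(chosen)

    def mean(attr: str) -> float:
        return sum(getattr(night, attr) for night in chosen) / n

    return NightIndicators(
        sol=mean("sol"),
        nwak=mean("nwak"),
        twak=mean("twak"),
        waso=mean("waso"),
        tib=mean("tib"),
        tst=mean("tst"),
        se=mean("se"),
    )


def _hhmm(minutes: float) -> str:
    """Render minutes as HH:MM, rounding half-up to the nearest minute."""
    total = int(math.floor(minutes + 0.5))
    return f"{total // 60:02d}:{total % 60:02d}"


def make_feedback(ind: NightIndicators) -> FeedbackSummary:
    """Morning feedback (time in bed, total sleep time, sleep efficiency)."""
    return FeedbackSummary(
        tib=ind.tib,
        tst=ind.tst,
        se=ind.se,
        tib_hhmm=_hhmm(ind.tib),
        tst_hhmm=_hhmm(ind.tst),
        se_text=f"{ind.se:.1f}",
    )


def diary_complete(entries: Iterable[DiaryEntry], required_days: int = 7) -> bool:
    """True when at least ``required_days`` validated entries exist.

    Entries that fail :func:`derive_night` do not count.  Days need not be
    consecutive.
    """
    if required_days < 1:
        raise ValueError("required_days must be >= 1")
    n = 0
    for entry in entries:
        try:
            derive_night(entry)
        except DiaryError:
            continue
        n += 1
        if n >= required_days:
            return True
    return False


# ---------------------------------------------------------------------------
# CSV interface: one row per night, ISO dates, HH:MM clock times
# ---------------------------------------------------------------------------


def _parse_clock(text: str) -> time:
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"clock time {text!r} is not HH:MM")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return time(h, m, s)


def parse_diary_row(row: dict) -> DiaryEntry:
    """Build a validated :class:`DiaryEntry` from a CSV row dict."""
    missing = [c for c in DIARY_CSV_COLUMNS if row.get(c) in (None, "")]
    if missing:
        raise DiaryError(f"missing field(s): {', '.join(missing)}")
    entry = DiaryEntry(
        night_date=date.fromisoformat(row["night_date"].strip()),
        try_sleep_time=_parse_clock(row["try_sleep_time"]),
        reported_sol_min=float(row["reported_sol_min"]),
        nwak=int(float(row["nwak"])),
        reported_waso_min=float(row["reported_waso_min"]),
        final_wake_time=_parse_clock(row["final_wake_time"]),
        arise_time=_parse_clock(row["arise_time"]),
    )
    derive_night(entry)  # full validation, including ordering and identity
    return entry


def read_diary_csv(
    source: Union[str, Path, io.TextIOBase],
    strict: bool = False,
) -> Tuple[List[DiaryEntry], List[Tuple[int, str]]]:
    """Read a diary CSV, validating each row.

    Returns ``(entries, errors)`` where ``errors`` is a list of
    ``(row_number, message)`` for rejected rows (row numbers count data rows
    from 1).  With ``strict=True`` the first bad row raises instead.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_diary_csv(fh, strict=strict)
    reader = csv.DictReader(source)
    entries: List[DiaryEntry] = []
    errors: List[Tuple[int, str]] = []
    for i, row in enumerate(reader, start=1):
        try:
            entries.append(parse_diary_row(row))
        except (DiaryError, ValueError) as exc:
            if strict:
                raise DiaryError(f"row {i}: {exc}") from exc
            errors.append((i, str(exc)))
    return entries, errors


def write_diary_csv(
    entries: Sequence[DiaryEntry], target: Union[str, Path, io.TextIOBase]
) -> None:
    """Write diary entries using the canonical CSV schema."""
    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            write_diary_csv(entries, fh)
            return
    writer = csv.writer(target)
    writer.writerow(DIARY_CSV_COLUMNS)
    for e in entries:
        writer.writerow(
            [
                e.night_date.isoformat(),
                e.try_sleep_time.strftime("%H:%M"),
                f"{e.reported_sol_min:g}",
                e.nwak,
                f"{e.reported_waso_min:g}",
                e.final_wake_time.strftime("%H:%M"),
                e.arise_time.strftime("%H:%M"),
            ]
        )
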