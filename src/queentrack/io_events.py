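"""Strict CSV readers and writers for every on-disk table.

Schemas (UTF-8, comma-separated, header required):

- ``reads.csv``:        nest_id,tag_id,time,board
- ``power.csv``:        nest_id,off_start,off_end
- ``queens.csv``:       queen_id,nest_id,species,year,tag_date,
                        brood_stage_at_tagging,fate,worker_first_forage_date,role
- ``observations.csv``: nest_id,time,direction,caste

Timestamps are ISO 8601 with an explicit UTC offset and are normalised to
UTC on read.  Readers never silently drop rows: every input row is either
parsed into a record, deduplicated (identical rows, counted), or rejected
with its 1-based line number and a reason.  With ``errors="raise"`` (the
default) any rejection aborts the load; with ``errors="collect"`` the
rejects are returned in the :class:`LoadResult` for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Generic, Sequence, TypeVar

import pandas as pd

from .records import (
    Board,
    BroodStage,
    Caste,
    Direction,
    ObservationEvent,
    PowerInterval,
    QueenRecord,
    RawRead,
    Role,
    Fate,
)

logger = logging.getLogger(__name__)

T = TypeVar("T")


class SchemaError(ValueError):
    """The file-level schema (header, required columns) does not match."""


class RowError(ValueError):
    """One or more rows failed validation; message lists line numbers."""


@dataclass
class Reject:
    line: int  # 1-based line number in the file (header is line 1)
    reason: str


@dataclass
class LoadResult(Generic[T]):
    records: list[T]
    rejected: list[Reject] = field(default_factory=list)
    n_deduplicated: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_parsed(self) -> int:
        """Input data rows = records + duplicates + rejects (conservation)."""
        return len(self.records) + self.n_deduplicated + len(self.rejected)


def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; header must be "
                          f"{','.join(columns)}")
    return df


def _parse_time(value: str):
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {value!r} lacks a UTC offset")
    return ts.tz_convert("UTC")


def _finish(result: LoadResult, errors: str, path) -> LoadResult:
    if result.rejected and errors == "raise":
        detail = "; ".join(f"line {r.line}: {r.reason}" for r in result.rejected[:10])
        raise RowError(f"{path}: {len(result.rejected)} invalid row(s): {detail}")
    if result.n_deduplicated:
        msg = f"{path}: dropped {result.n_deduplicated} duplicate identical row(s)"
        logger.warning(msg)
        result.warnings.append(msg)
    return result


def _load_rows(path, columns, build: Callable[[dict], T], errors: str) -> LoadResult[T]:
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    df = _read_table(path, columns)
    result: LoadResult[T] = LoadResult(records=[])
    seen: set[tuple] = set()
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        key = tuple(row[c] for c in columns)
        if key in seen:
            result.n_deduplicated += 1
            continue
        try:
            result.records.append(build(row))
        except (ValueError, KeyError) as exc:
            result.rejected.append(Reject(line=line, reason=str(exc)))
            continue
        seen.add(key)
    return _finish(result, errors, path)


# ---------------------------------------------------------------------------
# readers


READS_COLUMNS = ("nest_id", "tag_id", "time", "board")
POWER_COLUMNS = ("nest_id", "off_start", "off_end")
QUEENS_COLUMNS = (
    "queen_id", "nest_id", "species", "year", "tag_date",
    "brood_stage_at_tagging", "fate", "worker_first_forage_date", "role",
)
OBS_COLUMNS = ("nest_id", "time", "direction", "caste")
SESSIONS_COLUMNS = ("nest_id", "start", "end")


def read_raw_reads(path, errors: str = "raise") -> LoadResult[RawRead]:
    """Load antenna reads, sorted by (nest_id, tag_id, time, board).

    The board tie-break (INNER before OUTER at identical times) makes the
    ordering total and deterministic.  ``read_id`` is assigned after sorting.
    """

    def build(row: dict) -> RawRead:
        try:
            board = Board(row["board"])
        except ValueError:
            raise ValueError(f"board must be INNER or OUTER, got {row['board']!r}")
        return RawRead(
            nest_id=row["nest_id"],
            tag_id=row["tag_id"],
            time=_parse_time(row["time"]),
            board=board,
        )

    result = _load_rows(path, READS_COLUMNS, build, errors)
    result.records.sort(key=RawRead.sort_key)
    result.records = [
        RawRead(r.nest_id, r.tag_id, r.time, r.board, read_id=i)
        for i, r in enumerate(result.records)
    ]
    return result


def merge_power_intervals(intervals: Sequence[PowerInterval]) -> tuple[list[PowerInterval], int]:
    """Union overlapping/touching intervals per nest; returns (merged, n_merged_away)."""
    merged: list[PowerInterval] = []
    n_merged = 0
    by_nest: dict[str, list[PowerInterval]] = {}
    for iv in intervals:
        by_nest.setdefault(iv.nest_id, []).append(iv)
    for nest_id in sorted(by_nest):
        ivs = sorted(by_nest[nest_id], key=lambda p: (p.off_start, p.off_end))
        cur = ivs[0]
        for nxt in ivs[1:]:
            if nxt.off_start <= cur.off_end:  # overlap or touch
                n_merged += 1
                cur = PowerInterval(nest_id, cur.off_start, max(cur.off_end, nxt.off_end))
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    return merged, n_merged


def read_power_log(path, errors: str = "raise") -> LoadResult[PowerInterval]:
    """Load reader power-outage intervals; overlapping intervals are merged."""

    def build(row: dict) -> PowerInterval:
        return PowerInterval(
            nest_id=row["nest_id"],
            off_start=_parse_time(row["off_start"]),
            off_end=_parse_time(row["off_end"]),
        )

    result = _load_rows(path, POWER_COLUMNS, build, errors)
    merged, n_merged = merge_power_intervals(result.records)
    if n_merged:
        msg = f"{path}: merged {n_merged} overlapping power interval(s)"
        logger.warning(msg)
        result.warnings.append(msg)
    result.records = merged
    return result


def read_queens(path, errors: str = "raise") -> LoadResult[QueenRecord]:
    def build(row: dict) -> QueenRecord:
        wffd = row["worker_first_forage_date"]
        return QueenRecord(
            queen_id=row["queen_id"],
            nest_id=row["nest_id"],
            species=row["species"],
            year=int(row["year"]),
            tag_date=pd.Timestamp(row["tag_date"]),
            brood_stage_at_tagging=BroodStage(row["brood_stage_at_tagging"]),
            fate=Fate(row["fate"]),
            worker_first_forage_date=pd.Timestamp(wffd) if wffd else None,
            role=Role(row["role"]) if row["role"] else Role.RESIDENT,
        )

    result = _load_rows(path, QUEENS_COLUMNS, build, errors)
    for q in result.records:
        if q.fate in (Fate.WORKERS_NO_GYNES, Fate.GYNES) and q.worker_first_forage_date is None:
            msg = (f"queen {q.queen_id}: fate {q.fate.value} but no "
                   f"worker_first_forage_date; late-stage window cannot be anchored")
            logger.warning(msg)
            result.warnings.append(msg)
    return result


def read_observations(path, errors: str = "raise") -> LoadResult[ObservationEvent]:
    """Load in-person observation events (both castes pass through;
    queen-only analyses filter downstream)."""

    def build(row: dict) -> ObservationEvent:
        return ObservationEvent(
            nest_id=row["nest_id"],
            time=_parse_time(row["time"]),
            direction=Direction(row["direction"]),
            caste=Caste(row["caste"]),
        )

    result = _load_rows(path, OBS_COLUMNS, build, errors)
    result.records.sort(key=lambda o: (o.nest_id, o.time))
    return result


def read_sessions(path, errors: str = "raise") -> LoadResult[tuple]:
    """Load observation sessions as (nest_id, start, end) tuples."""

    def build(row: dict):
        start, end = _parse_time(row["start"]), _parse_time(row["end"])
        if not start < end:
            raise ValueError(f"session start {start} not before end {end}")
        return (row["nest_id"], start, end)

    result = _load_rows(path, SESSIONS_COLUMNS, build, errors)
    result.records.sort()
    return result


# ---------------------------------------------------------------------------
# writers (canonical formatting: ISO 8601 with +00:00 offset, '\n' endings)


def _fmt_time(ts: pd.Timestamp) -> str:
    return ts.tz_convert("UTC").isoformat()


def write_raw_reads(records: Sequence[RawRead], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(READS_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.nest_id},{r.tag_id},{_fmt_time(r.time)},{r.board.value}\n")


def write_power_log(records: Sequence[PowerInterval], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(POWER_COLUMNS) + "\n")
        for p in records:
            fh.write(f"{p.nest_id},{_fmt_time(p.off_start)},{_fmt_time(p.off_end)}\n")


def write_observations(records: Sequence[ObservationEvent], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(OBS_COLUMNS) + "\n")
        for o in records:
            fh.write(f"{o.nest_id},{_fmt_time(o.time)},{o.direction.value},{o.caste.value}\n")


def write_queens(records: Sequence[QueenRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(QUEENS_COLUMNS) + "\n")
        for q in records:
            wffd = q.worker_first_forage_date.date().isoformat() if q.worker_first_forage_date is not None else ""
            fh.write(
                f"{q.queen_id},{q.nest_id},{q.species},{q.year},"
                f"{q.tag_date.date().isoformat()},{q.brood_stage_at_tagging.value},"
                f"{q.fate.value},{wffd},{q.role.value}\n"
            )


def write_sessions(sessions, path) -> None:
    """Write observation sessions; accepts objects with nest_id/start/end."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(SESSIONS_COLUMNS) + "\n")
        for s in sessions:
            fh.write(f"{s.nest_id},{_fmt_time(s.start)},{_fmt_time(s.end)}\n")


# dataframe views of pipeline outputs ---------------------------------------


def trips_to_frame(trips) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [t.tag_id for t in trips],
            "nest_id": [t.nest_id for t in trips],
            "exit_time": [t.exit_time for t in trips],
            "entrance_time": [t.entrance_time for t in trips],
            "duration_s": [t.duration_s for t in trips],
            "trip_class": [t.trip_class.value for t in trips],
            "power_interrupted": [t.power_interrupted for t in trips],
            "overnight_flag": [t.overnight_flag for t in trips],
        }
    )


def stays_to_frame(stays) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [s.tag_id for s in stays],
            "nest_id": [s.nest_id for s in stays],
            "entrance_time": [s.entrance_time for s in stays],
            "exit_time": [s.exit_time for s in stays],
            "duration_s": [s.duration_s for s in stays],
            "stay_class": [s.stay_class.value for s in stays],
            "power_interrupted": [s.power_interrupted for s in stays],
        }
    )


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag_id": [e.tag_id for e in events],
            "nest_id": [e.nest_id for e in events],
            "time": [e.time for e in events],
            "direction": [e.direction.value for e in events],
            "provenance": [e.provenance.value for e in events],
            "source_read_ids": [";".join(map(str, e.source_read_ids)) for e in events],
        }
    )
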