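"""Descriptive statistics over inferred trips and stays.

Per-queen summaries (trip counts, mean duration, trips/day), extended and
overnight trip summaries, the trimodal in-nest stay breakdown, the early/late
foundress-stage subsets used by the mixed models, and the queen fate flow.

Conventions: "foraging trip" in every summary means a retained trip with
duration at most the foraging maximum (default 4 h); extended trips are
summarised separately so a handful of overnight absences does not skew the
typical-behaviour statistics.  Calendar days are computed in the configured
local timezone, since trips per day is a local-clock concept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .records import (
    BroodStage,
    Fate,
    QueenRecord,
    Stay,
    StayClass,
    Trip,
    TripClass,
)


def sem(values: Iterable[float]) -> Optional[float]:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n).

    Undefined (None) for fewer than two values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        return None
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


@dataclass(frozen=True)
class QueenSummary:
    """One row of a per-queen foraging summary table."""

    queen_id: str
    species: str
    first_forage_date: Optional[pd.Timestamp]  # local calendar date
    last_forage_date: Optional[pd.Timestamp]
    n_trips: int
    mean_duration_min: Optional[float]
    sem_duration_min: Optional[float]
    trips_per_day_mean: Optional[float]
    trips_per_day_sem: Optional[float]


def _local_date(ts: pd.Timestamp, tz: str) -> pd.Timestamp:
    return ts.tz_convert(tz).normalize().tz_localize(None)


def daily_trip_counts(
    trips: Sequence[Trip], config: PipelineConfig
) -> pd.Series:
    """Foraging trips per local calendar day over the recording span.

    The span runs from the first to the last foraging day inclusive; days
    with zero trips inside the span count as zeros unless the config opts
    into active-days-only accounting.  A trip belongs to the day of its exit.
    """
    foraging = [t for t in trips if t.trip_class is TripClass.FORAGING]
    if not foraging:
        return pd.Series(dtype=int)
    days = pd.Series([_local_date(t.exit_time, config.local_tz) for t in foraging])
    counts = days.value_counts().sort_index()
    if config.trips_per_day_include_zero_days:
        full = pd.date_range(counts.index.min(), counts.index.max(), freq="D")
        counts = counts.reindex(full, fill_value=0)
    return counts


def summarize_queen(
    trips: Sequence[Trip],
    config: PipelineConfig,
    queen_id: str = "",
    species: str = "",
) -> QueenSummary:
    """Per-queen summary over retained foraging trips.

    Extended trips (> foraging max) are excluded from the duration mean and
    the daily counts; micro trips never reach this function because they are
    removed by the filter stage.
    """
    foraging = [t for t in trips if t.trip_class is TripClass.FORAGING]
    durations_min = [t.duration_s / 60.0 for t in foraging]
    counts = daily_trip_counts(trips, config)
    if not foraging:
        return QueenSummary(queen_id, species, None, None, 0, None, None, None, None)
    return QueenSummary(
        queen_id=queen_id,
        species=species,
        first_forage_date=counts.index.min(),
        last_forage_date=counts.index.max(),
        n_trips=len(foraging),
        mean_duration_min=float(np.mean(durations_min)),
        sem_duration_min=sem(durations_min),
        trips_per_day_mean=float(counts.mean()),
        trips_per_day_sem=sem(counts),
    )


def summary_table(
    trips: Sequence[Trip],
    queens: Sequence[QueenRecord],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Study-level per-queen summary table (one row per queen with trips)."""
    rows = []
    by_queen: dict[str, list[Trip]] = {}
    for t in trips:
        by_queen.setdefault(t.tag_id, []).append(t)
    meta = {q.queen_id: q for q in queens}
    for queen_id in sorted(by_queen):
        q = meta.get(queen_id)
        s = summarize_queen(
            by_queen[queen_id], config, queen_id=queen_id,
            species=q.species if q else "",
        )
        rows.append(
            {
                "queen_id": s.queen_id,
                "species": s.species,
                "first_forage_date": s.first_forage_date,
                "last_forage_date": s.last_forage_date,
                "n_trips": s.n_trips,
                "mean_duration_min": s.mean_duration_min,
                "sem_duration_min": s.sem_duration_min,
                "trips_per_day_mean": s.trips_per_day_mean,
                "trips_per_day_sem": s.trips_per_day_sem,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExtendedSummary:
    n_overnight: int
    mean_h: Optional[float]
    sem_h: Optional[float]


def extended_summary(trips: Sequence[Trip]) -> ExtendedSummary:
    """Count and duration summary of overnight trips (> overnight minimum)."""
    overnight = [t.duration_s / 3600.0 for t in trips if t.overnight_flag]
    if not overnight:
        return ExtendedSummary(0, None, None)
    return ExtendedSummary(
        n_overnight=len(overnight),
        mean_h=float(np.mean(overnight)),
        sem_h=sem(overnight),
    )


def stay_mixture_summary(stays: Sequence[Stay]) -> dict[StayClass, tuple[int, Optional[float]]]:
    """Per-class (count, mean duration in seconds) of the trimodal stay mix.

    Classes come from each stay's stored ``stay_class`` (assigned against the
    pipeline thresholds at build time); an empty class reports (0, None).
    """
    out: dict[StayClass, tuple[int, Optional[float]]] = {}
    for cls in StayClass:
        durs = [s.duration_s for s in stays if s.stay_class is cls]
        out[cls] = (len(durs), float(np.mean(durs)) if durs else None)
    return out


# ---------------------------------------------------------------------------
# foundress-stage subsets


_EARLY_ELIGIBLE = {BroodStage.YOUNG_LARVAE, BroodStage.MATURE_LARVAE}
_LATE_ELIGIBLE = {Fate.WORKERS_NO_GYNES, Fate.GYNES}


@dataclass
class StageSubsetResult:
    """Early/late labeled trips and daily counts for the stage models."""

    trips: pd.DataFrame   # queen_id, date, duration_s, stage
    daily_counts: pd.DataFrame  # queen_id, date, stage, n_trips
    queens_retained: list[str] = field(default_factory=list)
    queens_excluded: dict[str, str] = field(default_factory=dict)  # queen_id -> reason


def stage_subsets(
    trips: Sequence[Trip],
    queens: Sequence[QueenRecord],
    config: PipelineConfig,
) -> StageSubsetResult:
    """Label foraging trips with the foundress stage.

    EARLY: the first ``stage_window_days`` foraging days (days with at least
    one retained foraging trip) of queens who had larvae in the nest when
    tagged.  LATE: the last ``stage_window_days`` foraging days of queens who
    went on to produce adult workers.  Only queens with both windows are
    retained for modeling; a queen whose total foraging span is shorter than
    the two windows combined would overlap and is excluded with a reason.
    """
    by_queen: dict[str, list[Trip]] = {}
    for t in trips:
        if t.trip_class is TripClass.FORAGING:
            by_queen.setdefault(t.tag_id, []).append(t)
    meta = {q.queen_id: q for q in queens}

    result = StageSubsetResult(
        trips=pd.DataFrame(columns=["queen_id", "date", "duration_s", "stage"]),
        daily_counts=pd.DataFrame(columns=["queen_id", "date", "stage", "n_trips"]),
    )
    trip_rows = []
    count_rows = []
    for queen_id in sorted(by_queen):
        q = meta.get(queen_id)
        if q is None:
            result.queens_excluded[queen_id] = "no metadata record"
            continue
        if q.brood_stage_at_tagging not in _EARLY_ELIGIBLE:
            result.queens_excluded[queen_id] = "no larvae at tagging (no early window)"
            continue
        if q.fate not in _LATE_ELIGIBLE:
            result.queens_excluded[queen_id] = "did not produce workers (no late window)"
            continue
        qtrips = by_queen[queen_id]
        dates = sorted({_local_date(t.exit_time, config.local_tz) for t in qtrips})
        w = config.stage_window_days
        if len(dates) < 2 * w:
            result.queens_excluded[queen_id] = (
                f"only {len(dates)} foraging days; early/late windows overlap"
            )
            continue
        early_days = set(dates[:w])
        late_days = set(dates[-w:])
        result.queens_retained.append(queen_id)
        per_day_counts: dict[tuple, int] = {}
        for t in qtrips:
            d = _local_date(t.exit_time, config.local_tz)
            stage = "EARLY" if d in early_days else ("LATE" if d in late_days else None)
            if stage is None:
                continue
            trip_rows.append(
                {"queen_id": queen_id, "date": d, "duration_s": t.duration_s,
                 "stage": stage}
            )
            per_day_counts[(d, stage)] = per_day_counts.get((d, stage), 0) + 1
        for (d, stage), n in sorted(per_day_counts.items()):
            count_rows.append(
                {"queen_id": queen_id, "date": d, "stage": stage, "n_trips": n}
            )
    if trip_rows:
        result.trips = pd.DataFrame(trip_rows)
    if count_rows:
        result.daily_counts = pd.DataFrame(count_rows)
    return result


# ---------------------------------------------------------------------------
# fate flow


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _pct(numer: int, denom: int) -> dict[str, float]:
    """One ratio rendered three ways: 1-decimal, round-half-up int, truncated int."""
    if denom == 0:
        return {"one_decimal": 0.0, "rounded": 0, "truncated": 0}
    x = 100.0 * numer / denom
    return {
        "one_decimal": math.floor(x * 10 + 0.5) / 10,
        "rounded": _round_half_up(x),
        "truncated": int(x),
    }


@dataclass(frozen=True)
class FateFlow:
    """Counts along the queen fate progression and the derived percentages.

    Nodes are monotone: every gyne-producing nest produced workers, every
    worker-producing nest had eggs, every egg-laying queen was observed.
    """

    n_observed: int
    n_selected_only: int
    n_eggs: int
    n_workers: int
    n_gynes: int
    pct_gynes_of_observed: dict[str, float]
    pct_gynes_of_eggs: dict[str, float]
    pct_gynes_of_workers: dict[str, float]


def fate_flow(queens: Sequence[QueenRecord]) -> FateFlow:
    fates = [q.fate for q in queens]
    n_observed = len(fates)
    n_selected_only = sum(f is Fate.SELECTED_ABSCONDED for f in fates)
    n_eggs = n_observed - n_selected_only
    n_workers = sum(f in (Fate.WORKERS_NO_GYNES, Fate.GYNES) for f in fates)
    n_gynes = sum(f is Fate.GYNES for f in fates)
    return FateFlow(
        n_observed=n_observed,
        n_selected_only=n_selected_only,
        n_eggs=n_eggs,
        n_workers=n_workers,
        n_gynes=n_gynes,
        pct_gynes_of_observed=_pct(n_gynes, n_observed),
        pct_gynes_of_eggs=_pct(n_gynes, n_eggs),
        pct_gynes_of_workers=_pct(n_gynes, n_workers),
    )
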