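"""Entrance/exit inference from a bidirectional antenna read stream.

A queen walking through the entrance tunnel passes under two antenna cards
in sequence; the order of the two detections gives the direction of travel.
The inference proceeds in a fixed stage order:

1. collapse same-board re-reads within the pairing window (a stationary bee
   re-detected under one card is not a passage),
2. pair successive opposite-board reads separated by strictly less than the
   pairing window (greedy, left to right),
3. label each pair: inner board then outer board is an EXIT, the reverse an
   ENTRANCE; the event time is the second read of the pair,
4. relabel lone reads flanked by two same-direction events (two entrances
   imply an undetected exit between them, and vice versa),
5. drop residual lone inner-board reads preceded by an entrance or by
   another lone inner read (a queen standing in the entrance), logging every
   other residual read as unresolvable,
6. build alternating trips (exit -> next entrance) and stays (entrance ->
   next exit), reporting consecutive same-direction events as anomalies
   (missed passages) rather than bridging them,
7. filter: trips below the minimum duration are removed first, then any
   trip or stay whose interval overlaps a reader power outage.

Every raw read is accounted for exactly once: pair member, relabeled,
collapsed re-read, removed-with-reason, or unresolvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, Union

from .config import PipelineConfig
from .records import (
    Board,
    DirectedEvent,
    Direction,
    PowerInterval,
    Provenance,
    RawRead,
    Stay,
    StayClass,
    Trip,
    TripClass,
)

logger = logging.getLogger(__name__)

TimelineItem = Union[RawRead, DirectedEvent]


@dataclass
class StageReport:
    """Bookkeeping for one (nest, tag) stream, one count per disposal route."""

    nest_id: str = ""
    tag_id: str = ""
    n_reads_in: int = 0
    n_collapsed_rereads: int = 0
    n_paired_events: int = 0
    n_relabeled: int = 0
    n_spurious_inner_removed: int = 0
    n_unresolvable_removed: int = 0
    n_anomalies: int = 0
    n_trips_built: int = 0
    n_stays_built: int = 0
    n_micro_removed: int = 0
    n_power_removed_trips: int = 0
    n_power_removed_stays: int = 0
    anomalies: list[tuple[DirectedEvent, DirectedEvent]] = field(default_factory=list)
    spurious_inner_reads: list[RawRead] = field(default_factory=list)
    unresolvable_reads: list[RawRead] = field(default_factory=list)
    collapsed_reads: list[RawRead] = field(default_factory=list)

    def reads_accounted(self) -> int:
        return (
            2 * self.n_paired_events
            + self.n_relabeled
            + self.n_collapsed_rereads
            + self.n_spurious_inner_removed
            + self.n_unresolvable_removed
        )


@dataclass
class InferenceResult:
    trips: list[Trip]
    stays: list[Stay]
    events: list[DirectedEvent]
    removed_trips: list[Trip]          # MICRO + power-interrupted
    removed_stays: list[Stay]          # power-interrupted
    reports: dict[tuple[str, str], StageReport]

    @property
    def removal_rows(self) -> list[dict]:
        """Flat reason-coded removal table (reason codes MICRO, POWER,
        SPURIOUS_INNER, UNRESOLVABLE)."""
        rows = []
        for t in self.removed_trips:
            reason = "POWER" if t.power_interrupted else "MICRO"
            rows.append({"nest_id": t.nest_id, "tag_id": t.tag_id, "reason": reason,
                         "time": t.exit_time, "duration_s": t.duration_s})
        for rep in self.reports.values():
            for r in rep.spurious_inner_reads:
                rows.append({"nest_id": r.nest_id, "tag_id": r.tag_id,
                             "reason": "SPURIOUS_INNER", "time": r.time, "duration_s": None})
            for r in rep.unresolvable_reads:
                rows.append({"nest_id": r.nest_id, "tag_id": r.tag_id,
                             "reason": "UNRESOLVABLE", "time": r.time, "duration_s": None})
        return rows


# ---------------------------------------------------------------------------
# stage 1: re-read collapse


def collapse_rereads(reads: Sequence[RawRead], window_s: float) -> tuple[list[RawRead], list[RawRead]]:
    """Collapse bursts of same-board reads separated by < window to the first read.

    Gaps are measured against the last *kept* read, so a slow burst that
    drifts past the window starts a new read.
    """
    kept: list[RawRead] = []
    collapsed: list[RawRead] = []
    for r in reads:
        if (
            kept
            and kept[-1].board is r.board
            and (r.time - kept[-1].time).total_seconds() < window_s
        ):
            collapsed.append(r)
        else:
            kept.append(r)
    return kept, collapsed


# ---------------------------------------------------------------------------
# stages 2-3: pairing and direction labeling


def label_direction(first: RawRead, second: RawRead) -> DirectedEvent:
    """Inner -> outer is an EXIT, outer -> inner an ENTRANCE.

    The event carries the time of the second read: the passage is complete
    once the bee clears the far card.
    """
    if first.board is second.board:
        raise ValueError("a pair must span opposite boards")
    direction = Direction.EXIT if first.board is Board.INNER else Direction.ENTRANCE
    return DirectedEvent(
        nest_id=first.nest_id,
        tag_id=first.tag_id,
        time=second.time,
        direction=direction,
        provenance=Provenance.PAIRED,
        source_read_ids=(first.read_id, second.read_id),
    )


def pair_reads(reads: Sequence[RawRead], window_s: float) -> tuple[list[DirectedEvent], list[RawRead]]:
    """Greedy left-to-right pairing of successive opposite-board reads.

    A read pairs with the immediately next read iff the boards differ and the
    gap is strictly below the window; paired reads are consumed and cannot
    pair again.  Everything unconsumed is returned as lone reads.
    """
    events: list[DirectedEvent] = []
    lone: list[RawRead] = []
    i = 0
    n = len(reads)
    while i < n:
        if (
            i + 1 < n
            and reads[i].board is not reads[i + 1].board
            and (reads[i + 1].time - reads[i].time).total_seconds() < window_s
        ):
            events.append(label_direction(reads[i], reads[i + 1]))
            i += 2
        else:
            lone.append(reads[i])
            i += 1
    return events, lone


# ---------------------------------------------------------------------------
# stage 4: lone-read relabeling


def _timeline_key(item: TimelineItem):
    # events sort before reads at identical times (a completed passage is
    # older information than a stray detection)
    if isinstance(item, DirectedEvent):
        return (item.time, 0)
    return (item.time, 1)


def relabel_lone_reads(
    events: Sequence[DirectedEvent], lone_reads: Sequence[RawRead]
) -> tuple[list[DirectedEvent], list[RawRead]]:
    """Relabel lone reads flanked by two same-direction events.

    A lone read immediately preceded and followed by ENTRANCE events becomes
    an EXIT; one flanked by two EXITs becomes an ENTRANCE.  Flanks are the
    nearest in-time neighbours on the merged timeline, with no gap limit,
    and are taken from the original items in a single pass: an adjacent lone
    read disqualifies its neighbour.  Everything else stays unlabeled.
    """
    items: list[TimelineItem] = sorted([*events, *lone_reads], key=_timeline_key)
    out_events = list(events)
    residual: list[RawRead] = []
    for idx, item in enumerate(items):
        if not isinstance(item, RawRead):
            continue
        prev = items[idx - 1] if idx > 0 else None
        nxt = items[idx + 1] if idx + 1 < len(items) else None
        if not (isinstance(prev, DirectedEvent) and isinstance(nxt, DirectedEvent)):
            residual.append(item)
            continue
        if prev.direction is Direction.ENTRANCE and nxt.direction is Direction.ENTRANCE:
            new_dir = Direction.EXIT
        elif prev.direction is Direction.EXIT and nxt.direction is Direction.EXIT:
            new_dir = Direction.ENTRANCE
        else:
            residual.append(item)
            continue
        out_events.append(
            DirectedEvent(
                nest_id=item.nest_id,
                tag_id=item.tag_id,
                time=item.time,
                direction=new_dir,
                provenance=Provenance.RELABELED_LONE,
                source_read_ids=(item.read_id,),
            )
        )
    out_events.sort(key=lambda e: e.time)
    return out_events, residual


# ---------------------------------------------------------------------------
# stage 5: spurious inner-read removal


def drop_spurious_inner(
    events: Sequence[DirectedEvent], residual_lone: Sequence[RawRead]
) -> tuple[list[DirectedEvent], list[RawRead], list[RawRead]]:
    """Remove residual lone reads, splitting them into spurious and unresolvable.

    A residual INNER read whose immediately preceding timeline item is an
    ENTRANCE event or another residual INNER read is a queen standing in the
    nest entrance: removed and counted as spurious.  All other residual
    reads (outer-board, or inner reads with non-matching context) carry no
    defensible direction; they are removed from the timeline and logged as
    unresolvable rather than guessed into passages.
    """
    items: list[TimelineItem] = sorted([*events, *residual_lone], key=_timeline_key)
    spurious: list[RawRead] = []
    unresolvable: list[RawRead] = []
    for idx, item in enumerate(items):
        if not isinstance(item, RawRead):
            continue
        prev = items[idx - 1] if idx > 0 else None
        preceded_by_entrance = (
            isinstance(prev, DirectedEvent) and prev.direction is Direction.ENTRANCE
        )
        preceded_by_lone_inner = isinstance(prev, RawRead) and prev.board is Board.INNER
        if item.board is Board.INNER and (preceded_by_entrance or preceded_by_lone_inner):
            spurious.append(item)
        else:
            unresolvable.append(item)
    kept_events = sorted(events, key=lambda e: e.time)
    return kept_events, spurious, unresolvable


# ---------------------------------------------------------------------------
# stage 6: interval construction


def classify_trip(duration_s: float, config: PipelineConfig) -> TripClass:
    if duration_s < config.min_trip_s:
        return TripClass.MICRO
    if duration_s > config.foraging_max_s:
        return TripClass.EXTENDED
    return TripClass.FORAGING


def classify_stay(duration_s: float, config: PipelineConfig) -> StayClass:
    if duration_s < config.stay_short_max_s:
        return StayClass.SHORT
    if duration_s <= config.stay_mid_max_s:
        return StayClass.MID
    return StayClass.LONG


def build_trips_and_stays(
    events: Sequence[DirectedEvent], config: PipelineConfig
) -> tuple[list[Trip], list[Stay], list[tuple[DirectedEvent, DirectedEvent]]]:
    """Alternate events into trips and stays.

    Consecutive same-direction events are a missed passage: reported as an
    anomaly, with no interval bridged across them.  Leading/trailing partial
    intervals are not emitted.
    """
    trips: list[Trip] = []
    stays: list[Stay] = []
    anomalies: list[tuple[DirectedEvent, DirectedEvent]] = []
    for a, b in zip(events, events[1:]):
        if a.direction is Direction.EXIT and b.direction is Direction.ENTRANCE:
            dur = (b.time - a.time).total_seconds()
            trips.append(
                Trip(
                    nest_id=a.nest_id,
                    tag_id=a.tag_id,
                    exit_event=a,
                    entrance_event=b,
                    trip_class=classify_trip(dur, config),
                    overnight_flag=dur > config.overnight_min_s,
                )
            )
        elif a.direction is Direction.ENTRANCE and b.direction is Direction.EXIT:
            dur = (b.time - a.time).total_seconds()
            stays.append(
                Stay(
                    nest_id=a.nest_id,
                    tag_id=a.tag_id,
                    entrance_event=a,
                    exit_event=b,
                    stay_class=classify_stay(dur, config),
                )
            )
        else:
            anomalies.append((a, b))
    return trips, stays, anomalies


# ---------------------------------------------------------------------------
# stage 7: filtering


def _interrupted(start, end, power: Sequence[PowerInterval]) -> bool:
    return any(p.overlaps(start, end) for p in power)


def filter_trips(
    trips: Sequence[Trip],
    power: Sequence[PowerInterval],
    config: PipelineConfig,
) -> tuple[list[Trip], list[Trip], int, int]:
    """Apply the removal rules in order: micro-trips first, then power overlap.

    Returns (retained, removed, n_micro, n_power).  A trip below the minimum
    duration (strictly) is removed regardless of outages; among the rest,
    any trip whose [exit, entrance] interval overlaps a power-off interval
    at the same nest is removed with its flag set.
    """
    retained: list[Trip] = []
    removed: list[Trip] = []
    n_micro = n_power = 0
    for t in trips:
        if t.duration_s < config.min_trip_s:
            removed.append(t)
            n_micro += 1
            continue
        nest_power = [p for p in power if p.nest_id == t.nest_id]
        if _interrupted(t.exit_time, t.entrance_time, nest_power):
            removed.append(
                Trip(t.nest_id, t.tag_id, t.exit_event, t.entrance_event,
                     t.trip_class, power_interrupted=True, overnight_flag=t.overnight_flag)
            )
            n_power += 1
            continue
        retained.append(t)
    return retained, removed, n_micro, n_power


def filter_stays(
    stays: Sequence[Stay],
    power: Sequence[PowerInterval],
    config: PipelineConfig,
) -> tuple[list[Stay], list[Stay]]:
    """Flag stays overlapping a power outage invalid, mirroring the trip rule."""
    retained: list[Stay] = []
    removed: list[Stay] = []
    for s in stays:
        nest_power = [p for p in power if p.nest_id == s.nest_id]
        if _interrupted(s.entrance_time, s.exit_time, nest_power):
            removed.append(
                Stay(s.nest_id, s.tag_id, s.entrance_event, s.exit_event,
                     s.stay_class, power_interrupted=True)
            )
        else:
            retained.append(s)
    return retained, removed


# ---------------------------------------------------------------------------
# composed pipeline


def infer_single(
    reads: Sequence[RawRead],
    power: Sequence[PowerInterval],
    config: PipelineConfig,
) -> tuple[list[Trip], list[Stay], list[DirectedEvent], list[Trip], list[Stay], StageReport]:
    """Run the full stage order on one time-sorted (nest, tag) stream."""
    report = StageReport(
        nest_id=reads[0].nest_id if reads else "",
        tag_id=reads[0].tag_id if reads else "",
        n_reads_in=len(reads),
    )
    kept, collapsed = collapse_rereads(reads, config.pairing_window_s)
    report.n_collapsed_rereads = len(collapsed)
    report.collapsed_reads = collapsed

    paired, lone = pair_reads(kept, config.pairing_window_s)
    report.n_paired_events = len(paired)

    events, residual = relabel_lone_reads(paired, lone)
    report.n_relabeled = len(events) - len(paired)

    events, spurious, unresolvable = drop_spurious_inner(events, residual)
    report.n_spurious_inner_removed = len(spurious)
    report.n_unresolvable_removed = len(unresolvable)
    report.spurious_inner_reads = spurious
    report.unresolvable_reads = unresolvable

    trips, stays, anomalies = build_trips_and_stays(events, config)
    report.n_anomalies = len(anomalies)
    report.anomalies = anomalies
    report.n_trips_built = len(trips)
    report.n_stays_built = len(stays)

    trips_kept, trips_removed, n_micro, n_power = filter_trips(trips, power, config)
    report.n_micro_removed = n_micro
    report.n_power_removed_trips = n_power
    stays_kept, stays_removed = filter_stays(stays, power, config)
    report.n_power_removed_stays = len(stays_removed)

    assert report.reads_accounted() == report.n_reads_in, (
        f"read conservation violated for ({report.nest_id}, {report.tag_id}): "
        f"{report.reads_accounted()} != {report.n_reads_in}"
    )
    return trips_kept, stays_kept, events, trips_removed, stays_removed, report


def infer(
    reads: Sequence[RawRead],
    power: Sequence[PowerInterval],
    config: PipelineConfig | None = None,
) -> InferenceResult:
    """Composed pipeline over all (nest, tag) streams, fully deterministic.

    Multiple tagged individuals at one nest (e.g. a resident and an invading
    queen) are processed independently per tag.
    """
    config = config or PipelineConfig()
    groups: dict[tuple[str, str], list[RawRead]] = {}
    for r in sorted(reads, key=RawRead.sort_key):
        groups.setdefault((r.nest_id, r.tag_id), []).append(r)

    result = InferenceResult([], [], [], [], [], {})
    for key in sorted(groups):
        trips, stays, events, rm_trips, rm_stays, report = infer_single(
            groups[key], power, config
        )
        result.trips.extend(trips)
        result.stays.extend(stays)
        result.events.extend(events)
        result.removed_trips.extend(rm_trips)
        result.removed_stays.extend(rm_stays)
        result.reports[key] = report
    return result
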