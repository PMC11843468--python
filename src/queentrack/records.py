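"""Typed records shared across the pipeline.

All timestamps are timezone-aware :class:`pandas.Timestamp` objects in UTC.
Durations are plain floats in seconds.  Day-level concepts (trips per day,
overnight classification) are computed in a configurable local timezone, not
here; these records never carry naive times.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


class Board(str, enum.Enum):
    """Which of the two antenna cards produced a read.

    INNER is the card closer to the nest chamber, OUTER the card closer to
    the outside world; a full passage crosses both.
    """

    INNER = "INNER"
    OUTER = "OUTER"


#: Tie-break for reads with identical timestamps: INNER sorts before OUTER.
BOARD_SORT_ORDER = {Board.INNER: 0, Board.OUTER: 1}


class Direction(str, enum.Enum):
    ENTRANCE = "ENTRANCE"
    EXIT = "EXIT"


class Provenance(str, enum.Enum):
    """How a directed event was inferred."""

    PAIRED = "PAIRED"              # two reads on opposite boards within the window
    RELABELED_LONE = "RELABELED_LONE"  # a lone read flanked by two same-direction events


class TripClass(str, enum.Enum):
    MICRO = "MICRO"          # shorter than the minimum trip duration; removed
    FORAGING = "FORAGING"    # the typical trip; at most the foraging maximum
    EXTENDED = "EXTENDED"    # longer than the foraging maximum


class StayClass(str, enum.Enum):
    SHORT = "SHORT"  # below the short-stay ceiling (default 3 min)
    MID = "MID"      # between the short ceiling and the mid ceiling (default 4 h)
    LONG = "LONG"    # above the mid ceiling; typically overnight


class BroodStage(str, enum.Enum):
    EGGS = "EGGS"
    YOUNG_LARVAE = "YOUNG_LARVAE"
    MATURE_LARVAE = "MATURE_LARVAE"
    PUPAE = "PUPAE"
    WORKERS = "WORKERS"


class Fate(str, enum.Enum):
    """Terminal outcome of a queen observed at a nest box.

    The categories are mutually exclusive and map onto the fate-flow nodes:
    every queen is OBSERVED; all but SELECTED_ABSCONDED laid eggs; the last
    two produced adult workers; GYNES additionally produced new queens.
    """

    SELECTED_ABSCONDED = "SELECTED_ABSCONDED"
    COLONIZED_ABSCONDED = "COLONIZED_ABSCONDED"
    DIED = "DIED"
    WORKERS_NO_GYNES = "WORKERS_NO_GYNES"
    GYNES = "GYNES"


class Role(str, enum.Enum):
    RESIDENT = "RESIDENT"
    INVADER = "INVADER"


class Caste(str, enum.Enum):
    QUEEN = "QUEEN"
    WORKER = "WORKER"


@dataclass(frozen=True)
class RawRead:
    """One antenna detection of a tag."""

    nest_id: str
    tag_id: str
    time: pd.Timestamp
    board: Board
    #: stable identifier assigned at load/simulation time, used for provenance
    read_id: int = -1

    def sort_key(self):
        return (self.nest_id, self.tag_id, self.time, BOARD_SORT_ORDER[self.board])


@dataclass(frozen=True)
class PowerInterval:
    """An interval during which the reader at a nest was without power."""

    nest_id: str
    off_start: pd.Timestamp
    off_end: pd.Timestamp

    def __post_init__(self):
        if not self.off_start < self.off_end:
            raise ValueError(
                f"power interval must have off_start < off_end, got "
                f"[{self.off_start}, {self.off_end}]"
            )

    def overlaps(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        """Open-interval overlap with [start, end]."""
        return start < self.off_end and self.off_start < end


@dataclass(frozen=True)
class QueenRecord:
    queen_id: str
    nest_id: str
    species: str
    year: int
    tag_date: pd.Timestamp
    brood_stage_at_tagging: BroodStage
    fate: Fate
    worker_first_forage_date: Optional[pd.Timestamp] = None
    role: Role = Role.RESIDENT

    def __post_init__(self):
        if (
            self.worker_first_forage_date is not None
            and self.worker_first_forage_date < self.tag_date
        ):
            raise ValueError(
                f"queen {self.queen_id}: worker_first_forage_date "
                f"{self.worker_first_forage_date} precedes tag_date {self.tag_date}"
            )


@dataclass(frozen=True)
class ObservationEvent:
    """One in-person record of an individual crossing the nest entrance."""

    nest_id: str
    time: pd.Timestamp
    direction: Direction
    caste: Caste


@dataclass(frozen=True)
class DirectedEvent:
    """An inferred entrance or exit.

    PAIRED events reference exactly two reads on opposite boards; the event
    time is the time of the second read of the pair (passage completion).
    RELABELED_LONE events reference the single lone read they came from.
    """

    nest_id: str
    tag_id: str
    time: pd.Timestamp
    direction: Direction
    provenance: Provenance
    source_read_ids: tuple[int, ...] = ()

    def __post_init__(self):
        n = len(self.source_read_ids)
        if self.provenance is Provenance.PAIRED and n not in (0, 2):
            raise ValueError("PAIRED events reference exactly two reads")
        if self.provenance is Provenance.RELABELED_LONE and n not in (0, 1):
            raise ValueError("RELABELED_LONE events reference exactly one read")


@dataclass(frozen=True)
class Trip:
    """An out-of-nest interval: an exit followed by the next entrance."""

    nest_id: str
    tag_id: str
    exit_event: DirectedEvent
    entrance_event: DirectedEvent
    trip_class: TripClass
    power_interrupted: bool = False
    overnight_flag: bool = False

    @property
    def exit_time(self) -> pd.Timestamp:
        return self.exit_event.time

    @property
    def entrance_time(self) -> pd.Timestamp:
        return self.entrance_event.time

    @property
    def duration_s(self) -> float:
        return (self.entrance_time - self.exit_time).total_seconds()


@dataclass(frozen=True)
class Stay:
    """An in-nest interval: an entrance followed by the next exit."""

    nest_id: str
    tag_id: str
    entrance_event: DirectedEvent
    exit_event: DirectedEvent
    stay_class: StayClass
    power_interrupted: bool = False

    @property
    def entrance_time(self) -> pd.Timestamp:
        return self.entrance_event.time

    @property
    def exit_time(self) -> pd.Timestamp:
        return self.exit_event.time

    @property
    def duration_s(self) -> float:
        return (self.exit_time - self.entrance_time).total_seconds()


@dataclass(frozen=True)
class TruthEvent:
    """A ground-truth passage emitted by the simulator (no sensor noise)."""

    tag_id: str
    time: pd.Timestamp
    direction: Direction
    index: int  # trip index for EXIT events, stay index for ENTRANCE events
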