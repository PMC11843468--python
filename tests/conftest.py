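"""Shared fixtures: read-stream builders and the hand-worked filter trace."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from queentrack.records import Board, PowerInterval, RawRead

T0 = pd.Timestamp("2022-06-20 12:00:00+00:00")


def ts(seconds: float) -> pd.Timestamp:
    return T0 + pd.Timedelta(seconds=seconds)


def mk_reads(spec, nest_id="N1", tag_id="Q1"):
    """Build a sorted read stream from (board_letter, offset_seconds) pairs.

    board_letter: 'I' for inner, 'O' for outer.
    """
    reads = [
        RawRead(
            nest_id=nest_id,
            tag_id=tag_id,
            time=ts(sec),
            board=Board.INNER if b == "I" else Board.OUTER,
        )
        for b, sec in spec
    ]
    reads.sort(key=RawRead.sort_key)
    return [
        RawRead(r.nest_id, r.tag_id, r.time, r.board, read_id=i)
        for i, r in enumerate(reads)
    ]


def random_stream(rng: np.random.Generator, max_reads: int = 12):
    """A random short read stream with gaps straddling the 10 s window."""
    n = int(rng.integers(0, max_reads + 1))
    gaps = rng.choice([0, 1, 2, 5, 8, 9, 10, 11, 15, 40], size=n)
    t = np.cumsum(gaps)
    boards = rng.choice(["I", "O"], size=n)
    return mk_reads(list(zip(boards, t.tolist())))


#: The hand-worked 20-read trace.  Timeline (seconds from T0):
#:   pairs A-H:  (O0,I3)=ENTRANCE@3  (I100,O102)=EXIT@102  (O700,I703)=ENTRANCE@703
#:               (O1500,I1503)=ENTRANCE@1503 (I2000,O2004)=EXIT@2004
#:               (O2025,I2028)=ENTRANCE@2028 (I2600,O2603)=EXIT@2603
#:               (O4000,I4003)=ENTRANCE@4003
#:   I2001: same-board re-read of I2000, collapsed before pairing
#:   I800:  lone read flanked by two entrances -> relabeled EXIT@800
#:   I1600: lone inner read preceded by ENTRANCE@1503 -> spurious, removed
#:   O4100: lone outer read at the stream end -> unresolvable, removed
#: Intervals: trips 102->703 (601 s, kept), 800->1503 (703 s, kept),
#:   2004->2028 (24 s, MICRO removed), 2603->4003 (1400 s, overlaps the
#:   outage [3000, 3300] -> POWER removed); stays 99, 97, 501, 575 s.
WORKED_TRACE_SPEC = [
    ("O", 0), ("I", 3),
    ("I", 100), ("O", 102),
    ("O", 700), ("I", 703),
    ("I", 800),
    ("O", 1500), ("I", 1503),
    ("I", 1600),
    ("I", 2000), ("I", 2001), ("O", 2004),
    ("O", 2025), ("I", 2028),
    ("I", 2600), ("O", 2603),
    ("O", 4000), ("I", 4003),
    ("O", 4100),
]


@pytest.fixture
def worked_trace():
    reads = mk_reads(WORKED_TRACE_SPEC)
    power = [PowerInterval("N1", ts(3000), ts(3300))]
    return reads, power
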