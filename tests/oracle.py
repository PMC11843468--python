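"""Brute-force reference implementation of the read-filtering rules.

Deliberately independent of the streaming implementation: pairing is found
by enumerating every valid matching of adjacent opposite-board reads and
selecting the earliest-first maximal one; the downstream rules are applied
with plain list scans.  Only usable on short streams (pairing enumeration
is exponential).
"""

from __future__ import annotations

from queentrack.records import Board, Direction, RawRead


def _eligible(a: RawRead, b: RawRead, window_s: float) -> bool:
    return a.board is not b.board and (b.time - a.time).total_seconds() < window_s


def collapse_rereads_ref(reads, window_s):
    kept = []
    for r in reads:
        if kept and kept[-1].board is r.board and (
            r.time - kept[-1].time
        ).total_seconds() < window_s:
            continue
        kept.append(r)
    return kept


def enumerate_matchings(reads, window_s):
    """All ways to partition the stream into adjacent pairs and lone reads."""
    results = []

    def rec(i, pairs, lones):
        if i >= len(reads):
            results.append((tuple(pairs), tuple(lones)))
            return
        rec(i + 1, pairs, lones + [i])
        if i + 1 < len(reads) and _eligible(reads[i], reads[i + 1], window_s):
            rec(i + 2, pairs + [(i, i + 1)], lones)

    rec(0, [], [])
    return results


def best_matching(reads, window_s):
    """Earliest-first maximal matching: lexicographically prefer a pair
    starting at the earliest position."""

    def key(matching):
        pairs, _ = matching
        starts = {i for i, _ in pairs}
        return tuple(1 if i in starts else 0 for i in range(len(reads)))

    return max(enumerate_matchings(reads, window_s), key=key)


def reference_events(reads, window_s):
    """(events, spurious, unresolvable, n_collapsed) per the full rule set.

    Events are plain (time, direction, relabeled?) tuples.
    """
    collapsed_stream = collapse_rereads_ref(reads, window_s)
    n_collapsed = len(reads) - len(collapsed_stream)
    pairs, lones = best_matching(collapsed_stream, window_s)

    events = []
    for i, j in pairs:
        first, second = collapsed_stream[i], collapsed_stream[j]
        direction = (
            Direction.EXIT if first.board is Board.INNER else Direction.ENTRANCE
        )
        events.append([second.time, direction, False])
    lone_reads = [collapsed_stream[i] for i in lones]

    # merged timeline; events before reads at equal times
    timeline = sorted(
        [("E", e) for e in events] + [("R", r) for r in lone_reads],
        key=lambda item: (item[1][0], 0) if item[0] == "E" else (item[1].time, 1),
    )

    # relabel pass over the original timeline
    residual = []
    for idx, (kind, item) in enumerate(timeline):
        if kind != "R":
            continue
        prev = timeline[idx - 1] if idx > 0 else None
        nxt = timeline[idx + 1] if idx + 1 < len(timeline) else None
        flanks = []
        for nb in (prev, nxt):
            flanks.append(nb[1][1] if nb is not None and nb[0] == "E" else None)
        if flanks[0] is Direction.ENTRANCE and flanks[1] is Direction.ENTRANCE:
            events.append([item.time, Direction.EXIT, True])
        elif flanks[0] is Direction.EXIT and flanks[1] is Direction.EXIT:
            events.append([item.time, Direction.ENTRANCE, True])
        else:
            residual.append(item)

    # spurious-inner pass
    timeline2 = sorted(
        [("E", e) for e in events] + [("R", r) for r in residual],
        key=lambda item: (item[1][0], 0) if item[0] == "E" else (item[1].time, 1),
    )
    spurious, unresolvable = [], []
    for idx, (kind, item) in enumerate(timeline2):
        if kind != "R":
            continue
        prev = timeline2[idx - 1] if idx > 0 else None
        prev_is_entrance = (
            prev is not None and prev[0] == "E" and prev[1][1] is Direction.ENTRANCE
        )
        prev_is_lone_inner = (
            prev is not None and prev[0] == "R" and prev[1].board is Board.INNER
        )
        if item.board is Board.INNER and (prev_is_entrance or prev_is_lone_inner):
            spurious.append(item)
        else:
            unresolvable.append(item)

    events.sort(key=lambda e: e[0])
    return events, spurious, unresolvable, n_collapsed


def reference_intervals(events):
    """(trips, stays, n_anomalies) as raw duration lists from event tuples."""
    trips, stays, anomalies = [], [], 0
    for (t0, d0, _), (t1, d1, _) in zip(events, events[1:]):
        if d0 is Direction.EXIT and d1 is Direction.ENTRANCE:
            trips.append((t1 - t0).total_seconds())
        elif d0 is Direction.ENTRANCE and d1 is Direction.EXIT:
            stays.append((t1 - t0).total_seconds())
        else:
            anomalies += 1
    return trips, stays, anomalies
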