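"""Summary statistics, stage subsets and the fate flow."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import queentrack.bout_statistics as bs
from queentrack import PipelineConfig
from queentrack.records import (
    BroodStage,
    DirectedEvent,
    Direction,
    Fate,
    Provenance,
    QueenRecord,
    Role,
    Stay,
    StayClass,
    Trip,
)
from queentrack.trip_inference import classify_stay, classify_trip

CFG = PipelineConfig()
T0 = pd.Timestamp("2022-06-20 16:00:00+00:00")  # 10:00 local in America/Denver


def mk_trip(start_s: float, duration_s: float, tag="Q1") -> Trip:
    t_exit = T0 + pd.Timedelta(seconds=start_s)
    t_in = t_exit + pd.Timedelta(seconds=duration_s)
    ev_out = DirectedEvent("N1", tag, t_exit, Direction.EXIT, Provenance.PAIRED)
    ev_in = DirectedEvent("N1", tag, t_in, Direction.ENTRANCE, Provenance.PAIRED)
    return Trip(
        "N1", tag, ev_out, ev_in,
        trip_class=classify_trip(duration_s, CFG),
        overnight_flag=duration_s > CFG.overnight_min_s,
    )


def mk_stay(duration_s: float, tag="Q1") -> Stay:
    ev_in = DirectedEvent("N1", tag, T0, Direction.ENTRANCE, Provenance.PAIRED)
    ev_out = DirectedEvent(
        "N1", tag, T0 + pd.Timedelta(seconds=duration_s), Direction.EXIT,
        Provenance.PAIRED,
    )
    return Stay("N1", tag, ev_in, ev_out, classify_stay(duration_s, CFG))


def mk_queen(queen_id="Q1", brood=BroodStage.YOUNG_LARVAE, fate=Fate.GYNES,
             **kwargs) -> QueenRecord:
    defaults = dict(
        nest_id="N1", species="B. fervidus", year=2022,
        tag_date=pd.Timestamp("2022-06-01"),
        worker_first_forage_date=None, role=Role.RESIDENT,
    )
    defaults.update(kwargs)
    return QueenRecord(queen_id=queen_id, brood_stage_at_tagging=brood,
                       fate=fate, **defaults)


class TestSem:
    def test_closed_form(self):
        assert bs.sem([1, 2, 3]) == pytest.approx(1 / math.sqrt(3), abs=1e-4)

    def test_single_value_undefined(self):
        assert bs.sem([5.0]) is None

    def test_zero_variance(self):
        assert bs.sem([4.0, 4.0, 4.0, 4.0]) == 0.0


class TestQueenSummary:
    def test_hand_arithmetic_two_days(self):
        # 600 s + 1200 s on day 1, 1800 s on day 2 -> mean 20 min, 1.5/day
        day = 86400.0
        trips = [mk_trip(0, 600), mk_trip(4000, 1200), mk_trip(day, 1800)]
        s = bs.summarize_queen(trips, CFG)
        assert s.n_trips == 3
        assert s.mean_duration_min == pytest.approx(20.0)
        assert s.trips_per_day_mean == pytest.approx(1.5)

    def test_single_trip_sem_missing(self):
        s = bs.summarize_queen([mk_trip(0, 900)], CFG)
        assert s.mean_duration_min == pytest.approx(15.0)
        assert s.sem_duration_min is None

    def test_extended_trip_excluded_from_summary(self):
        trips = [mk_trip(0, 600), mk_trip(4000, 5 * 3600.0)]
        s = bs.summarize_queen(trips, CFG)
        assert s.n_trips == 1
        assert s.mean_duration_min == pytest.approx(10.0)

    def test_zero_trip_days_counted_in_span(self):
        # one trip on day 1, one on day 4: span 4 days -> 0.5 trips/day
        trips = [mk_trip(0, 600), mk_trip(3 * 86400.0, 600)]
        s = bs.summarize_queen(trips, CFG)
        assert s.trips_per_day_mean == pytest.approx(0.5)

    def test_active_days_only_switch(self):
        cfg = PipelineConfig(trips_per_day_include_zero_days=False)
        trips = [mk_trip(0, 600), mk_trip(3 * 86400.0, 600)]
        s = bs.summarize_queen(trips, cfg)
        assert s.trips_per_day_mean == pytest.approx(1.0)


class TestExtendedSummary:
    def test_no_overnight_trips(self):
        assert bs.extended_summary([mk_trip(0, 600)]) == bs.ExtendedSummary(0, None, None)

    def test_single_13h_trip(self):
        res = bs.extended_summary([mk_trip(0, 13 * 3600.0)])
        assert res.n_overnight == 1
        assert res.mean_h == pytest.approx(13.0)
        assert res.sem_h is None

    def test_known_mean_recovered(self):
        res = bs.extended_summary([mk_trip(0, h * 3600.0) for h in (9, 13, 17)])
        assert res.mean_h == pytest.approx(13.0)


class TestStayMixtureSummary:
    @pytest.mark.parametrize(
        "duration_s, cls",
        [(100.0, StayClass.SHORT), (1800.0, StayClass.MID), (5 * 3600.0, StayClass.LONG)],
    )
    def test_classes(self, duration_s, cls):
        summary = bs.stay_mixture_summary([mk_stay(duration_s)])
        assert summary[cls] == (1, pytest.approx(duration_s))

    def test_empty_class_missing_mean(self):
        summary = bs.stay_mixture_summary([mk_stay(100.0)])
        assert summary[StayClass.LONG] == (0, None)


class TestStageSubsets:
    def _trips_over_days(self, days, per_day=3, tag="Q1"):
        return [
            mk_trip(d * 86400.0 + k * 3600.0, 600 + 60 * k, tag=tag)
            for d in days
            for k in range(per_day)
        ]

    def test_twelve_day_queen_gets_both_windows(self):
        trips = self._trips_over_days(range(12))
        queens = [mk_queen(fate=Fate.WORKERS_NO_GYNES)]
        res = bs.stage_subsets(trips, queens, CFG)
        assert res.queens_retained == ["Q1"]
        by_stage = res.trips.groupby("stage")["date"].nunique()
        assert by_stage["EARLY"] == 5 and by_stage["LATE"] == 5
        # days 6-7 (0-based 5,6) belong to neither window
        assert len(res.trips) == 30

    def test_eggs_at_tagging_no_early_window(self):
        trips = self._trips_over_days(range(12))
        queens = [mk_queen(brood=BroodStage.EGGS)]
        res = bs.stage_subsets(trips, queens, CFG)
        assert res.queens_retained == []
        assert "no larvae" in res.queens_excluded["Q1"]

    def test_absconded_queen_no_late_window(self):
        trips = self._trips_over_days(range(12))
        queens = [mk_queen(fate=Fate.COLONIZED_ABSCONDED)]
        res = bs.stage_subsets(trips, queens, CFG)
        assert "workers" in res.queens_excluded["Q1"]

    def test_short_span_overlapping_windows_excluded(self):
        trips = self._trips_over_days(range(9))  # 9 < 2 * 5 days
        queens = [mk_queen()]
        res = bs.stage_subsets(trips, queens, CFG)
        assert "overlap" in res.queens_excluded["Q1"]

    def test_daily_counts_match_trips(self):
        trips = self._trips_over_days(range(12), per_day=4)
        queens = [mk_queen()]
        res = bs.stage_subsets(trips, queens, CFG)
        assert (res.daily_counts["n_trips"] == 4).all()
        assert res.daily_counts.groupby("stage")["date"].count().tolist() == [5, 5]


class TestFateFlow:
    def _study_queens(self):
        fates = (
            [Fate.SELECTED_ABSCONDED] * 5
            + [Fate.COLONIZED_ABSCONDED] * 4
            + [Fate.DIED] * 2
            + [Fate.WORKERS_NO_GYNES] * 4
            + [Fate.GYNES] * 3
        )
        return [mk_queen(queen_id=f"Q{i}", fate=f) for i, f in enumerate(fates)]

    def test_study_counts(self):
        flow = bs.fate_flow(self._study_queens())
        assert (flow.n_observed, flow.n_eggs, flow.n_workers, flow.n_gynes) == (18, 13, 7, 3)

    def test_gynes_of_eggs_is_23_percent(self):
        flow = bs.fate_flow(self._study_queens())
        assert flow.pct_gynes_of_eggs["rounded"] == 23
        assert flow.pct_gynes_of_eggs["one_decimal"] == pytest.approx(23.1)

    def test_gynes_of_workers_renderings(self):
        flow = bs.fate_flow(self._study_queens())
        # 3/7 = 42.857...: 42.9 at one decimal, 43 rounded, 42 truncated
        assert flow.pct_gynes_of_workers["one_decimal"] == pytest.approx(42.9)
        assert flow.pct_gynes_of_workers["rounded"] == 43
        assert flow.pct_gynes_of_workers["truncated"] == 42

    def test_gynes_of_observed_renderings(self):
        flow = bs.fate_flow(self._study_queens())
        # 3/18 = 16.67: truncation gives 16, round-half-up 17
        assert flow.pct_gynes_of_observed["truncated"] == 16
        assert flow.pct_gynes_of_observed["rounded"] == 17

    def test_no_gynes_all_zero(self):
        queens = [mk_queen(queen_id="Q1", fate=Fate.WORKERS_NO_GYNES)]
        flow = bs.fate_flow(queens)
        assert flow.pct_gynes_of_eggs == {"one_decimal": 0.0, "rounded": 0, "truncated": 0}

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(list(Fate)), max_size=30))
    def test_monotone_nodes_for_any_roster(self, fates):
        queens = [mk_queen(queen_id=f"Q{i}", fate=f) for i, f in enumerate(fates)]
        flow = bs.fate_flow(queens)
        assert flow.n_gynes <= flow.n_workers <= flow.n_eggs <= flow.n_observed


def test_summary_recovers_simulated_duration_mean():
    """On simulator output the per-queen duration mean lands within 2 sem of
    the configured trip mean in most seeds."""
    import queentrack as qt
    from queentrack.synthetic_data import perfect_sensing

    target_mean_min = 21.9
    hits = 0
    seeds = range(20)
    for seed in seeds:
        cfg = perfect_sensing(
            qt.SimConfig(n_days=10, rng_seed=seed, p_overnight_trip=0.0)
        )
        ev = qt.simulate_truth(cfg)
        res = qt.infer(qt.corrupt_to_reads(ev, cfg), [])
        s = bs.summarize_queen(res.trips, CFG)
        if s.sem_duration_min and abs(s.mean_duration_min - target_mean_min) <= 2 * s.sem_duration_min:
            hits += 1
    assert hits >= 0.9 * len(seeds) - 1
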