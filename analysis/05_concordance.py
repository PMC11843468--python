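#!/usr/bin/env python
"""Validate RFID-inferred events against the in-person observation log.

Matches events inside observation sessions and reports the two error rates
(RFID missed/mislabeled observer events; observer missed RFID events),
plus a sensitivity table over matching tolerances.

Usage: python analysis/05_concordance.py [--datadir results/data] [--outdir results]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import queentrack as qt
from queentrack import io_events
from queentrack.concordance import Session, sensitivity_report


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    reads = io_events.read_raw_reads(args.datadir / "reads.csv").records
    power = io_events.read_power_log(args.datadir / "power.csv").records
    observations = io_events.read_observations(args.datadir / "observations.csv").records
    sessions = [
        Session(*row) for row in io_events.read_sessions(args.datadir / "sessions.csv").records
    ]
    cfg = qt.PipelineConfig()
    res = qt.infer(reads, power, cfg)

    unknown = [
        (r.nest_id, r.time)
        for rep in res.reports.values()
        for r in rep.unresolvable_reads
    ]
    conc = qt.match_events(
        res.events, observations, sessions, cfg.concordance_tolerance_s,
        rfid_unknown_times=unknown,
    )
    session_hours = sum(
        (s.end - s.start).total_seconds() for s in sessions
    ) / 3600.0
    out = {
        "session_hours": session_hours,
        "n_obs_events": conc.n_obs_events,
        "n_rfid_events": conc.n_rfid_events,
        "n_matched": conc.n_matched,
        "n_mislabeled": conc.n_mislabeled,
        "rfid_missed": conc.rfid_missed,
        "rfid_direction_unknown": conc.rfid_direction_unknown,
        "observer_missed": conc.observer_missed,
        "rate_rfid_error_pct": conc.rate_rfid_error,
        "rate_observer_missed_pct": conc.rate_observer_missed,
    }
    (args.outdir / "concordance.json").write_text(json.dumps(out, indent=2) + "\n")

    sens = sensitivity_report(res.events, observations, sessions)
    sens.to_csv(args.outdir / "concordance_sensitivity.csv", index=False)

    print(f"compared {session_hours:.1f} h of concurrent RFID and in-person data")
    print(f"  observer logged {conc.n_obs_events} queen events; "
          f"RFID recorded {conc.n_rfid_events}")
    print(f"  RFID missed/mislabeled {conc.rate_rfid_error:.1f}% of observer events "
          f"({conc.rfid_missed} missed, {conc.n_mislabeled} mislabeled, "
          f"{conc.rfid_direction_unknown} direction-unknown)")
    print(f"  observer missed {conc.rate_observer_missed:.1f}% of RFID events "
          f"(n = {conc.observer_missed})")
    print("sensitivity to matching tolerance:")
    print(sens.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
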