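"""Pipeline configuration: every numeric threshold used by the inference.

The defaults are the filtering rules of the field protocol this package
implements: paired reads are opposite-board reads separated by strictly less
than 10 s; trips shorter than 30 s are discarded; trips above 4 h are
"extended" and reported separately; trips above 8 h are overnight; in-nest
stays are classed short (< 3 min), mid (3 min - 4 h), or long (> 4 h); the
early/late foundress-stage windows span 5 foraging days each.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineConfig:
    pairing_window_s: float = 10.0
    min_trip_s: float = 30.0
    foraging_max_h: float = 4.0
    overnight_min_h: float = 8.0
    stay_short_max_s: float = 180.0
    stay_mid_max_h: float = 4.0
    stage_window_days: int = 5
    concordance_tolerance_s: float = 120.0
    #: timezone in which calendar days and overnight boundaries are computed
    local_tz: str = "America/Denver"
    #: count zero-trip calendar days inside the recording span in trips/day
    trips_per_day_include_zero_days: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if not self.pairing_window_s > 0:
            raise ValueError("pairing_window_s must be positive")
        if not (0 < self.min_trip_s < self.foraging_max_h * 3600.0):
            raise ValueError("need 0 < min_trip_s < foraging_max_h")
        if not self.stay_short_max_s < self.stay_mid_max_h * 3600.0:
            raise ValueError("need stay_short_max_s < stay_mid_max_h")
        if self.concordance_tolerance_s <= 0:
            raise ValueError("concordance_tolerance_s must be positive")
        if self.stage_window_days < 1:
            raise ValueError("stage_window_days must be >= 1")

    @property
    def foraging_max_s(self) -> float:
        return self.foraging_max_h * 3600.0

    @property
    def overnight_min_s(self) -> float:
        return self.overnight_min_h * 3600.0

    @property
    def stay_mid_max_s(self) -> float:
        return self.stay_mid_max_h * 3600.0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        """Load a config from a TOML key-value file; unknown keys are an error."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
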