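"""Pipeline configuration: every tunable, with units and defaults.

Defaults live here (not hard-coded in the algorithms) so a run can be
reproduced from its echoed config file alone. Unknown keys are fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

#: Default first-order Markov transition matrix over (W, L, D, R) at 30-s
#: epochs: long light-sleep runs, deep sleep reachable only through light
#: sleep (biased early via the initial wake state), REM entered from light
#: sleep. Shipped as configuration; any row-stochastic matrix may be used.
DEFAULT_TRANSITION_MATRIX = [
    [0.920, 0.070, 0.000, 0.010],  # W
    [0.020, 0.900, 0.050, 0.030],  # L
    [0.005, 0.060, 0.935, 0.000],  # D
    [0.020, 0.060, 0.000, 0.920],  # R
]
DEFAULT_INITIAL_DISTRIBUTION = [1.0, 0.0, 0.0, 0.0]


@dataclass
class PipelineConfig:
    """All pipeline tunables. Units in field comments; see docs/methods.md."""

    fs: float = 100.0                 # accelerometer sampling rate, Hz
    target_fs: float = 10.0           # decimated rate for orientation, Hz
    q_min: float = 0.5                # beat-quality threshold in [0, 1]
    act_scale: float = 6.6            # activity-count scaling before mixing
    ibi_lo: float = 0.33              # shortest admissible IBI, s (≈180 bpm)
    ibi_hi: float = 2.0               # longest admissible IBI, s (≈30 bpm)
    smoothness_weight: float = 10.0   # IBI-smoothness prior weight (1/s²)
    grid_fs: float = 2.0              # tachogram grid for synchronization, Hz
    o_lo: float = -120.0              # clock-offset search range, s
    o_hi: float = 120.0
    r_lo: float = 0.999               # clock-rate search range, dimensionless
    r_hi: float = 1.001
    epoch_s: float = 30.0             # scoring epoch length, s
    gap_m: int = 20                   # M-gap tolerance for stage intervals
    fdr: float = 0.05                 # false discovery rate for factor tests

    def __post_init__(self) -> None:
        if not 0 <= self.q_min <= 1:
            raise ValueError("q_min must lie in [0, 1]")
        if not 0 < self.ibi_lo < self.ibi_hi:
            raise ValueError("require 0 < ibi_lo < ibi_hi")
        if self.act_scale <= 0:
            raise ValueError("act_scale must be positive")
        if self.grid_fs <= 0 or self.fs <= 0 or self.target_fs <= 0:
            raise ValueError("rates must be positive")
        if not (0 < self.r_lo <= self.r_hi):
            raise ValueError("rate range must be positive")
        if self.gap_m < 0:
            raise ValueError("gap_m must be non-negative")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
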