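"""Core containers shared across the pipeline.

Stage alphabet
--------------
Four sleep stages are used throughout, with single-letter file codes:

====  ==========  =========================================
code  name        meaning
====  ==========  =========================================
W     Wake        wakefulness
L     N1+N2       light sleep (stages N1 and N2 merged)
D     N3          deep / slow-wave sleep
R     REM         rapid-eye-movement sleep
====  ==========  =========================================

The canonical in-memory order is ``(W, L, D, R)``; reporting functions
accept an explicit class order where a different table layout is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGES: tuple[str, ...] = ("W", "L", "D", "R")
STAGE_NAMES: dict[str, str] = {"W": "Wake", "L": "N1+N2", "D": "N3", "R": "REM"}
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}


@dataclass
class TriaxialAccel:
    """Triaxial acceleration in g, uniformly sampled.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    x, y, z : ndarray
        Equal-length channel arrays (g).
    start : float
        Time of the first sample (s).
    """

    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    start: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("channel lengths differ")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        for name, ch in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"non-finite values in channel {name}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.x) / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start + np.arange(len(self.x)) / self.fs

    def as_matrix(self) -> np.ndarray:
        """Return an (n, 3) matrix of the channels."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class BeatSeries:
    """Heartbeat localizations with inter-beat intervals.

    ``ibis[i]`` is the time to the next beat: ``t[i+1] - t[i]`` wherever a
    next beat exists; the final entry extends the hold interval of the last
    beat. ``quality`` grades each beat's local signal quality in [0, 1].
    """

    times: np.ndarray
    ibis: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if self.quality is None:
            self.quality = np.ones_like(self.times)
        else:
            self.quality = np.asarray(self.quality, dtype=float)
        if not (len(self.times) == len(self.ibis) == len(self.quality)):
            raise ValueError("times, ibis and quality must have equal length")
        if len(self.times) > 1:
            d = np.diff(self.times)
            if np.any(d <= 0):
                raise ValueError("beat times must be strictly increasing")
            if not np.allclose(self.ibis[:-1], d, atol=1e-9):
                raise ValueError("ibis[:-1] must equal diff(times)")
        if len(self.ibis) and np.any(self.ibis <= 0):
            raise ValueError("IBIs must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_times(cls, times: np.ndarray, quality: np.ndarray | None = None,
                   last_ibi: float | None = None) -> "BeatSeries":
        """Build a series from beat times alone.

        The final IBI, which has no successor beat, defaults to the last
        observed interval (or ``last_ibi`` if given).
        """
        times = np.asarray(times, dtype=float)
        if len(times) == 0:
            return cls(times, np.empty(0), quality)
        d = np.diff(times)
        if last_ibi is None:
            last_ibi = d[-1] if len(d) else 1.0
        return cls(times, np.append(d, last_ibi), quality)

    @property
    def end(self) -> float:
        """End of the hold interval of the last beat."""
        if len(self.times) == 0:
            return 0.0
        return float(self.times[-1] + self.ibis[-1])


@dataclass
class GappedSeries:
    """Uniformly sampled series with a validity mask."""

    fs: float
    values: np.ndarray
    valid: np.ndarray
    start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.values) != len(self.valid):
            raise ValueError("values and mask lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) / self.fs

    def copy(self) -> "GappedSeries":
        return GappedSeries(self.fs, self.values.copy(), self.valid.copy(), self.start)


@dataclass
class OrientationSignal:
    """Sensor orientation at 10 Hz: two horizontal components and a vertical one.

    ``(h1, h2)`` read like the bubble coordinates of a planar spirit level;
    ``v`` is the projection onto the gravity direction. At every valid sample
    h1² + h2² + v² = 1.
    """

    h1: np.ndarray
    h2: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    fs: float = 10.0

    def __post_init__(self) -> None:
        n = len(self.h1)
        if not (len(self.h2) == len(self.v) == len(self.valid) == n):
            raise ValueError("component lengths differ")
        norm = self.h1 ** 2 + self.h2 ** 2 + self.v ** 2
        if n and np.any(np.abs(norm[self.valid] - 1.0) > 1e-6):
            raise ValueError("orientation components are not unit-norm")

    def __len__(self) -> int:
        return len(self.h1)


@dataclass
class EffortBundle:
    """The classifier inputs: IHR, respiratory effort, activity, and their mix.

    All 10 Hz members share length; ``act`` is the native 1 Hz activity-count
    series and ``act10`` its sample-and-hold upsampled copy.
    """

    ihr: GappedSeries
    res: GappedSeries
    act: np.ndarray
    act10: np.ndarray
    resact: GappedSeries

    def __post_init__(self) -> None:
        n = len(self.res)
        if not (len(self.ihr) == len(self.resact) == len(self.act10) == n):
            raise ValueError("10 Hz members must share length")
        if np.any(np.asarray(self.act) < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.res)


@dataclass
class StageSequence:
    """Per-30-s-epoch stage labels, optionally with class probabilities.

    ``probabilities`` rows follow the canonical stage order ``STAGES`` (or
    ``classes`` when a merged scheme is in play) and sum to 1.
    """

    labels: np.ndarray
    probabilities: np.ndarray | None = None
    epoch_s: float = 30.0
    classes: tuple[str, ...] = STAGES
    flags: np.ndarray | None = None  # e.g. context-only classified epochs

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.labels), len(self.classes)):
                raise ValueError("probability matrix shape mismatch")
            if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
                raise ValueError("probability rows must sum to 1")
            self.probabilities = p

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StageSequence):
            return NotImplemented
        return (np.array_equal(self.labels, other.labels)
                and self.epoch_s == other.epoch_s
                and self.classes == other.classes)
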