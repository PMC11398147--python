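"""Synthetic overnight recordings: hypnogram, physiology, and acceleration.

The generator produces the statistical structure the downstream pipeline
assumes, so every stage is testable without clinical data:

* a first-order Markov hypnogram over (Wake, N1+N2, N3, REM) at 30-s epochs;
* heartbeats whose rate and beat-to-beat variability are stage-conditional
  (rate lowest and variability smallest in deep sleep, variability largest
  in REM and wake);
* a respiratory effort whose rate jitter is small in non-REM and larger in
  REM/wake (breathing is more regular in non-REM sleep);
* gross body movements as short broadband bursts, most frequent in wake;
* a triaxial acceleration trace in which respiration appears as slow
  orientation variations, heartbeats as small transient peaks, and
  movements as high-amplitude bursts, riding on a slowly drifting gravity
  vector plus sensor noise.

One root seed spawns independent child streams per signal component, so a
recording is bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_INITIAL_DISTRIBUTION, DEFAULT_TRANSITION_MATRIX
from .types import STAGES, BeatSeries, StageSequence, TriaxialAccel

_G_STD = 0.7978845608028654  # E|X|/std for a centred Gaussian, sqrt(2/pi)


@dataclass
class SleepArchitecture:
    """First-order Markov model of overnight sleep-stage succession."""

    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_TRANSITION_MATRIX))
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_INITIAL_DISTRIBUTION))
    n_epochs: int = 960  # 8 h at 30 s

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if self.transition_matrix.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4 over (W, L, D, R)")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition probabilities must be non-negative")
        rowsum = self.transition_matrix.sum(axis=1)
        bad = np.nonzero(np.abs(rowsum - 1.0) > 1e-9)[0]
        if len(bad):
            raise ValueError(
                f"transition matrix row {bad[0]} (stage {STAGES[bad[0]]}) "
                f"sums to {rowsum[bad[0]]!r}, expected 1")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-9 or np.any(
                self.initial_distribution < 0):
            raise ValueError("initial distribution must be a probability vector")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be non-negative")


def _stage_dict(d: dict) -> dict:
    missing = set(STAGES) - set(d)
    if missing:
        raise ValueError(f"per-stage parameter missing stages: {sorted(missing)}")
    return {k: float(v) for k, v in d.items()}


@dataclass
class PhysiologyParams:
    """Stage-conditional cardiorespiratory and movement parameters.

    Defaults are literature-plausible values for a middle-aged clinical
    population; they are configuration, not estimates from any dataset.

    Attributes
    ----------
    hr_mean : dict
        Mean heart rate per stage (bpm).
    ibi_sdsd : dict
        Std of successive IBI differences per stage (s). Wake and REM must
        exceed N3 (autonomic stability is greatest in deep sleep).
    resp_rate : dict
        Mean respiratory rate per stage (Hz).
    resp_jitter : dict
        Fractional respiratory-rate jitter per stage; smaller in non-REM.
    movement_rate : dict
        Gross body-movement bursts per minute per stage.
    burst_amp, burst_dur : float
        Movement-burst amplitude (g) and mean duration (s).
    cardiac_amp : float
        Peak amplitude of the cardiac transient (g).
    noise_std : float
        White sensor-noise std per channel (g).
    tilt_deg : float
        Peak respiratory tilt of the gravity vector (degrees, small-angle).
    drift_deg : float
        Amplitude of the slow (tens of minutes) postural drift of the
        gravity vector (degrees); 0 gives a fixed gravity direction.
    hr_wander_std, hr_wander_tau : float
        Std (bpm) and time constant (s) of the slow AR(1) heart-rate wander
        superimposed on the stage means.
    """

    hr_mean: dict = field(default_factory=lambda: {"W": 72.0, "L": 64.0, "D": 58.0, "R": 70.0})
    ibi_sdsd: dict = field(default_factory=lambda: {"W": 0.050, "L": 0.035, "D": 0.020, "R": 0.060})
    resp_rate: dict = field(default_factory=lambda: {"W": 0.27, "L": 0.24, "D": 0.22, "R": 0.28})
    resp_jitter: dict = field(default_factory=lambda: {"W": 0.12, "L": 0.05, "D": 0.03, "R": 0.15})
    movement_rate: dict = field(default_factory=lambda: {"W": 1.0, "L": 0.08, "D": 0.02, "R": 0.15})
    burst_amp: float = 0.3
    burst_dur: float = 2.0
    cardiac_amp: float = 0.01
    noise_std: float = 0.001
    tilt_deg: float = 2.0
    drift_deg: float = 3.0
    hr_wander_std: float = 2.0
    hr_wander_tau: float = 60.0

    def __post_init__(self) -> None:
        for name in ("hr_mean", "ibi_sdsd", "resp_rate", "resp_jitter", "movement_rate"):
            setattr(self, name, _stage_dict(getattr(self, name)))
        for s, v in self.hr_mean.items():
            if not 30.0 <= v <= 180.0:
                raise ValueError(f"heart rate for stage {s} outside [30, 180] bpm")
        for s, v in self.resp_rate.items():
            if not 0.1 <= v <= 0.7:
                raise ValueError(f"respiratory rate for stage {s} outside [0.1, 0.7] Hz")
        for name in ("ibi_sdsd", "resp_jitter", "movement_rate"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be non-negative")
        for name in ("burst_amp", "burst_dur", "cardiac_amp", "noise_std",
                     "drift_deg", "hr_wander_std", "hr_wander_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.ibi_sdsd["W"] > self.ibi_sdsd["D"]
                and self.ibi_sdsd["R"] > self.ibi_sdsd["D"]):
            raise ValueError("Wake and REM IBI variability must exceed N3")
        if not (self.resp_jitter["R"] >= self.resp_jitter["L"]
                and self.resp_jitter["R"] >= self.resp_jitter["D"]):
            raise ValueError("REM respiratory jitter must be >= non-REM jitter")
        if self.tilt_deg <= 0 or self.tilt_deg > 5:
            raise ValueError("tilt_deg must lie in (0, 5] (small-angle model)")


@dataclass
class SimulatedRecording:
    """A complete synthetic night with its ground truth."""

    hypnogram: StageSequence
    true_beats: BeatSeries
    true_effort: np.ndarray          # 10 Hz
    movement_intervals: list         # (start s, end s) pairs
    accel: TriaxialAccel | None
    seed: int
    params: PhysiologyParams

    @property
    def duration(self) -> float:
        return len(self.hypnogram) * self.hypnogram.epoch_s


def simulate_hypnogram(arch: SleepArchitecture, seed: int) -> StageSequence:
    """Draw a stage sequence from the Markov sleep-architecture model."""
    rng = np.random.default_rng(seed)
    n = arch.n_epochs
    labels = np.empty(n, dtype=object)
    if n == 0:
        return StageSequence(labels)
    cum0 = np.cumsum(arch.initial_distribution)
    cum = np.cumsum(arch.transition_matrix, axis=1)
    u = rng.random(n)
    state = int(np.searchsorted(cum0, u[0], side="right"))
    state = min(state, 3)
    labels[0] = STAGES[state]
    for i in range(1, n):
        state = min(int(np.searchsorted(cum[state], u[i], side="right")), 3)
        labels[i] = STAGES[state]
    return StageSequence(labels)


def _stage_at(hyp: StageSequence, t: float) -> str:
    idx = min(int(t / hyp.epoch_s), len(hyp) - 1)
    return hyp.labels[idx]


def simulate_beats(hyp: StageSequence, phys: PhysiologyParams, seed: int) -> BeatSeries:
    """Generate heartbeat times with stage-conditional rate and variability.

    The instantaneous mean rate is the stage mean plus a slow AR(1) wander
    (shared across stages) that gives the tachogram the low-frequency
    structure clock synchronization relies on; white beat-scale noise is
    added so the std of successive IBI differences matches ``ibi_sdsd``.
    """
    rng = np.random.default_rng(seed)
    duration = len(hyp) * hyp.epoch_s
    if duration <= 0:
        return BeatSeries.from_times(np.empty(0))
    times = []
    t = 0.0
    wander = 0.0
    tau = max(phys.hr_wander_tau, 1e-6)
    while t < duration:
        stage = _stage_at(hyp, t)
        hr = phys.hr_mean[stage] + wander
        hr = float(np.clip(hr, 30.0, 180.0))
        ibi = 60.0 / hr
        sd = phys.ibi_sdsd[stage] / np.sqrt(2.0)
        if sd > 0:
            ibi += rng.normal(0.0, sd)
        ibi = float(np.clip(ibi, 0.33, 2.0))
        times.append(t)
        a = np.exp(-ibi / tau)
        wander = a * wander + phys.hr_wander_std * np.sqrt(1 - a * a) * rng.standard_normal()
        t += ibi
    return BeatSeries.from_times(np.asarray(times))


def simulate_effort(hyp: StageSequence, phys: PhysiologyParams, seed: int,
                    fs: float = 10.0) -> np.ndarray:
    """Respiratory effort at ``fs`` Hz via phase accumulation.

    The instantaneous rate is the stage rate modulated by a slow AR(1)
    fractional jitter whose magnitude is stage-conditional.
    """
    rng = np.random.default_rng(seed)
    n = int(round(len(hyp) * hyp.epoch_s * fs))
    if n == 0:
        return np.empty(0)
    epoch_len = int(round(hyp.epoch_s * fs))
    rates = np.repeat([phys.resp_rate[s] for s in hyp.labels], epoch_len)
    jit = np.repeat([phys.resp_jitter[s] for s in hyp.labels], epoch_len)
    # AR(1) jitter process, ~10 s time constant, unit marginal std
    a = np.exp(-1.0 / (10.0 * fs))
    w = rng.standard_normal(n) * np.sqrt(1 - a * a)
    u = np.empty(n)
    acc = rng.standard_normal()
    for i in range(n):
        acc = a * acc + w[i]
        u[i] = acc
    f_inst = rates * np.clip(1.0 + jit * u, 0.4, 1.8)
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    phase += rng.uniform(0, 2 * np.pi)
    return np.sin(phase)


def simulate_movements(hyp: StageSequence, phys: PhysiologyParams,
                       seed: int) -> list[tuple[float, float]]:
    """Draw gross-body-movement intervals, Poisson per stage."""
    rng = np.random.default_rng(seed)
    duration = len(hyp) * hyp.epoch_s
    intervals: list[tuple[float, float]] = []
    for i, s in enumerate(hyp.labels):
        lam = phys.movement_rate[s] * hyp.epoch_s / 60.0
        for _ in range(rng.poisson(lam)):
            start = i * hyp.epoch_s + rng.uniform(0, hyp.epoch_s)
            dur = rng.exponential(phys.burst_dur) + 0.5
            intervals.append((start, min(start + dur, duration)))
    intervals.sort()
    merged: list[tuple[float, float]] = []
    for st, en in intervals:
        if merged and st <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], en))
        else:
            merged.append((st, en))
    return merged


def _cardiac_pulse(fs: float, carrier_hz: float = 15.0) -> np.ndarray:
    """One-cycle Gaussian-windowed sinusoid: the SCG 'small peak'."""
    width = 1.0 / carrier_hz
    tt = np.arange(-width, width + 1.0 / fs, 1.0 / fs)
    return np.exp(-0.5 * (tt / (width / 2.5)) ** 2) * np.sin(2 * np.pi * carrier_hz * tt)


def synthesize_acceleration(beats: BeatSeries, effort: np.ndarray,
                            movements: list[tuple[float, float]],
                            phys: PhysiologyParams, fs: float, seed: int,
                            duration: float | None = None,
                            effort_fs: float = 10.0) -> TriaxialAccel:
    """Assemble the triaxial trace from its physiological components.

    accel = slowly drifting gravity vector
          + respiration-driven small-angle tilt of that vector
          + one short biphasic cardiac pulse per beat (on the chest-normal z)
          + broadband bursts inside movement intervals
          + white sensor noise.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz to resolve cardiac peaks")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = len(effort) / effort_fs if len(effort) else beats.end
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # slow gravity drift (posture): small random-phase, ~20 min period tilt
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    drift = np.deg2rad(phys.drift_deg)
    theta_slow = drift * np.sin(2 * np.pi * t / 1200.0 + ph1)
    phi_slow = 0.8 * drift * np.sin(2 * np.pi * t / 1700.0 + ph2)

    # respiration as small-angle tilt
    if len(effort):
        eff = np.interp(t, np.arange(len(effort)) / effort_fs, effort)
    else:
        eff = np.zeros(n)
    theta = theta_slow + np.deg2rad(phys.tilt_deg) * eff

    x = np.sin(theta) * np.cos(phi_slow)
    y = np.sin(theta) * np.sin(phi_slow)
    z = np.cos(theta)

    # cardiac transients on the chest normal
    if phys.cardiac_amp > 0 and len(beats):
        pulse = phys.cardiac_amp * _cardiac_pulse(fs)
        half = len(pulse) // 2
        for tb in beats.times:
            if not 0 <= tb < duration:
                continue
            i0 = int(round(tb * fs)) - half
            a0, a1 = max(i0, 0), min(i0 + len(pulse), n)
            if a1 > a0:
                z[a0:a1] += pulse[a0 - i0:a1 - i0]

    # movement bursts: broadband noise with raised-cosine on/off ramps
    for st, en in movements:
        i0, i1 = int(st * fs), min(int(en * fs), n)
        if i1 <= i0:
            continue
        m = i1 - i0
        env = np.ones(m)
        ramp = min(int(0.2 * fs), m // 2)
        if ramp > 0:
            win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] *= win
            env[m - ramp:] *= win[::-1]
        for ch in (x, y, z):
            ch[i0:i1] += phys.burst_amp * env * rng.standard_normal(m)

    if phys.noise_std > 0:
        x += rng.normal(0, phys.noise_std, n)
        y += rng.normal(0, phys.noise_std, n)
        z += rng.normal(0, phys.noise_std, n)
    return TriaxialAccel(fs=fs, x=x, y=y, z=z)


def inject_clock_skew(beats: BeatSeries, offset: float, rate: float) -> BeatSeries:
    """Retime a beat series: t' = offset + rate * t, IBIs scaled by rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return BeatSeries(offset + rate * beats.times, rate * beats.ibis,
                      None if beats.quality is None else beats.quality.copy())


def simulate_recording(arch: SleepArchitecture | None = None,
                       phys: PhysiologyParams | None = None,
                       fs: float = 100.0, seed: int = 0,
                       synthesize: bool = True) -> SimulatedRecording:
    """Generate a full synthetic night.

    One root seed spawns independent child streams for the hypnogram, beats,
    effort, movements, and acceleration noise. With ``synthesize=False`` the
    (expensive) raw-acceleration synthesis is skipped and ``accel`` is None;
    the physiological ground truth is still produced.
    """
    arch = arch or SleepArchitecture()
    phys = phys or PhysiologyParams()
    children = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    hyp = simulate_hypnogram(arch, seeds[0])
    beats = simulate_beats(hyp, phys, seeds[1])
    effort = simulate_effort(hyp, phys, seeds[2])
    movements = simulate_movements(hyp, phys, seeds[3])
    accel = None
    if synthesize:
        accel = synthesize_acceleration(
            beats, effort, movements, phys, fs, seeds[4],
            duration=len(hyp) * hyp.epoch_s)
        dur_err = abs(accel.duration - len(hyp) * hyp.epoch_s)
        assert dur_err <= 1.0 / fs + 1e-9
    return SimulatedRecording(hyp, beats, effort, movements, accel, seed, phys)


def bundle_from_truth(rec: SimulatedRecording, act_scale: float = 6.6,
                      q_movement: float = 0.0, q_min: float = 0.5):
    """Assemble an :class:`~accelsleep.types.EffortBundle` from ground truth.

    Uses the simulated beats, effort, and movement intervals directly —
    bypassing acceleration synthesis and beat detection — to produce the
    classifier inputs. Beats inside movement intervals get quality
    ``q_movement`` so quality masking produces the same IHR gaps the full
    pipeline would. Activity counts are the analytic expectation of the
    per-second mean absolute deviation of the burst-plus-noise process.
    """
    from .extract import compute_ihr, mask_low_quality, mix_effort
    from .types import EffortBundle, GappedSeries

    duration = rec.duration
    n_sec = int(duration)
    act = np.full(n_sec, 3 * _G_STD * rec.params.noise_std)
    for st, en in rec.movement_intervals:
        for s in range(max(int(st), 0), min(int(np.ceil(en)), n_sec)):
            frac = min(en, s + 1) - max(st, s)
            act[s] += 3 * _G_STD * rec.params.burst_amp * max(frac, 0.0)

    q = np.ones(len(rec.true_beats))
    for st, en in rec.movement_intervals:
        inside = (rec.true_beats.times >= st) & (rec.true_beats.times <= en)
        q[inside] = q_movement
    beats = BeatSeries(rec.true_beats.times, rec.true_beats.ibis, q)

    ihr = compute_ihr(beats, duration=duration)
    ihr = mask_low_quality(ihr, beats, q_min)
    res = GappedSeries(10.0, rec.true_effort, np.ones(len(rec.true_effort), bool))
    return EffortBundle(ihr=ihr, res=res, act=act,
                        act10=np.repeat(act, 10),
                        resact=mix_effort(res, act, act_scale))
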