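"""Columnar text formats for every pipeline artifact.

All writers emit a small ``# key: value`` comment header (pipeline version,
root seed, rates) followed by tab-separated columns; floats are written in
shortest round-trip representation, so write-then-read is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import STAGES, BeatSeries, EffortBundle, GappedSeries, StageSequence, TriaxialAccel

log = logging.getLogger("accelsleep")


def _write_table(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# accelsleep-version: {__version__}\n")
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return df, meta


def write_accel(accel: TriaxialAccel, path, seed: int | None = None) -> None:
    df = pd.DataFrame({"t_s": accel.t, "x_g": accel.x, "y_g": accel.y, "z_g": accel.z})
    _write_table(path, df, {"fs": accel.fs, "seed": seed})


def read_accel(path) -> TriaxialAccel:
    """Read a columnar accelerometer file (t_s, x_g, y_g, z_g).

    Timestamps must be strictly increasing; the rate inferred from the
    median time step must match the header rate within 1%.
    """
    df, meta = _read_table(path)
    required = ["t_s", "x_g", "y_g", "z_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(t)
    bad = np.nonzero(d <= 0)[0]
    if len(bad):
        raise ValueError(f"non-monotone timestamp at row {bad[0] + 1} "
                         f"(t = {t[bad[0] + 1]!r})")
    fs_inferred = 1.0 / float(np.median(d))
    fs_header = float(meta.get("fs", fs_inferred))
    if abs(fs_inferred - fs_header) > 0.01 * fs_header:
        raise ValueError(f"inferred rate {fs_inferred:.3f} Hz does not match "
                         f"header rate {fs_header:.3f} Hz within 1%")
    return TriaxialAccel(fs=fs_header, x=df["x_g"].to_numpy(float),
                         y=df["y_g"].to_numpy(float), z=df["z_g"].to_numpy(float),
                         start=float(t[0]))


def read_accel_edf(path, channel_names: tuple[str, str, str] = ("x", "y", "z"),
                   scale: float = 1.0) -> TriaxialAccel:
    """Optional EDF ingestion of three accelerometer channels (needs mne)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF ingestion requires the optional 'mne' package") from err
    raw = mne.io.read_raw_edf(path, include=list(channel_names), preload=True,
                              verbose="error")
    data = raw.get_data(picks=list(channel_names)) * scale
    return TriaxialAccel(fs=float(raw.info["sfreq"]), x=data[0], y=data[1], z=data[2])


def write_hypnogram(stages: StageSequence, path, seed: int | None = None) -> None:
    cols = {"epoch_index": np.arange(len(stages)), "stage": list(stages.labels)}
    if stages.probabilities is not None:
        for i, c in enumerate(stages.classes):
            cols[f"p_{c}"] = stages.probabilities[:, i]
    _write_table(path, pd.DataFrame(cols), {"epoch_s": stages.epoch_s, "seed": seed})


def read_hypnogram(path) -> StageSequence:
    """Read an epoch-label file: (epoch_index, stage in {W, L, D, R})."""
    df, meta = _read_table(path)
    for c in ("epoch_index", "stage"):
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
    idx = df["epoch_index"].to_numpy()
    if len(idx) and not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError("epoch_index must be contiguous from 0")
    labels = df["stage"].astype(str).to_numpy(dtype=object)
    unknown = sorted(set(labels) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage labels {unknown}; allowed: {list(STAGES)}")
    probs = None
    pcols = [f"p_{c}" for c in STAGES]
    if all(c in df.columns for c in pcols):
        probs = df[pcols].to_numpy(dtype=float)
    return StageSequence(labels, probabilities=probs,
                         epoch_s=float(meta.get("epoch_s", 30.0)))


def write_beats(beats: BeatSeries, path, seed: int | None = None) -> None:
    df = pd.DataFrame({"t_s": beats.times, "ibi_s": beats.ibis,
                       "quality": beats.quality})
    _write_table(path, df, {"seed": seed})


def read_beats(path) -> BeatSeries:
    df, _ = _read_table(path)
    for c in ("t_s", "ibi_s"):
        if c not in df.columns:
            raise ValueError(f"missing column {c!r}")
    q = df["quality"].to_numpy(float) if "quality" in df.columns else None
    return BeatSeries(df["t_s"].to_numpy(float), df["ibi_s"].to_numpy(float), q)


def write_bundle(bundle: EffortBundle, path, seed: int | None = None) -> None:
    n = bundle.n_samples
    df = pd.DataFrame({
        "t_s": np.arange(n) / bundle.ihr.fs,
        "ihr_bpm": bundle.ihr.values, "ihr_valid": bundle.ihr.valid.astype(int),
        "res": bundle.res.values, "res_valid": bundle.res.valid.astype(int),
        "act": bundle.act10[:n],
        "resact": bundle.resact.values,
        "resact_valid": bundle.resact.valid.astype(int),
    })
    _write_table(path, df, {"fs": bundle.ihr.fs, "seed": seed})


def read_bundle(path) -> EffortBundle:
    df, meta = _read_table(path)
    fs = float(meta.get("fs", 10.0))
    up = int(round(fs))
    n = len(df) // up * up  # whole seconds
    df = df.iloc[:n]
    act10 = df["act"].to_numpy(float)
    return EffortBundle(
        ihr=GappedSeries(fs, df["ihr_bpm"].to_numpy(float),
                         df["ihr_valid"].to_numpy(bool)),
        res=GappedSeries(fs, df["res"].to_numpy(float),
                         df["res_valid"].to_numpy(bool)),
        act=act10[::up].copy(),
        act10=act10,
        resact=GappedSeries(fs, df["resact"].to_numpy(float),
                            df["resact_valid"].to_numpy(bool)))


@dataclass
class RecordingManifest:
    """Paths and provenance for one recording's pipeline run."""

    recording_id: str
    accel_path: str | None = None
    beats_path: str | None = None
    ref_beats_path: str | None = None
    bundle_path: str | None = None
    ref_hypnogram_path: str | None = None
    fs: float = 100.0
    seed: int = 0
    pipeline_version: str = field(default="")

    def __post_init__(self) -> None:
        if not self.pipeline_version:
            self.pipeline_version = __version__
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def validate(self, require: tuple = ()) -> None:
        for name in require:
            p = getattr(self, f"{name}_path")
            if p is None or not Path(p).exists():
                raise FileNotFoundError(
                    f"manifest for {self.recording_id!r} needs {name} file: {p}")
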