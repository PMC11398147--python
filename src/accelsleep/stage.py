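"""Four-class sleep staging from IHR and movement-mixed respiratory effort.

A transparent, trainable stager honoring the cardiorespiratory classifier's
contract: 10 Hz inputs in, per-30-s-epoch class probabilities out, with
whole-night temporal context. Per-epoch cardiorespiratory features feed a
multinomial linear scorer; global context comes from hidden-Markov
smoothing — Viterbi decoding for the label path and forward–backward for
the reported posteriors — in place of a recurrent network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression

from .types import STAGES, EffortBundle, StageSequence

BASE_FEATURES = [
    "ihr_mean", "ihr_std", "ihr_range", "ihr_sdrms",
    "ihr_lf_power", "ihr_hf_power", "ihr_lf_hf",
    "resp_freq", "resp_peakedness", "resact_cv",
    "act_sum", "ihr_invalid_frac",
]
#: context copies: each base feature averaged over the +-2 surrounding epochs
FEATURE_NAMES = BASE_FEATURES + [f"{n}_ctx" for n in BASE_FEATURES] + ["ihr_missing"]

_LF_BAND = (0.04, 0.15)   # Hz, sympathetic-dominated heart-rate band
_HF_BAND = (0.15, 0.40)   # Hz, respiratory (vagal) heart-rate band
_RESP_BAND = (0.10, 0.70)  # Hz, admissible respiratory rates


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    m = (f >= band[0]) & (f <= band[1])
    return float(p[m].sum()) if m.any() else 0.0


def epochize(bundle: EffortBundle, epoch_s: float = 30.0) -> pd.DataFrame:
    """Per-epoch cardiorespiratory features from a 10 Hz bundle.

    One row per complete epoch (trailing partial epoch dropped). IHR-derived
    features are missing (NaN) where fewer than 50% of the epoch's IHR
    samples are valid. Context columns average each feature over the two
    surrounding epochs on either side.
    """
    fs = bundle.ihr.fs
    n_per = int(round(epoch_s * fs))
    n_ep = bundle.n_samples // n_per
    rows = np.full((n_ep, len(BASE_FEATURES)), np.nan)
    for e in range(n_ep):
        sl = slice(e * n_per, (e + 1) * n_per)
        ihr_v = bundle.ihr.values[sl]
        ihr_ok = bundle.ihr.valid[sl]
        resact = bundle.resact.values[sl]
        act_sum = bundle.act10[sl].sum() / fs
        invalid_frac = 1.0 - ihr_ok.mean()

        feats = {"act_sum": act_sum, "ihr_invalid_frac": invalid_frac}
        if ihr_ok.mean() >= 0.5:
            v = ihr_v[ihr_ok]
            feats["ihr_mean"] = v.mean()
            feats["ihr_std"] = v.std()
            feats["ihr_range"] = v.max() - v.min()
            dv = np.diff(v)
            feats["ihr_sdrms"] = np.sqrt(np.mean(dv ** 2)) if len(dv) else 0.0
            filled = np.where(ihr_ok, ihr_v, v.mean())
            f, p = sps.periodogram(filled - filled.mean(), fs=fs, nfft=1024)
            lf = _band_power(f, p, _LF_BAND)
            hf = _band_power(f, p, _HF_BAND)
            feats["ihr_lf_power"] = lf
            feats["ihr_hf_power"] = hf
            feats["ihr_lf_hf"] = lf / hf if hf > 0 else np.nan

        f, p = sps.periodogram(resact - resact.mean(), fs=fs, nfft=1024)
        m = (f >= _RESP_BAND[0]) & (f <= _RESP_BAND[1])
        if m.any() and p[m].sum() > 0:
            feats["resp_freq"] = f[m][np.argmax(p[m])]
            feats["resp_peakedness"] = p[m].max() / p[m].sum()
        aa = np.abs(resact)
        feats["resact_cv"] = aa.std() / aa.mean() if aa.mean() > 0 else 0.0
        for j, name in enumerate(BASE_FEATURES):
            rows[e, j] = feats.get(name, np.nan)

    df = pd.DataFrame(rows, columns=BASE_FEATURES)
    ctx = df.rolling(window=5, center=True, min_periods=1).mean()
    ctx.columns = [f"{n}_ctx" for n in BASE_FEATURES]
    df = pd.concat([df, ctx], axis=1)
    df["ihr_missing"] = (df["ihr_mean"].isna()).astype(float)
    return df


@dataclass
class StagerModel:
    """Linear per-class scorer plus Markov temporal-smoothing parameters."""

    feature_names: list
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    coef: np.ndarray            # (4, n_features)
    intercept: np.ndarray       # (4,)
    transition: np.ndarray      # (4, 4) row-stochastic
    initial: np.ndarray         # (4,)
    impute_medians: np.ndarray  # per-feature fallback for missing values
    classes: tuple = STAGES
    seed: int = 0
    data_description: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9) or np.any(t < 0):
            raise ValueError("transition matrix must be row-stochastic")
        if not np.all(np.isfinite(self.scaler_mean)) or not np.all(
                np.isfinite(self.scaler_std)):
            raise ValueError("standardization constants must be finite")

    def save(self, path: str | Path) -> None:
        d = {
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "impute_medians": self.impute_medians.tolist(),
            "classes": list(self.classes),
            "seed": self.seed,
            "data_description": self.data_description,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StagerModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_std=np.array(d["scaler_std"]),
            coef=np.array(d["coef"]),
            intercept=np.array(d["intercept"]),
            transition=np.array(d["transition"]),
            initial=np.array(d["initial"]),
            impute_medians=np.array(d["impute_medians"]),
            classes=tuple(d["classes"]),
            seed=d["seed"],
            data_description=d["data_description"],
        )


def _impute(X: np.ndarray, names: list, medians: np.ndarray) -> np.ndarray:
    """Fill missing base features from their context copies, else medians."""
    X = X.copy()
    name_idx = {n: i for i, n in enumerate(names)}
    for n in BASE_FEATURES:
        i, j = name_idx[n], name_idx.get(f"{n}_ctx")
        bad = ~np.isfinite(X[:, i])
        if j is not None:
            ctx_ok = bad & np.isfinite(X[:, j])
            X[bad & ctx_ok, i] = X[bad & ctx_ok, j]
            bad = ~np.isfinite(X[:, i])
        X[bad, i] = medians[i]
    bad = ~np.isfinite(X)
    X[bad] = np.broadcast_to(medians, X.shape)[bad]
    return X


def train_stager(features: list[pd.DataFrame], labels: list[StageSequence],
                 seed: int = 0, C: float = 1.0) -> StagerModel:
    """Fit the linear scorer and the temporal-smoothing transition matrix.

    Requires at least two recordings with all four stages represented. The
    scorer is a multinomial logistic regression on standardized features;
    the transition matrix is the Laplace-smoothed empirical label
    transition frequency.
    """
    if len(features) < 2:
        raise ValueError("training requires at least 2 recordings")
    if len(features) != len(labels):
        raise ValueError("features and labels must pair up")
    y = np.concatenate([np.asarray(l.labels, dtype=object) for l in labels])
    for s in STAGES:
        if s not in set(y):
            raise ValueError(f"training labels are missing class {s}")
    X = np.vstack([f[FEATURE_NAMES].to_numpy(dtype=float) for f in features])
    if len(X) != len(y):
        raise ValueError("epoch counts of features and labels differ")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(X, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    X = _impute(X, FEATURE_NAMES, medians)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    Xs = (X - mean) / std

    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    yi = np.array([STAGES.index(s) for s in y])
    clf.fit(Xs, yi)
    coef = np.zeros((4, Xs.shape[1]))
    intercept = np.zeros(4)
    for row, cls in zip(range(len(clf.classes_)), clf.classes_):
        coef[cls] = clf.coef_[row]
        intercept[cls] = clf.intercept_[row]

    trans = np.ones((4, 4))  # Laplace smoothing
    init = np.ones(4)
    for l in labels:
        seq = [STAGES.index(s) for s in l.labels]
        if seq:
            init[seq[0]] += 1
        for a, b in zip(seq[:-1], seq[1:]):
            trans[a, b] += 1
    trans /= trans.sum(axis=1, keepdims=True)
    init /= init.sum()
    return StagerModel(
        feature_names=list(FEATURE_NAMES), scaler_mean=mean, scaler_std=std,
        coef=coef, intercept=intercept, transition=trans, initial=init,
        impute_medians=medians, seed=seed,
        data_description=f"{len(features)} recordings, {len(y)} epochs")


def viterbi_path(log_emission: np.ndarray, transition: np.ndarray,
                 initial: np.ndarray) -> np.ndarray:
    """Most probable state path (log-space dynamic programming)."""
    n, k = log_emission.shape
    with np.errstate(divide="ignore"):
        lt = np.log(transition)
        li = np.log(initial)
    delta = li + log_emission[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + lt
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + log_emission[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def forward_backward(log_emission: np.ndarray, transition: np.ndarray,
                     initial: np.ndarray) -> np.ndarray:
    """Per-epoch posterior state probabilities (scaled recursions)."""
    n, k = log_emission.shape
    em = np.exp(log_emission - log_emission.max(axis=1, keepdims=True))
    alpha = np.zeros((n, k))
    beta = np.zeros((n, k))
    a = initial * em[0]
    alpha[0] = a / a.sum()
    for t in range(1, n):
        a = (alpha[t - 1] @ transition) * em[t]
        alpha[t] = a / a.sum()
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = transition @ (em[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def classify_stages(features: pd.DataFrame, model: StagerModel) -> StageSequence:
    """Classify epochs with whole-night temporal context.

    Labels come from most-probable-path (Viterbi) decoding of the linear
    scorer's emissions under the model's transition matrix; the reported
    probabilities are the forward–backward posteriors. Epochs whose IHR was
    missing are classified from context features only and flagged.
    """
    cols = list(features.columns)
    if cols != list(model.feature_names):
        raise ValueError(
            f"feature schema mismatch: got {cols[:3]}..., "
            f"model expects {list(model.feature_names)[:3]}...")
    X = features.to_numpy(dtype=float)
    if len(X) == 0:
        return StageSequence(np.empty(0, dtype=object), classes=model.classes)
    missing = ~np.isfinite(X[:, cols.index("ihr_mean")])
    X = _impute(X, list(model.feature_names), model.impute_medians)
    Xs = (X - model.scaler_mean) / model.scaler_std
    scores = Xs @ model.coef.T + model.intercept
    log_em = scores - _logsumexp(scores)
    path = viterbi_path(log_em, model.transition, model.initial)
    post = forward_backward(log_em, model.transition, model.initial)
    labels = np.array([model.classes[i] for i in path], dtype=object)
    return StageSequence(labels, probabilities=post, classes=model.classes,
                         flags=missing)


def _logsumexp(scores: np.ndarray) -> np.ndarray:
    m = scores.max(axis=1, keepdims=True)
    return m + np.log(np.exp(scores - m).sum(axis=1, keepdims=True))


def merge_classes(stages: StageSequence, scheme: str) -> StageSequence:
    """Remap a four-class sequence to a coarser scheme.

    ``scheme`` is ``"four"``, ``"three"`` (N1+N2 and N3 merge into NREM,
    code N), or ``"one_vs_rest:<code>"`` (the named class becomes ``pos``,
    everything else ``neg``). Probabilities, when present, are summed over
    the merged classes.
    """
    if tuple(stages.classes) != STAGES:
        raise ValueError("merge_classes expects a four-class input")
    if scheme == "four":
        mapping = {s: s for s in STAGES}
        classes = STAGES
    elif scheme == "three":
        mapping = {"W": "W", "L": "N", "D": "N", "R": "R"}
        classes = ("W", "N", "R")
    elif scheme.startswith("one_vs_rest:"):
        pos = scheme.split(":", 1)[1]
        if pos not in STAGES:
            raise ValueError(f"unknown positive class {pos!r}")
        mapping = {s: ("pos" if s == pos else "neg") for s in STAGES}
        classes = ("pos", "neg")
    else:
        raise ValueError(f"unknown merge scheme {scheme!r}")

    labels = np.array([mapping[s] for s in stages.labels], dtype=object)
    probs = None
    if stages.probabilities is not None:
        probs = np.zeros((len(labels), len(classes)))
        for i, s in enumerate(STAGES):
            probs[:, classes.index(mapping[s])] += stages.probabilities[:, i]
    return StageSequence(labels, probabilities=probs, classes=classes,
                         epoch_s=stages.epoch_s, flags=stages.flags)
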