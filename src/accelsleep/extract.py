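"""Classifier inputs from raw triaxial acceleration.

The chain mirrors the staging front-end: the three channels are summed into
one seismocardiographic signal from which heartbeats are localized (dynamic
programming over envelope peaks with an IBI-smoothness prior, plus a
periodicity-based quality self-assessment); instantaneous heart rate is
60/IBI held constant between beats at 10 Hz, with low-quality stretches
masked out. In parallel the channels are filtered and decimated to 10 Hz,
converted to an orientation signal (two horizontal spirit-level components
and a vertical one), from which respiratory effort is estimated; per-second
activity counts quantify gross body movement and are mixed back into the
effort signal as (1 + Act)·Res so movement artifacts look like those of a
thoracic belt.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import (BeatSeries, EffortBundle, GappedSeries, OrientationSignal,
                    TriaxialAccel)


def collapse_channels(accel: TriaxialAccel) -> np.ndarray:
    """Reduce the 3-D acceleration to 1-D by summing the channels."""
    return accel.x + accel.y + accel.z


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _block_percentile(x: np.ndarray, fs: float, block_s: float, q: float) -> np.ndarray:
    """Per-block percentile, held per sample (robust local scale).

    Block scales are capped at 3x their median so short high-amplitude
    artifacts (movement bursts) cannot flatten the normalized envelope of
    their whole block.
    """
    n = len(x)
    bl = max(int(block_s * fs), 1)
    n_blocks = max(n // bl, 1)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    scales = np.array([np.percentile(x[edges[i]:edges[i + 1]], q)
                       for i in range(n_blocks)])
    scales = np.minimum(scales, 3.0 * np.median(scales))
    out = np.empty(n)
    for i in range(n_blocks):
        out[edges[i]:edges[i + 1]] = scales[i]
    return out


def detect_heartbeats(s: np.ndarray, fs: float,
                      ibi_bounds: tuple[float, float] = (0.33, 2.0),
                      smoothness_weight: float = 10.0,
                      beat_cost: float = 0.25) -> BeatSeries:
    """Localize heartbeats in the channel-summed acceleration.

    The 5–20 Hz band-passed envelope is peak-picked, and the admissible
    peak sequence maximizing

        sum(normalized envelope amplitude - beat_cost)
        - smoothness_weight * sum((IBI_{i+1} - IBI_i)^2)

    is found by dynamic programming, so beats sit on points of maximum
    acceleration while the IBIs follow the local periodicity. Per-beat
    quality is the autocorrelation peak ratio of the envelope in a ±5 s
    window, clipped to [0, 1].

    Parameters
    ----------
    s : ndarray
        Channel-summed acceleration (g).
    fs : float
        Sampling rate, >= 50 Hz.
    ibi_bounds : (float, float)
        Admissible IBI range in seconds (default 0.33–2.0, i.e. 30–180 bpm).
    smoothness_weight : float
        Weight of the squared successive-IBI-difference penalty (1/s²).
    beat_cost : float
        Per-beat amplitude threshold; peaks weaker than this lower the score.
    """
    ibi_lo, ibi_hi = ibi_bounds
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    if not 0 < ibi_lo < ibi_hi:
        raise ValueError("require 0 < ibi_lo < ibi_hi")
    s = np.asarray(s, dtype=float)
    if len(s) < 2 * ibi_hi * fs:
        warnings.warn("recording shorter than two maximal IBIs; no beats detected")
        return BeatSeries.from_times(np.empty(0))
    if not np.any(s - s[0]):
        return BeatSeries.from_times(np.empty(0))

    band = _bandpass(s, fs, 5.0, min(20.0, 0.45 * fs))
    env = np.abs(sps.hilbert(band))
    # light smoothing (~10 ms) so one heartbeat gives one envelope peak
    k = max(int(0.01 * fs), 1)
    env = np.convolve(env, np.ones(k) / k, mode="same")
    scale = _block_percentile(env, fs, 10.0, 95.0)
    env_n = env / np.maximum(scale, 1e-12)

    peaks, _ = sps.find_peaks(env_n, distance=max(int(0.25 * fs), 1), height=0.15)
    if len(peaks) < 2:
        return BeatSeries.from_times(np.empty(0))
    tp = peaks / fs
    amp = np.minimum(env_n[peaks], 2.0)

    # Dynamic programming over edges (previous peak j, current peak k).
    # Besides regular beat-to-beat edges (IBI within bounds, smoothness
    # penalty against the previous IBI), a chain may resume after a gap
    # longer than ibi_hi (e.g. a movement artifact) via a penalty-free
    # "break" edge from the best chain ending before the gap.
    n_pk = len(peaks)
    edge_score: list[np.ndarray] = [np.empty(0)] * n_pk
    edge_ibi: list[np.ndarray] = [np.empty(0)] * n_pk
    edge_prev: list[np.ndarray] = [np.empty(0, int)] * n_pk
    edge_back: list[np.ndarray] = [np.empty(0, int)] * n_pk
    start_score = amp - beat_cost
    node_best = np.full(n_pk, -np.inf)
    node_best_edge = np.full(n_pk, -1, dtype=int)
    prefix_best = np.full(n_pk + 1, -np.inf)   # max node_best over nodes < i
    prefix_node = np.full(n_pk + 1, -1, dtype=int)
    best_final, best_node = -np.inf, -1
    for kk in range(n_pk):
        j0 = np.searchsorted(tp, tp[kk] - ibi_hi, side="left")
        j1 = np.searchsorted(tp, tp[kk] - ibi_lo, side="right")
        js = list(range(j0, j1))
        sc, bk, ibis = [], [], []
        for j in js:
            ibi_jk = tp[kk] - tp[j]
            if len(edge_score[j]):
                pen = np.where(np.isnan(edge_ibi[j]), 0.0,
                               smoothness_weight * (ibi_jk - edge_ibi[j]) ** 2)
                cand = edge_score[j] - pen
                mi = int(np.argmax(cand))
                if cand[mi] >= start_score[j]:
                    sc.append(cand[mi])
                    bk.append(mi)
                else:
                    sc.append(start_score[j])
                    bk.append(-1)
            else:
                sc.append(start_score[j])
                bk.append(-1)
            ibis.append(ibi_jk)
        if prefix_best[j0] > -np.inf:  # resume across a long gap
            js.append(prefix_node[j0])
            sc.append(prefix_best[j0])
            bk.append(node_best_edge[prefix_node[j0]])
            ibis.append(np.nan)
        if js:
            edge_score[kk] = np.asarray(sc) + amp[kk] - beat_cost
            edge_ibi[kk] = np.asarray(ibis)
            edge_prev[kk] = np.asarray(js, dtype=int)
            edge_back[kk] = np.asarray(bk, dtype=int)
            mi = int(np.argmax(edge_score[kk]))
            node_best[kk] = edge_score[kk][mi]
            node_best_edge[kk] = mi
            if node_best[kk] > best_final:
                best_final, best_node = node_best[kk], kk
        else:
            node_best[kk] = start_score[kk]
            node_best_edge[kk] = -1
        if node_best[kk] > prefix_best[kk]:
            prefix_best[kk + 1] = node_best[kk]
            prefix_node[kk + 1] = kk
        else:
            prefix_best[kk + 1] = prefix_best[kk]
            prefix_node[kk + 1] = prefix_node[kk]
    if best_node < 0:
        return BeatSeries.from_times(np.empty(0))

    chain = [best_node]
    node, edge = best_node, int(node_best_edge[best_node])
    while edge >= 0:
        prev = int(edge_prev[node][edge])
        chain.append(prev)
        edge = int(edge_back[node][edge])
        node = prev
    chain.reverse()
    beat_times = tp[chain]
    quality = _periodicity_quality(env_n, peaks[chain], fs, ibi_lo, ibi_hi)
    return BeatSeries.from_times(beat_times, quality=quality)


def _periodicity_quality(env: np.ndarray, idx: np.ndarray, fs: float,
                         ibi_lo: float, ibi_hi: float,
                         half_window_s: float = 5.0) -> np.ndarray:
    """Autocorrelation peak ratio of the envelope around each beat."""
    w = int(half_window_s * fs)
    lag0 = int(ibi_lo * fs)
    lag1 = int(ibi_hi * fs)
    q = np.empty(len(idx))
    for i, p in enumerate(idx):
        seg = env[max(p - w, 0):p + w]
        seg = seg - seg.mean()
        ac = sps.correlate(seg, seg, mode="full", method="fft")[len(seg) - 1:]
        if ac[0] <= 0:
            q[i] = 0.0
            continue
        hi = min(lag1 + 1, len(ac))
        q[i] = np.clip(ac[lag0:hi].max() / ac[0], 0.0, 1.0) if hi > lag0 else 0.0
    return q


def compute_ihr(beats: BeatSeries, duration: float | None = None,
                fs: float = 10.0) -> GappedSeries:
    """Instantaneous heart rate, 60/IBI, sample-and-hold at ``fs`` Hz.

    The value 60/IBI_i holds on [t_i, t_{i+1}); samples before the first
    beat or after the last beat's hold interval are invalid.
    """
    if duration is None:
        duration = beats.end
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    values = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    if len(beats) == 0:
        return GappedSeries(fs, values, valid)
    idx = np.searchsorted(beats.times, t, side="right") - 1
    ok = idx >= 0
    safe = np.where(ok, idx, 0)
    within = t < beats.times[safe] + beats.ibis[safe]
    valid = ok & within
    values[valid] = 60.0 / beats.ibis[safe[valid]]
    return GappedSeries(fs, values, valid)


def mask_low_quality(ihr: GappedSeries, beats: BeatSeries, q_min: float) -> GappedSeries:
    """Invalidate IHR samples whose governing beat has quality < q_min."""
    if not 0 <= q_min <= 1:
        raise ValueError("q_min must lie in [0, 1]")
    out = ihr.copy()
    if len(beats) == 0 or q_min == 0:
        return out
    t = out.t
    idx = np.searchsorted(beats.times, t, side="right") - 1
    safe = np.where(idx >= 0, idx, 0)
    low = (idx >= 0) & (beats.quality[safe] < q_min)
    out.valid &= ~low
    return out


def decimate_accel(accel: TriaxialAccel, target_fs: float = 10.0) -> TriaxialAccel:
    """Anti-aliased decimation of the three channels to ``target_fs``."""
    if target_fs >= accel.fs:
        raise ValueError("target_fs must be below the input rate")
    ratio = accel.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        k = int(round(ratio))
        sos = sps.butter(8, 0.45 * target_fs, btype="low", fs=accel.fs, output="sos")
        chans = [sps.sosfiltfilt(sos, c)[::k] for c in (accel.x, accel.y, accel.z)]
    else:
        from fractions import Fraction
        fr = Fraction(target_fs / accel.fs).limit_denominator(10000)
        chans = [sps.resample_poly(c, fr.numerator, fr.denominator, padtype="line")
                 for c in (accel.x, accel.y, accel.z)]
    return TriaxialAccel(fs=target_fs, x=chans[0], y=chans[1], z=chans[2],
                         start=accel.start)


def to_orientation(accel10: TriaxialAccel,
                   gravity_ref: np.ndarray | None = None) -> OrientationSignal:
    """Convert 10 Hz acceleration to a unit orientation signal.

    ``v`` is the projection of the unit acceleration vector onto the gravity
    direction — by default the 0.05 Hz low-pass of the unit vectors, or a
    fixed external reference if ``gravity_ref`` is given. ``(h1, h2)`` are
    the components in the orthogonal plane with a deterministic basis whose
    first vector is the normalized projection of the device x-axis.
    Samples with near-zero vector norm (< 0.1 g) are marked invalid.
    """
    a = accel10.as_matrix()
    norms = np.linalg.norm(a, axis=1)
    valid = norms >= 0.1
    safe = np.where(norms > 1e-12, norms, 1.0)
    u = a / safe[:, None]
    u[~valid] = (0.0, 0.0, 1.0)

    if gravity_ref is not None:
        g = np.asarray(gravity_ref, dtype=float)
        g = g / np.linalg.norm(g)
        g = np.broadcast_to(g, u.shape).copy()
    else:
        sos = sps.butter(2, 0.05, btype="low", fs=accel10.fs, output="sos")
        g = sps.sosfiltfilt(sos, u, axis=0)
        gn = np.linalg.norm(g, axis=1)
        g = g / np.where(gn > 1e-12, gn, 1.0)[:, None]

    xaxis = np.array([1.0, 0.0, 0.0])
    e1 = xaxis - g * (g @ xaxis)[:, None]
    n1 = np.linalg.norm(e1, axis=1)
    degen = n1 < 1e-6  # gravity along the device x-axis
    if np.any(degen):
        yaxis = np.array([0.0, 1.0, 0.0])
        alt = yaxis - g[degen] * (g[degen] @ yaxis)[:, None]
        e1[degen] = alt
        n1 = np.linalg.norm(e1, axis=1)
    e1 = e1 / n1[:, None]
    e2 = np.cross(g, e1)

    v = np.einsum("ij,ij->i", u, g)
    h1 = np.einsum("ij,ij->i", u, e1)
    h2 = np.einsum("ij,ij->i", u, e2)
    return OrientationSignal(h1=h1, h2=h2, v=v, valid=valid, fs=accel10.fs)


def estimate_effort(orient: OrientationSignal, window_s: float = 60.0,
                    band: tuple[float, float] = (0.1, 0.7),
                    norm_window_s: float = 300.0) -> GappedSeries:
    """Respiratory effort from the horizontal orientation components.

    Projects (h1, h2) onto their dominant direction in sliding 60-s windows
    (principal direction of the windowed covariance, sign-continuous),
    band-passes to the respiratory band, and normalizes to unit
    interquartile range per 5-min window. This is a transparent estimator
    standing behind the respiratory-effort interface; any 10 Hz estimator
    with the same contract (e.g. a learned one) can replace it.
    """
    fs = orient.fs
    n = len(orient)
    if n == 0:
        return GappedSeries(fs, np.empty(0), np.empty(0, bool))
    h = np.column_stack([orient.h1, orient.h2])
    valid = orient.valid.copy()

    bl = max(int(window_s * fs), 2)
    n_blocks = max(int(np.ceil(n / bl)), 1)
    proj = np.empty(n)
    prev_dir = None
    for b in range(n_blocks):
        sl = slice(b * bl, min((b + 1) * bl, n))
        hb = h[sl][valid[sl]]
        if len(hb) >= 4:
            hb = hb - hb.mean(axis=0)
            cov = hb.T @ hb / len(hb)
            _, vecs = np.linalg.eigh(cov)
            d = vecs[:, -1]  # dominant eigenvector
        else:
            d = prev_dir if prev_dir is not None else np.array([1.0, 0.0])
        if prev_dir is None:
            if (d[0] < 0) or (d[0] == 0 and d[1] < 0):
                d = -d
        elif d @ prev_dir < 0:
            d = -d
        prev_dir = d
        proj[sl] = h[sl] @ d

    # interpolate across invalid samples before filtering to limit ringing
    if not valid.all() and valid.any():
        idx = np.arange(n)
        proj = np.interp(idx, idx[valid], proj[valid])
    if valid.any():
        lo, hi = band
        sos = sps.butter(2, [lo, hi], btype="band", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, proj)
    else:
        out = np.zeros(n)

    nb = max(int(norm_window_s * fs), 2)
    n_nb = max(int(np.ceil(n / nb)), 1)
    global_iqr = np.subtract(*np.percentile(out[valid], [75, 25])) if valid.any() else 0.0
    scaled = np.empty(n)
    for b in range(n_nb):
        sl = slice(b * nb, min((b + 1) * nb, n))
        seg = out[sl][valid[sl]]
        iqr = np.subtract(*np.percentile(seg, [75, 25])) if len(seg) >= 4 else global_iqr
        if iqr < 1e-9:
            iqr = global_iqr if global_iqr >= 1e-9 else 1.0
        scaled[sl] = out[sl] / iqr
    return GappedSeries(fs, scaled, valid)


def activity_counts(accel: TriaxialAccel) -> np.ndarray:
    """Per-second activity counts.

    For each full second: the mean absolute deviation from the window mean,
    computed per channel and summed over the three channels. The trailing
    partial second is dropped.
    """
    n_per = int(round(accel.fs))
    if n_per < 1:
        raise ValueError("fs must be >= 1 Hz")
    n_sec = len(accel) // n_per
    out = np.zeros(n_sec)
    for ch in (accel.x, accel.y, accel.z):
        w = ch[:n_sec * n_per].reshape(n_sec, n_per)
        out += np.abs(w - w.mean(axis=1, keepdims=True)).mean(axis=1)
    return out


def mix_effort(res: GappedSeries, act_1hz: np.ndarray, act_scale: float) -> GappedSeries:
    """Mix activity into the effort signal: ResAct = (1 + scale·Act) · Res.

    Act is upsampled to 10 Hz by sample-and-hold; the offset by 1.0 keeps
    the effort unattenuated where there is no movement. Invalid Res samples
    stay invalid.
    """
    if act_scale <= 0:
        raise ValueError("act_scale must be positive")
    act_1hz = np.asarray(act_1hz, dtype=float)
    up = int(round(res.fs))
    act10 = np.repeat(act_1hz, up)
    if abs(len(act10) - len(res)) > up:
        raise ValueError(
            f"length mismatch after upsampling: Act gives {len(act10)} samples, "
            f"Res has {len(res)}")
    n = min(len(act10), len(res))
    vals = (1.0 + act_scale * act10[:n]) * res.values[:n]
    return GappedSeries(res.fs, vals, res.valid[:n].copy(), res.start)


def extract_bundle(accel: TriaxialAccel, config=None) -> tuple[EffortBundle, BeatSeries]:
    """Run the full front-end: acceleration in, classifier inputs out."""
    from .config import PipelineConfig
    cfg = config or PipelineConfig(fs=accel.fs)
    s = collapse_channels(accel)
    beats = detect_heartbeats(s, accel.fs, (cfg.ibi_lo, cfg.ibi_hi),
                              cfg.smoothness_weight)
    ihr = compute_ihr(beats, duration=accel.duration, fs=cfg.target_fs)
    ihr = mask_low_quality(ihr, beats, cfg.q_min)
    acc10 = decimate_accel(accel, cfg.target_fs)
    res = estimate_effort(to_orientation(acc10))
    act = activity_counts(accel)

    n = min(len(ihr), len(res), len(act) * int(round(cfg.target_fs)))
    ihr = GappedSeries(ihr.fs, ihr.values[:n], ihr.valid[:n])
    res = GappedSeries(res.fs, res.values[:n], res.valid[:n])
    resact = mix_effort(res, act, cfg.act_scale)
    n = min(n, len(resact))
    act10 = np.repeat(act, int(round(cfg.target_fs)))[:n]
    bundle = EffortBundle(
        ihr=GappedSeries(ihr.fs, ihr.values[:n], ihr.valid[:n]),
        res=GappedSeries(res.fs, res.values[:n], res.valid[:n]),
        act=act,
        act10=act10,
        resact=GappedSeries(resact.fs, resact.values[:n], resact.valid[:n]))
    return bundle, beats
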