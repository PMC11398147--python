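"""Hypnogram agreement and sleep-metric evaluation.

Epoch-by-epoch agreement (confusion matrix, Cohen's kappa, accuracy,
one-vs-rest sensitivity/specificity/PPV), overnight sleep metrics with
Bland–Altman 95% limits of agreement, M-gap stage-interval analysis, and
factor-influence statistics (Mann–Whitney U, Spearman rank correlation,
Benjamini–Hochberg FDR control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import STAGES, STAGE_NAMES, StageSequence

#: the conventional reporting order for confusion tables
TABLE_ORDER = ("L", "D", "R", "W")


@dataclass
class ConfusionMatrix:
    """Reference-by-estimate epoch counts with row percentages."""

    classes: tuple
    counts: np.ndarray  # rows: reference, columns: estimate

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape must match the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percentages(self) -> np.ndarray:
        """Each cell as % of its reference-class row total (NaN for empty rows)."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, self.counts / rows * 100.0, np.nan)

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        names = [STAGE_NAMES.get(c, c) for c in self.classes]
        pct = self.row_percentages
        data = [[f"{self.counts[i, j]:,} ({pct[i, j]:.{decimals}f}%)"
                 for j in range(len(names))] for i in range(len(names))]
        return pd.DataFrame(data, index=names, columns=names)


def confusion(ref: StageSequence, est: StageSequence,
              class_order: tuple = TABLE_ORDER) -> ConfusionMatrix:
    """Count estimate-vs-reference epochs over a shared class order."""
    if len(ref) != len(est):
        raise ValueError(f"length mismatch: reference {len(ref)} vs estimate {len(est)}")
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for a, b in zip(ref.labels, est.labels):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(tuple(class_order), counts)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement from a confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed and p_e the
    chance agreement from the marginals. In the degenerate case p_e = 1
    (a single class on both sides), kappa is 1 when agreement is perfect.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / total
    rows = cm.counts.sum(axis=1) / total
    cols = cm.counts.sum(axis=0) / total
    pe = float(rows @ cols)
    if abs(1.0 - pe) < 1e-12:
        warnings.warn("degenerate single-class agreement; kappa by convention")
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def accuracy(cm: ConfusionMatrix) -> float:
    """Observed agreement as a percentage."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total * 100.0)


@dataclass
class BinaryMetrics:
    sensitivity: float  # %
    specificity: float  # %
    ppv: float          # %
    accuracy: float     # %


def binary_metrics(cm: ConfusionMatrix, positive) -> BinaryMetrics:
    """One-vs-rest sensitivity, specificity, PPV and accuracy (percent).

    Undefined denominators yield NaN ("missing"), never zero.
    """
    if positive not in cm.classes:
        raise ValueError(f"unknown positive class {positive!r}")
    i = cm.classes.index(positive)
    tp = cm.counts[i, i]
    fn = cm.counts[i].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fn - fp

    def pct(num, den):
        return float(num / den * 100.0) if den > 0 else float("nan")

    return BinaryMetrics(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        accuracy=pct(tp + tn, cm.total),
    )


@dataclass
class CohortSummary:
    """Both summary forms, with the distribution-appropriate one marked."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normal: bool
    primary: str  # "mean±sd" or "median{Q1,Q3}"

    def __str__(self) -> str:
        if self.primary == "mean±sd":
            return f"{self.mean:.3g} ± {self.sd:.3g}"
        return f"{self.median:.3g} {{{self.q1:.3g}, {self.q3:.3g}}}"


def cohort_summary(values, alpha: float = 0.05) -> CohortSummary:
    """Summarize per-recording values: mean ± SD if normally distributed
    (Shapiro–Wilk at ``alpha``), else median with quartiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("cohort summary requires at least 3 values")
    if np.ptp(v) == 0:
        normal = True  # constant sample; Shapiro is undefined
    else:
        normal = bool(stats.shapiro(v).pvalue >= alpha)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return CohortSummary(
        n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)),
        median=float(med), q1=float(q1), q3=float(q3), normal=normal,
        primary="mean±sd" if normal else "median{Q1,Q3}")


@dataclass
class SleepMetrics:
    """Overnight summary metrics from a hypnogram (30-s epochs, 0.5 min each).

    Sleep onset is the first non-Wake epoch; latencies are measured from
    recording start (sleep latency) and from onset (stage-R latency).
    Metrics undefined on the given night (e.g. no sleep) are NaN.
    """

    tst: float                 # total sleep time, min
    sleep_latency: float       # min
    waso: float                # wake after sleep onset, min
    rem_latency: float         # stage-R latency from onset, min
    sleep_efficiency: float    # %
    time_in: dict = field(default_factory=dict)   # minutes per stage code
    pct_tst: dict = field(default_factory=dict)   # % of TST per stage code


def sleep_metrics(hyp: StageSequence) -> SleepMetrics:
    """Compute the sleep-metric battery from one hypnogram."""
    if len(hyp) == 0:
        raise ValueError("empty hypnogram")
    labels = np.asarray(hyp.labels, dtype=object)
    epoch_min = hyp.epoch_s / 60.0
    n = len(labels)
    sleep = labels != "W"
    time_in = {s: float((labels == s).sum() * epoch_min) for s in STAGES}
    tst = float(sleep.sum() * epoch_min)
    se = tst / (n * epoch_min) * 100.0
    if not sleep.any():
        return SleepMetrics(tst=0.0, sleep_latency=np.nan, waso=np.nan,
                            rem_latency=np.nan, sleep_efficiency=0.0,
                            time_in=time_in,
                            pct_tst={s: np.nan for s in STAGES})
    onset = int(np.argmax(sleep))
    latency = onset * epoch_min
    waso = float((labels[onset:] == "W").sum() * epoch_min)
    rem_idx = np.nonzero(labels == "R")[0]
    rem_latency = float((rem_idx[0] - onset) * epoch_min) if len(rem_idx) else np.nan
    pct_tst = {s: time_in[s] / tst * 100.0 for s in STAGES}
    return SleepMetrics(tst=tst, sleep_latency=latency, waso=waso,
                        rem_latency=rem_latency, sleep_efficiency=se,
                        time_in=time_in, pct_tst=pct_tst)


@dataclass
class BlandAltman:
    """Error distribution of estimate minus reference, per recording."""

    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    loa_lower: float
    loa_upper: float


def bland_altman(est, ref) -> BlandAltman:
    """Bland–Altman summary of paired per-recording metric errors.

    Errors are estimate minus reference; the 95% limits of agreement are
    mean(error) ± 1.96 · SD(error) with the sample (n−1) SD.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("est and ref must pair up")
    ok = np.isfinite(est) & np.isfinite(ref)
    e = est[ok] - ref[ok]
    if len(e) < 3:
        raise ValueError("Bland-Altman requires at least 3 pairs")
    q1, med, q3 = np.percentile(e, [25, 50, 75])
    mean = float(e.mean())
    sd = float(e.std(ddof=1))
    return BlandAltman(n=len(e), median=float(med), q1=float(q1), q3=float(q3),
                       mean=mean, sd=sd,
                       loa_lower=mean - 1.96 * sd, loa_upper=mean + 1.96 * sd)


@dataclass
class StageIntervalSet:
    """Maximal stage intervals tolerating gaps of at most M epochs."""

    stage: str
    m: int
    intervals: list  # (start epoch, end epoch), inclusive, 0-based


def stage_intervals(hyp: StageSequence, stage: str, m: int) -> StageIntervalSet:
    """Find the maximal intervals in which ``stage`` occurs without being
    interrupted by more than ``m`` consecutive other-stage epochs.

    Intervals start and end on epochs of the target stage; consecutive
    intervals are separated by gaps longer than ``m``.
    """
    if m < 0:
        raise ValueError("M must be non-negative")
    idx = np.nonzero(np.asarray(hyp.labels, dtype=object) == stage)[0]
    if len(idx) == 0:
        return StageIntervalSet(stage, m, [])
    intervals = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev - 1 > m:
            intervals.append((start, prev))
            start = int(i)
        prev = int(i)
    intervals.append((start, prev))
    return StageIntervalSet(stage, m, intervals)


@dataclass
class IntervalMatchReport:
    n_ref: int
    n_est: int
    matched_ref: int            # reference intervals overlapped by >= 1 estimate
    unmatched_ref: list         # reference intervals with no estimate overlap
    unmatched_est: list         # estimate intervals with no reference overlap
    pairs: list                 # one-to-one (ref, est) pairs


def match_intervals(ref: StageIntervalSet, est: StageIntervalSet) -> IntervalMatchReport:
    """Match stage intervals between reference and estimate.

    Two intervals overlap when they share at least one epoch. One-to-one
    pairs are assigned by greatest shared-epoch count; ties go to the
    earliest reference interval.
    """
    if ref.stage != est.stage:
        raise ValueError("interval sets must target the same stage")

    def shared(a, b):
        return min(a[1], b[1]) - max(a[0], b[0]) + 1

    overl_ref = [r for r in ref.intervals if any(shared(r, e) >= 1 for e in est.intervals)]
    unmatched_ref = [r for r in ref.intervals if r not in overl_ref]
    unmatched_est = [e for e in est.intervals
                     if all(shared(r, e) < 1 for r in ref.intervals)]

    cands = [(shared(r, e), r, e) for r in ref.intervals for e in est.intervals
             if shared(r, e) >= 1]
    cands.sort(key=lambda c: (-c[0], c[1][0], c[2][0]))
    used_r, used_e, pairs = set(), set(), []
    for s, r, e in cands:
        if r in used_r or e in used_e:
            continue
        used_r.add(r)
        used_e.add(e)
        pairs.append((r, e))
    pairs.sort(key=lambda p: p[0][0])
    return IntervalMatchReport(
        n_ref=len(ref.intervals), n_est=len(est.intervals),
        matched_ref=len(overl_ref), unmatched_ref=unmatched_ref,
        unmatched_est=unmatched_est, pairs=pairs)


def factor_influence(kappas, binary_factors: dict | None = None,
                     continuous_factors: dict | None = None,
                     fdr: float = 0.05) -> pd.DataFrame:
    """Test which cohort factors influence per-recording agreement.

    Binary factors get a two-sided Mann–Whitney U test (exact distribution
    for group sizes <= 8, normal approximation with tie correction
    otherwise); continuous factors a Spearman rank correlation with kappa.
    All p-values are jointly Benjamini–Hochberg adjusted at the given FDR.
    """
    kappas = np.asarray(kappas, dtype=float)
    rows = []
    for name, flags in (binary_factors or {}).items():
        flags = np.asarray(flags, dtype=bool)
        g1, g0 = kappas[flags], kappas[~flags]
        if len(g1) == 0 or len(g0) == 0:
            warnings.warn(f"factor {name!r} has an empty group; skipped")
            continue
        method = "exact" if max(len(g0), len(g1)) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method=method)
        rows.append({"factor": name, "type": "binary",
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    for name, vals in (continuous_factors or {}).items():
        rho, p = stats.spearmanr(np.asarray(vals, dtype=float), kappas)
        rows.append({"factor": name, "type": "continuous",
                     "statistic": float(rho), "p": float(p)})
    df = pd.DataFrame(rows, columns=["factor", "type", "statistic", "p"])
    if len(df):
        reject, p_adj, _, _ = multipletests(df["p"].to_numpy(), alpha=fdr,
                                            method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = reject
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    return df


TASKS = ("four", "three", "one_vs_rest:L", "one_vs_rest:D",
         "one_vs_rest:R", "one_vs_rest:W")


def agreement_report(ref_seqs: list[StageSequence],
                     est_seqs: list[StageSequence]) -> pd.DataFrame:
    """Per-recording agreement for every classification task.

    Returns one row per (recording, task) with kappa, accuracy, and — for
    the binary tasks — sensitivity, specificity, and PPV in percent. Kappa
    is NaN (flagged missing) when a recording is single-class on both sides.
    """
    from .stage import merge_classes
    if len(ref_seqs) != len(est_seqs):
        raise ValueError("reference and estimate cohorts must pair up")
    rows = []
    for i, (ref, est) in enumerate(zip(ref_seqs, est_seqs)):
        for task in TASKS:
            r = merge_classes(ref, task)
            e = merge_classes(est, task)
            order = tuple(r.classes)
            cm = confusion(r, e, class_order=order)
            degenerate = (len(set(r.labels)) == 1 and set(r.labels) == set(e.labels))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kap = np.nan if degenerate else cohens_kappa(cm)
            row = {"recording": i, "task": task, "kappa": kap,
                   "accuracy": accuracy(cm)}
            if task.startswith("one_vs_rest:"):
                bm = binary_metrics(cm, "pos")
                row.update(sensitivity=bm.sensitivity, specificity=bm.specificity,
                           ppv=bm.ppv)
            rows.append(row)
    return pd.DataFrame(rows)
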