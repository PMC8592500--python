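"""Evaluation protocol: regime matrix, alarm scoring, chance-level statistics.

Covers four layers of the evaluation:

* segment-level metrics (sensitivity, specificity, accuracy, rank-based AUC)
  of the pre-ictal/interictal classifier;
* the TRTR/TSTR/TRTS/TSTS matrix — every combination of training and testing
  on real vs synthesized data, with a time-disjoint test partition shared by
  the regimes that test on the same source;
* event-level alarm scoring under a seizure prediction horizon (SPH) and
  seizure occurrence period (SOP): an alarm at time t predicts a seizure with
  onset o iff t + SPH <= o <= t + SPH + SOP; alarms predicting no onset are
  false alarms, and FPR/h divides them by the interictal hours;
* the chance-level predictor: a random alarm process at rate FPR raises an
  alarm within one SOP with probability P = 1 - exp(-FPR * SOP); the
  significance of n correct predictions out of N seizures is the binomial
  tail p = sum_{k>=n} C(N,k) P^k (1-P)^(N-k).  Hanley-McNeil standard errors
  give a single-tailed z-test for comparing two independent AUCs.

Boundary conventions (the definitions above do not pin these down): an alarm
closer to the onset than SPH counts as a false alarm; after each alarm a
refractory period (default = SOP) suppresses further alarms; interictal hours
exclude the (onset - SPH - SOP, onset] windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cesp import CESPConfig, TrainedCESP, predict, train_plain
from .preprocess import SpectrogramImage
from .synthetic import PREICTAL, SeizureTimeline

REGIME_NAMES = ("TRTR", "TSTR", "TRTS", "TSTS")


@dataclass(frozen=True)
class RegimeSpec:
    name: str

    def __post_init__(self):
        if self.name not in REGIME_NAMES:
            raise ValueError(f"unknown regime {self.name!r}; one of {REGIME_NAMES}")

    @property
    def train_source(self) -> str:
        return "synthetic" if self.name[1] == "S" else "real"

    @property
    def test_source(self) -> str:
        return "synthetic" if self.name[3] == "S" else "real"


@dataclass
class SegmentMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else np.nan


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank statistic U / (n_pos * n_neg), midranks for ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def segment_metrics(scores, labels, threshold: float = 0.5) -> SegmentMetrics:
    """Confusion counts at a threshold plus rank-based AUC (pre-ictal = positive)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray([1 if l in (1, PREICTAL) else 0 for l in labels])
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels differ in length")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    auc = None
    if 0 < labels.sum() < labels.size:
        auc = mann_whitney_auc(scores, labels)
    return SegmentMetrics(tp, fp, tn, fn, auc)


def time_disjoint_split(images: list[SpectrogramImage],
                        test_fraction: float = 0.25,
                        ) -> tuple[list[SpectrogramImage], list[SpectrogramImage]]:
    """Split on ``t_start`` so test samples come from later time sections."""
    order = sorted(images, key=lambda im: (im.t_start, im.label))
    n_test = max(int(round(test_fraction * len(order))), 1)
    return order[:-n_test], order[-n_test:]


def run_regime_matrix(real: list[SpectrogramImage],
                      synthetic: list[SpectrogramImage],
                      cfg: CESPConfig,
                      specs: list[RegimeSpec] | None = None,
                      test_fraction: float = 0.25,
                      threshold: float = 0.5) -> pd.DataFrame:
    """Train one classifier per regime and evaluate on the shared test split.

    Both pools are split time-disjointly; regimes that test on the same
    source reuse the identical test partition so rows are comparable.
    """
    specs = specs or [RegimeSpec(n) for n in REGIME_NAMES]
    pools = {"real": real, "synthetic": synthetic}
    splits = {}
    for src in {s.train_source for s in specs} | {s.test_source for s in specs}:
        if not pools[src]:
            raise ValueError(f"regime matrix needs non-empty {src} data")
        splits[src] = time_disjoint_split(pools[src], test_fraction)
    rows = []
    for spec in specs:
        train_imgs = splits[spec.train_source][0]
        test_imgs = splits[spec.test_source][1]
        if len({im.label for im in train_imgs}) < 2:
            raise ValueError(f"{spec.name}: training split lacks a class")
        trained = train_plain(train_imgs, cfg)
        scores = predict(trained, test_imgs)
        m = segment_metrics(scores, [im.label for im in test_imgs], threshold)
        rows.append({"regime": spec.name, "n_train": len(train_imgs),
                     "n_test": len(test_imgs), "sensitivity": m.sensitivity,
                     "specificity": m.specificity, "accuracy": m.accuracy,
                     "auc": m.auc, "tp": m.tp, "fp": m.fp, "tn": m.tn,
                     "fn": m.fn})
    return pd.DataFrame(rows).set_index("regime")


# ---------------------------------------------------------------------------
# event-level alarm scoring


@dataclass(frozen=True)
class AlarmConfig:
    sph: float = 10.0        # minutes
    sop: float = 30.0        # minutes
    threshold: float = 0.5
    refractory: float | None = None   # minutes; None -> SOP

    def __post_init__(self):
        if self.sph <= 0 or self.sop <= 0:
            raise ValueError("sph and sop must be positive")

    @property
    def refractory_min(self) -> float:
        return self.sop if self.refractory is None else self.refractory


@dataclass
class AlarmEvaluation:
    n_seizures: int
    n_predicted: int
    true_alarms: int
    false_alarms: int
    alarm_times: list[float]
    interictal_hours: float

    @property
    def sensitivity_event(self) -> float:
        return self.n_predicted / self.n_seizures if self.n_seizures else np.nan

    @property
    def fpr_per_h(self) -> float:
        return self.false_alarms / self.interictal_hours \
            if self.interictal_hours > 0 else np.nan


def _interictal_hours(duration_s: float, onsets: list[float], sph_s: float,
                      sop_s: float) -> float:
    """Duration minus the union of (onset - SPH - SOP, onset] windows."""
    windows = sorted((max(o - sph_s - sop_s, 0.0), min(o, duration_s))
                     for o in onsets)
    covered, end = 0.0, 0.0
    for lo, hi in windows:
        lo = max(lo, end)
        if hi > lo:
            covered += hi - lo
            end = hi
        end = max(end, hi)
    return (duration_s - covered) / 3600.0


def alarm_evaluate(timeline: SeizureTimeline, times: np.ndarray,
                   scores: np.ndarray, cfg: AlarmConfig) -> AlarmEvaluation:
    """Score a continuous run of per-segment pre-ictal probabilities.

    ``times``/``scores`` are the segment start times (s) and classifier
    scores, time-sorted.  Alarms fire where the score crosses the threshold
    outside the refractory period; each alarm either predicts some onset
    (t + SPH <= onset <= t + SPH + SOP) or is a false alarm — every alarm is
    counted exactly once.
    """
    times = np.asarray(times, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if times.shape != scores.shape:
        raise ValueError("times and scores differ in shape")
    if np.any(np.diff(times) < 0):
        raise ValueError("scores must be sorted by time")
    sph_s, sop_s = cfg.sph * 60.0, cfg.sop * 60.0
    refr_s = cfg.refractory_min * 60.0
    alarms = []
    last = -np.inf
    for t, s in zip(times, scores):
        if s >= cfg.threshold and t - last >= refr_s:
            alarms.append(t)
            last = t
    onsets = list(timeline.seizure_onsets)
    predicted = set()
    false_alarms = 0
    for t in alarms:
        hits = [o for o in onsets if t + sph_s <= o <= t + sph_s + sop_s]
        if hits:
            predicted.update(hits)
        else:
            false_alarms += 1   # includes alarms closer than SPH to an onset
    return AlarmEvaluation(
        n_seizures=len(onsets), n_predicted=len(predicted),
        true_alarms=len(alarms) - false_alarms, false_alarms=false_alarms,
        alarm_times=alarms,
        interictal_hours=_interictal_hours(timeline.duration_h * 3600.0,
                                           onsets, sph_s, sop_s))


# ---------------------------------------------------------------------------
# chance-level predictor


def chance_probability(fpr_per_h: float, sop: float) -> float:
    """P = 1 - exp(-FPR * SOP): chance of a random alarm within one SOP.

    ``fpr_per_h`` is in alarms/hour and ``sop`` in minutes; the exponent is
    made dimensionless by converting SOP to hours.
    """
    if fpr_per_h < 0 or sop <= 0:
        raise ValueError("fpr_per_h must be >= 0 and sop > 0")
    return float(-np.expm1(-fpr_per_h * sop / 60.0))


def chance_pvalue(n: int, N: int, P: float) -> float:
    """Binomial tail p = sum_{k>=n} C(N,k) P^k (1-P)^(N-k)."""
    if not (0 <= n <= N):
        raise ValueError("need 0 <= n <= N")
    if not (0.0 <= P <= 1.0):
        raise ValueError("P must be in [0, 1]")
    if n == 0:
        return 1.0
    return float(stats.binom.sf(n - 1, N, P))


@dataclass
class ChanceTestResult:
    P: float
    p_value: float
    alpha: float = 0.05

    @property
    def reject_null(self) -> bool:
        return self.p_value < self.alpha


def chance_test(n: int, N: int, fpr_per_h: float, sop: float,
                alpha: float = 0.05) -> ChanceTestResult:
    """Is predicting n of N seizures better than a random alarm at this FPR?"""
    P = chance_probability(fpr_per_h, sop)
    return ChanceTestResult(P, chance_pvalue(n, N, P), alpha)


# ---------------------------------------------------------------------------
# AUC comparison


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a rank AUC."""
    if not (0 < auc < 1):
        raise ValueError("AUC must be strictly inside (0, 1); use exact "
                         "methods for degenerate AUCs")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need positive class counts")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return float(np.sqrt(var))


def hanley_mcneil_compare(auc1: float, n_pos1: int, n_neg1: int,
                          auc2: float, n_pos2: int, n_neg2: int) -> float:
    """Single-tailed p-value for AUC1 > AUC2, independent samples."""
    se1 = hanley_mcneil_se(auc1, n_pos1, n_neg1)
    se2 = hanley_mcneil_se(auc2, n_pos2, n_neg2)
    z = (auc1 - auc2) / np.sqrt(se1**2 + se2**2)
    return float(stats.norm.sf(z))


def bonferroni_alpha(alpha: float = 0.05, m: int = 4) -> float:
    """Per-comparison significance level for m comparisons."""
    return alpha / m


# ---------------------------------------------------------------------------
# ROC reporting


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold); trapezoid AUC equals the rank AUC."""
    from sklearn.metrics import roc_curve

    labels = np.asarray([1 if l in (1, PREICTAL) else 0 for l in labels])
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=np.float64))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def roc_report(named_scores: dict[str, tuple[np.ndarray, list]],
               out_dir: str | Path) -> pd.DataFrame:
    """Write per-run ROC CSVs and one overlay plot; return the AUC table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    rows = []
    for name, (scores, labels) in named_scores.items():
        pts = roc_points(scores, labels)
        pts.to_csv(out / f"roc_{name}.csv", index=False)
        auc = float(np.trapezoid(pts["tpr"], pts["fpr"]))
        rows.append({"name": name, "auc": auc, "n": len(labels)})
        ax.plot(pts["fpr"], pts["tpr"], label=f"{name} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(out / "roc.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    table = pd.DataFrame(rows).set_index("name")
    table.to_csv(out / "auc.csv")
    return table
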