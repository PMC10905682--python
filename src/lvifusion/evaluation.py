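"""ROC analysis, Youden operating points, and the DeLong paired AUC test.

AUC is computed as the Mann-Whitney U statistic with ties counted 1/2
(midranks), which equals the trapezoidal area under the empirical ROC curve.
The DeLong test estimates the covariance of two correlated AUCs from their
placement values (structural components) and refers the standardized AUC
difference to a two-sided normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "YoudenMetrics",
    "DeLongComparison",
    "compute_roc_auc",
    "metrics_at_youden",
    "auc_variance",
    "delong_test",
    "compare_models_report",
    "plot_roc_curves",
]


@dataclass
class RocResult:
    thresholds: np.ndarray  # descending; score >= threshold predicts positive
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class YoudenMetrics:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    youden_j: float
    confusion: np.ndarray  # [[tn, fp], [fn, tp]]


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float
    degenerate: bool = False


def _check_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be paired 1D arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must be binary with both classes present")
    return s, y.astype(int)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    allr = stats.rankdata(np.concatenate([pos, neg]))
    posr = stats.rankdata(pos)
    negr = stats.rankdata(neg)
    v10 = (allr[:m] - posr) / n
    v01 = 1.0 - (allr[m:] - negr) / m
    return v10, v01, float(v10.mean())


def compute_roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve over all unique thresholds plus the Mann-Whitney AUC."""
    s, y = _check_scores(np.asarray(scores, float), np.asarray(labels))
    _, _, auc = _placements(s, y)
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    pos, neg = s[y == 1], s[y == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
    )


def metrics_at_youden(roc: RocResult, scores: Sequence[float], labels: Sequence[int]) -> YoudenMetrics:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1;
    ties broken toward the lower threshold."""
    s, y = _check_scores(np.asarray(scores, float), np.asarray(labels))
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    t = float(np.min(roc.thresholds[best]))
    pred = (s >= t).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return YoudenMetrics(
        threshold=t,
        accuracy=(tp + tn) / len(y),
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        confusion=np.array([[tn, fp], [fn, tp]]),
    )


def auc_variance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """DeLong variance of a single AUC from its placement values."""
    s, y = _check_scores(np.asarray(scores, float), np.asarray(labels))
    v10, v01, _ = _placements(s, y)
    if len(v10) < 2 or len(v01) < 2:
        raise ValueError("need at least two cases per class")
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> DeLongComparison:
    """Paired DeLong comparison of two AUCs computed on the same cases."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    a, y = _check_scores(a, np.asarray(labels))
    b, _ = _check_scores(b, np.asarray(labels))
    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    m, n = len(v10a), len(v01a)
    var = float(np.var(v10a - v10b, ddof=1) / m + np.var(v01a - v01b, ddof=1) / n)
    diff = auc_a - auc_b
    if var <= 0.0:
        if diff == 0.0:
            return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0, degenerate=True)
        return DeLongComparison(auc_a, auc_b, diff, 0.0, np.inf, 0.0, degenerate=True)
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a, auc_b, diff, var, float(z), p)


def compare_models_report(
    model_scores: Mapping[str, Sequence[float]],
    labels: Sequence[int],
    reference: str | None = None,
) -> pd.DataFrame:
    """One row per model (AUC, accuracy, sensitivity, specificity at the
    Youden point) plus the DeLong p-value against the reference model."""
    if len(model_scores) < 2:
        raise ValueError("need at least two models to compare")
    names = list(model_scores)
    reference = reference if reference is not None else names[-1]
    if reference not in model_scores:
        raise ValueError(f"unknown reference model {reference!r}")
    y = np.asarray(labels)
    n = len(y)
    for name, s in model_scores.items():
        if len(np.asarray(s)) != n:
            raise ValueError(f"scores for {name!r} are not paired with the labels")
    rows = []
    ref_scores = np.asarray(model_scores[reference], dtype=float)
    for name in names:
        s = np.asarray(model_scores[name], dtype=float)
        roc = compute_roc_auc(s, y)
        met = metrics_at_youden(roc, s, y)
        if name == reference:
            p = np.nan
        else:
            p = delong_test(ref_scores, s, y).p_value
        rows.append(
            {
                "model": name,
                "auc": roc.auc,
                "accuracy": met.accuracy,
                "sensitivity": met.sensitivity,
                "specificity": met.specificity,
                "delong_p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)


def plot_roc_curves(
    model_scores: Mapping[str, Sequence[float]], labels: Sequence[int], path: str
) -> None:
    """ROC overlay figure for all models (written to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, s in model_scores.items():
        roc = compute_roc_auc(np.asarray(s, float), np.asarray(labels))
        ax.plot(1.0 - roc.specificity, roc.sensitivity, label=f"{name} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
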