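"""Classifier evaluation: confusion counts, Matthews correlation, ROC/AUC.

MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the value
defined as 0 whenever a denominator factor vanishes. AUC is the normalized
Mann-Whitney statistic — the probability that a random positive outscores a
random negative, ties counting one half — which equals the trapezoidal area
under the sensitivity vs (1 - specificity) curve. A perfect ranking scores
1; label-independent scoring averages 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    """(sensitivity, specificity) as the probability threshold sweeps 0 -> 1."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    vals = set(np.unique(y).tolist())
    if not vals <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got values {sorted(vals)}")
    return y.astype(int)


def confusion_at_threshold(labels, probabilities, threshold: float) -> ConfusionCounts:
    """Tally the confusion matrix calling positive when p >= threshold."""
    y = _as_binary(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError("labels and probabilities differ in length")
    pred = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is zero."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_at_threshold(labels, probabilities, threshold: float = 0.5) -> float:
    return mcc(confusion_at_threshold(labels, probabilities, threshold))


def mcc_max(labels, probabilities) -> tuple[float, float]:
    """Maximum MCC over all distinct-score thresholds; returns (mcc, threshold)."""
    p = np.asarray(probabilities, dtype=float)
    best, best_t = -1.0, 0.5
    for t in np.unique(p):
        v = mcc_at_threshold(labels, p, float(t))
        if v > best:
            best, best_t = v, float(t)
    return best, best_t


def auc_score(labels, scores) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties get half credit)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s, method="average")
    u = float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_auc(labels, scores) -> RocCurve:
    """Full ROC curve plus AUC.

    The curve is swept over the distinct scores from high to low; by
    construction its trapezoidal area equals the Mann-Whitney AUC.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    auc = auc_score(y, s)        # validates class presence
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.where(np.diff(s_sorted) != 0)[0], len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    sens = np.r_[0.0, tps / n_pos]
    spec = np.r_[1.0, 1.0 - fps / n_neg]
    return RocCurve(sensitivity=sens, specificity=spec, auc=auc)


def write_roc_tsv(path: str, curve: RocCurve) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#auc\t{curve.auc:.6f}\n")
        fh.write("#sensitivity\tspecificity\n")
        for se, sp in zip(curve.sensitivity, curve.specificity):
            fh.write(f"{se:.6f}\t{sp:.6f}\n")
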