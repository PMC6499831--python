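"""Evaluation protocol for pi-helix prediction.

Two complementary views are implemented.  Per-residue scoring treats every
position independently: a 4 x 4 confusion matrix over {E, H, I, C}, class
precision/sensitivity/F1, Q accuracy, and the precision-recall curve with
its area for the pi class.  Per-segment scoring pools true and predicted
pi-helical segments and counts a true segment as detected when any
predicted segment overlaps it by at least one residue (and symmetrically
for false positives) — segment identity matters, not exact boundaries.

Method comparison across datasets uses a paired t-test on per-sequence
F1 scores, restricted upstream to sequences that actually contain
pi-helical residues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CLASSES",
    "ResidueConfusion",
    "SegmentEval",
    "residue_confusion",
    "class_metrics",
    "segment_eval",
    "f1",
    "q_accuracy",
    "pr_curve_auc",
    "paired_f1_ttest",
]

CLASSES = "EHIC"
_CLS_IDX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class ResidueConfusion:
    """counts[i, j] = residues with true class CLASSES[i] predicted CLASSES[j]."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, true_cls: str, pred_cls: str) -> int:
        return int(self.counts[_CLS_IDX[true_cls], _CLS_IDX[pred_cls]])


class SegmentEval(NamedTuple):
    tp: int
    fn: int
    fp: int
    matched_pairs: list


def residue_confusion(true4: str, pred4: str) -> ResidueConfusion:
    """4 x 4 confusion counts over the {E, H, I, C} labels."""
    if len(true4) != len(pred4):
        raise ValueError("true/pred label strings differ in length")
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(true4, pred4):
        counts[_CLS_IDX[t], _CLS_IDX[p]] += 1
    return ResidueConfusion(counts=counts)


def class_metrics(conf: ResidueConfusion, cls: str = "I") -> dict[str, float]:
    """Precision, sensitivity and F1 of one class from a confusion matrix.

    True positives are correctly predicted residues of the class; false
    negatives are class residues predicted otherwise; false positives are
    other residues predicted as the class.
    """
    i = _CLS_IDX[cls]
    tp = int(conf.counts[i, i])
    fn = int(conf.counts[i].sum()) - tp
    fp = int(conf.counts[:, i].sum()) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1(precision, sensitivity),
    }


def _check_disjoint(segments: Sequence[tuple[int, int]], name: str) -> None:
    segs = sorted(segments)
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise ValueError(f"{name} segments overlap: ({s1},{e1}) and ({s2},{e2})")


def segment_eval(
    true_segments: Sequence[tuple[int, int]],
    pred_segments: Sequence[tuple[int, int]],
) -> SegmentEval:
    """Overlap-based segment scoring (inclusive ranges).

    A true segment overlapped (>= 1 residue) by any predicted segment is a
    true positive; unmatched true segments are false negatives; unmatched
    predicted segments are false positives.  One predicted segment may
    match several true segments — matching is by non-overlap, not
    one-to-one assignment.
    """
    _check_disjoint(true_segments, "true")
    _check_disjoint(pred_segments, "pred")
    matched_true = set()
    matched_pred = set()
    pairs = []
    for i, (ts, te) in enumerate(true_segments):
        for j, (ps, pe) in enumerate(pred_segments):
            if ts <= pe and ps <= te:
                matched_true.add(i)
                matched_pred.add(j)
                pairs.append((i, j))
    tp = len(matched_true)
    fn = len(true_segments) - tp
    fp = len(pred_segments) - len(matched_pred)
    return SegmentEval(tp=tp, fn=fn, fp=fp, matched_pairs=pairs)


def f1(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    if precision == 0.0 and sensitivity == 0.0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def q_accuracy(true_labels: str, pred_labels: str) -> float:
    """Fraction of residues whose predicted label matches the true label."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("label strings differ in length")
    if not true_labels:
        raise ValueError("empty label strings")
    return sum(t == p for t, p in zip(true_labels, pred_labels)) / len(true_labels)


def pr_curve_auc(true_is_pi: np.ndarray, p_pi: np.ndarray):
    """Precision-recall curve and area for pi-residue detection.

    Evaluates precision and recall at every distinct score threshold,
    anchors the curve at recall 0 with the precision of the most stringent
    threshold, and integrates by trapezoid over recall.  The random
    baseline (pi prevalence) is reported alongside.
    """
    y = np.asarray(true_is_pi, bool)
    s = np.asarray(p_pi, float)
    if y.shape != s.shape:
        raise ValueError("shape mismatch")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive residues: AUPRC undefined")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    k = np.arange(1, len(y) + 1)
    # indices of the last occurrence of each distinct threshold
    last = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    precision = tp_cum[last] / k[last]
    recall = tp_cum[last] / n_pos
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    area = float(np.trapezoid(precision, recall))
    prevalence = n_pos / len(y)
    return {"precision": precision, "recall": recall, "auprc": area, "baseline": prevalence}


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def paired_f1_ttest(f1_a: Sequence[float], f1_b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on per-sequence F1 scores.

    Returns the t statistic and p-value from the t distribution with n-1
    degrees of freedom.  Zero-variance differences are degenerate: p = 1
    when all differences are 0, otherwise the result is flagged and the
    p-value is 0 with an infinite statistic.
    """
    a = np.asarray(f1_a, float)
    b = np.asarray(f1_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if d.std(ddof=1) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        if np.allclose(d, 0.0, atol=1e-12):
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        warnings.warn("zero variance of nonzero paired differences; t is infinite")
        return TTestResult(t=math.copysign(math.inf, float(d.mean())), p=0.0, degenerate=True)
    t_stat, p_val = stats.ttest_rel(a, b)
    return TTestResult(t=float(t_stat), p=float(p_val), degenerate=False)
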