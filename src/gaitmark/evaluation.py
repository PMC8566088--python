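"""Recognition metrics: error rate, confusion matrix, majority vote,
transition success, and the auto-labeling success / data-selection rates.

Definitions (S = number of movement patterns):

* ``RE = N_mis / N_total * 100`` — recognition error rate in percent over
  the classifier's native unit (sliding windows); accuracy = 100 - RE.
* Confusion matrix ``r_ij = s_ij / s_i * 100`` — row percentages, where
  ``s_i`` counts true-class-i units and ``s_ij`` those predicted as j.
* ``SR = N_C / N_I`` — fraction of auto-labeled (threshold-selected) gait
  cycles whose DTW label matches the manual label.
* ``DR = D_C / D_I`` — fraction of all complete cycles whose best DTW
  cost is below the selection threshold k.
* N-point majority vote (N = 5) — each streamed prediction is replaced by
  the modal label of the trailing N predictions (causal smoothing).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional, Sequence

import numpy as np


@dataclasses.dataclass
class EvalReport:
    """Metrics for one experiment arm."""

    re_percent: float
    confusion: np.ndarray        # (S, S) row percentages
    n_total: int
    n_mis: int
    sr: float = float("nan")     # auto-label success rate, when applicable
    dr: float = float("nan")     # data selection rate, when applicable

    @property
    def accuracy_percent(self) -> float:
        return 100.0 - self.re_percent


def recognition_error(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Misclassified fraction in percent."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("prediction and truth streams must be equal-length "
                         "and non-empty")
    return 100.0 * float(np.count_nonzero(pred != truth)) / pred.size


def confusion_matrix(pred: Sequence[int], truth: Sequence[int],
                     n_classes: int) -> np.ndarray:
    """Row-percentage confusion matrix; empty-class rows are all zero."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if np.any((pred < 1) | (pred > n_classes) | (truth < 1) | (truth > n_classes)):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (truth - 1, pred - 1), 1.0)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(row > 0, 100.0 * counts / row, 0.0)
    return r


def majority_vote(stream: Sequence[int], n: int = 5) -> np.ndarray:
    """Causal N-point majority vote over the trailing window.

    Ties keep the previous output (the raw sample at the first index).
    During warm-up the shorter prefix is used; output length equals the
    input length.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("n must be odd and >= 1")
    s = list(stream)
    if not s:
        raise ValueError("empty stream")
    out: list[int] = []
    for i in range(len(s)):
        window = s[max(0, i - n + 1): i + 1]
        counts = Counter(window).most_common()
        top = counts[0][1]
        modes = {lab for lab, c in counts if c == top}
        if len(modes) == 1:
            out.append(counts[0][0])
        else:
            prev = out[i - 1] if i > 0 else s[0]
            out.append(prev if prev in modes else sorted(modes)[0])
    return np.asarray(out)


def transition_success(pred: Sequence[int], event_index: int,
                       new_label: int, horizon: int = 5) -> bool:
    """True iff the new pattern is produced within the first ``horizon``
    outputs at/after the transition's critical gait event."""
    pred = np.asarray(pred)
    if not (0 <= event_index < pred.size):
        raise ValueError("event index out of range")
    return bool(np.any(pred[event_index: event_index + horizon] == new_label))


def success_rate(results, truth_labels: Sequence[int]) -> float:
    """SR over threshold-selected cycles; NaN when none were selected.

    ``results`` are :class:`~gaitmark.autolabel.AutoLabelResult` in cycle
    order; ``truth_labels`` the matching manual labels.
    """
    results = list(results)
    if len(results) != len(truth_labels):
        raise ValueError("results/truth length mismatch")
    sel = [(r.assigned_pattern == t)
           for r, t in zip(results, truth_labels) if r.selected]
    if not sel:
        return float("nan")
    return sum(sel) / len(sel)


def report(pred: Sequence[int], truth: Sequence[int], n_classes: int,
           vote: Optional[int] = 5, sr: float = float("nan"),
           dr: float = float("nan")) -> EvalReport:
    """Full report for one prediction stream (vote applied first if set)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if vote is not None and vote > 1:
        pred = majority_vote(pred, vote)
    n_mis = int(np.count_nonzero(pred != truth))
    return EvalReport(
        re_percent=100.0 * n_mis / pred.size,
        confusion=confusion_matrix(pred, truth, n_classes),
        n_total=int(pred.size), n_mis=n_mis, sr=sr, dr=dr)
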