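"""Cross-day experiment harness: manual-label baselines, the T-vs-AL
comparison, and template accumulation.

Protocols (one synthetic "day" = one labeled Recording):

* cross-day (D_i) — train on day i with manual labels, test on a held-out
  day; one report per training day.
* T vs AL — T trains on one day and tests on the afternoon half of
  another.  AL additionally builds DTW templates from the training day,
  auto-labels the *morning* half of the test day (threshold selection +
  transition suppression), retrains on the union of manual and selected
  pseudo-labeled windows, and tests on the same afternoon half.  The
  afternoon (test) windows never enter training in either arm.
* template accumulation (AL1..ALm) — level j pools the first j days into
  the template library and the manual training set, then runs the AL
  protocol.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .autolabel import autolabel_cycles, postprocess, select_training_data
from .classifiers import ClassifierSpec, predict, train
from .evaluation import EvalReport, report, success_rate
from .preprocess import LabeledWindow, extract_cycles, sliding_windows
from .signal_model import Recording
from .templates import build_template_library

DEFAULT_VOTE = 5

#: Target data-selection rate used when the threshold k is derived from the
#: observed cost distribution of the day being auto-labeled.
DR_TARGET = 0.9


def quantile_k(best_costs: Sequence[float], dr_target: float = DR_TARGET,
               ) -> float:
    """Threshold k achieving a target selection rate on observed costs.

    Rank-based selection keeps the ``dr_target`` most template-like cycles
    regardless of day-to-day cost-scale drift.
    """
    costs = np.asarray(best_costs, dtype=float)
    if costs.size == 0:
        raise ValueError("no costs supplied")
    return float(np.nextafter(np.quantile(costs, dr_target), np.inf))


def labeled_windows(rec: Recording) -> list[LabeledWindow]:
    """Sliding windows of a recording, restricted to labeled ones."""
    return [w for w in sliding_windows(rec) if w.label is not None]


def split_half(rec: Recording) -> tuple[Recording, Recording]:
    """Split a day into morning/afternoon halves at a cycle boundary.

    The cut falls at the start frame of the middle gait cycle; each half
    keeps the matching per-cycle labels.  A synthetic session has no group
    counter, so "morning" is simply the first half of the day's cycles.
    """
    cycles = extract_cycles(rec)
    if len(cycles) < 2:
        raise ValueError("recording has fewer than 2 cycles; cannot split")
    mid = len(cycles) // 2
    cut = cycles[mid].start_index
    labels = rec.pattern_labels
    # Each half keeps one boundary frame so the cut foot contact stays a
    # detectable rising edge in both halves (cycles still partition 1:1).
    morning = rec.slice(0, cut + 1, session_id=rec.session_id + "/am",
                        pattern_labels=None if labels is None
                        else list(labels[:mid]))
    afternoon = rec.slice(cut - 1, len(rec), session_id=rec.session_id + "/pm",
                          pattern_labels=None if labels is None
                          else list(labels[mid:]))
    return morning, afternoon


def _evaluate(model, rec: Recording, n_classes: int,
              vote: int = DEFAULT_VOTE, sr: float = float("nan"),
              dr: float = float("nan")) -> EvalReport:
    windows = labeled_windows(rec)
    if not windows:
        raise ValueError("test recording has no labeled windows")
    pred = predict(model, windows)
    truth = np.array([w.label for w in windows])
    return report(pred, truth, n_classes, vote=vote, sr=sr, dr=dr)


def _n_classes(recs: Sequence[Recording]) -> int:
    return max(max(r.pattern_labels) for r in recs
               if r.pattern_labels is not None)


def run_cross_day(days: Sequence[Recording], test_day: int,
                  spec: ClassifierSpec, vote: int = DEFAULT_VOTE,
                  ) -> dict[int, EvalReport]:
    """Train on each non-test day (manual labels), test on ``test_day``."""
    if len(days) < 2:
        raise ValueError("need at least 2 days")
    for i, d in enumerate(days):
        if d.pattern_labels is None:
            raise ValueError(f"day {i} lacks manual labels")
    S = _n_classes(days)
    reports = {}
    for i, day in enumerate(days):
        if i == test_day:
            continue
        model = train(spec, labeled_windows(day))
        reports[i] = _evaluate(model, days[test_day], S, vote=vote)
    return reports


def run_T_vs_AL(train_day: Recording, test_day: Recording,
                spec: ClassifierSpec, k: Optional[float] = None,
                vote: int = DEFAULT_VOTE,
                ) -> tuple[EvalReport, EvalReport]:
    """Compare plain cross-day training (T) with auto-label retraining (AL).

    When ``k`` is not given it is set to the cost quantile meeting the
    target selection rate on the morning being labeled (no labels needed);
    the labeled same-day protocol for picking k lives in ``tune_k``.
    """
    if train_day.pattern_labels is None or test_day.pattern_labels is None:
        raise ValueError("both days need manual labels")
    S = _n_classes([train_day, test_day])
    morning, afternoon = split_half(test_day)

    base_windows = labeled_windows(train_day)
    model_t = train(spec, base_windows)
    report_t = _evaluate(model_t, afternoon, S, vote=vote)

    library = build_template_library([train_day])
    cycles_m = extract_cycles(morning)
    results = autolabel_cycles(cycles_m, library, k=float("inf"))
    if k is None:
        # Day-to-day wear inflates all DTW costs roughly alike, so an
        # absolute threshold tuned on another day under-selects; take the
        # cost quantile that meets the target selection rate instead.
        k = quantile_k([r.best_cost for r in results], DR_TARGET)
    for r in results:
        r.selected = r.best_cost < k
    results = postprocess(results, cycles_m)
    windows_m = sliding_windows(morning, cycles=cycles_m)
    pseudo, dr = select_training_data(results, cycles_m, windows_m, k)
    sr = success_rate(results, [c.label for c in cycles_m])
    model_al = train(spec, base_windows + pseudo)
    report_al = _evaluate(model_al, afternoon, S, vote=vote, sr=sr, dr=dr)
    return report_t, report_al


def run_template_accumulation(days: Sequence[Recording],
                              test_day: Recording, spec: ClassifierSpec,
                              k: Optional[float] = None,
                              vote: int = DEFAULT_VOTE,
                              ) -> list[EvalReport]:
    """AL protocol with templates (and manual data) pooled over 1..m days."""
    if len(days) < 2:
        raise ValueError("need at least 2 template days")
    S = _n_classes(list(days) + [test_day])
    morning, afternoon = split_half(test_day)
    cycles_m = extract_cycles(morning)
    windows_m = sliding_windows(morning, cycles=cycles_m)
    truth_m = [c.label for c in cycles_m]
    reports = []
    for j in range(1, len(days) + 1):
        pool = days[:j]
        library = build_template_library(pool)
        results = autolabel_cycles(cycles_m, library, k=float("inf"))
        k_j = quantile_k([r.best_cost for r in results]) if k is None else k
        for r in results:
            r.selected = r.best_cost < k_j
        results = postprocess(results, cycles_m)
        pseudo, dr = select_training_data(results, cycles_m, windows_m, k_j)
        sr = success_rate(results, truth_m)
        base = [w for d in pool for w in labeled_windows(d)]
        model = train(spec, base + pseudo)
        reports.append(_evaluate(model, afternoon, S, vote=vote, sr=sr, dr=dr))
    return reports
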