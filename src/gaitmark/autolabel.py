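"""DTW-based automatic labeling of gait cycles and training-data selection.

Each completed gait cycle is z-scored with the template library's channel
statistics and DTW-aligned to the template of every movement pattern; the
pattern with the smallest normalized cost is assigned automatically.  Two
safeguards filter the pseudo-labels before retraining:

* threshold selection — only cycles whose best normalized cost is below a
  threshold ``k`` contribute training data (trading data quantity, DR,
  against pseudo-label accuracy, SR);
* transition suppression — when two adjacent cycles disagree, a gait
  transition likely occurred; since transitions happen in the swing phase,
  both cycles' swing-phase windows are excluded from retraining.

``tune_k`` mirrors the same-day morning/afternoon cross-test used to pick
``k`` per subject: sweep a grid, compute SR and DR at each value, and take
the smallest k maximizing SR subject to a DR floor.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dtw import dtw_align
from .evaluation import success_rate
from .preprocess import SWING, LabeledWindow, extract_cycles, sliding_windows
from .signal_model import GaitCycle, Recording
from .templates import Template, build_template_library

DEFAULT_DR_MIN = 0.9


@dataclasses.dataclass
class AutoLabelResult:
    """Outcome of matching one cycle against the template library."""

    cycle_ref: int
    assigned_pattern: int
    best_cost: float
    all_costs: np.ndarray      # indexed by pattern_id - 1
    selected: bool
    suppressed: bool = False


def autolabel_cycle(cycle: GaitCycle, library: Sequence[Template],
                    k: float) -> AutoLabelResult:
    """Label one cycle by minimum normalized DTW cost to the templates.

    Ties break toward the lowest pattern id; ``selected`` is true when the
    winning cost is below ``k``.
    """
    if not library:
        raise ValueError("empty template library")
    if k <= 0:
        raise ValueError("k must be positive")
    templates = sorted(library, key=lambda t: t.pattern_id)
    x = templates[0].channel_stats.apply(cycle.imu)
    costs = np.array([dtw_align(x, t.points).normalized_cost
                      for t in templates])
    best = int(np.argmin(costs))
    return AutoLabelResult(
        cycle_ref=cycle.cycle_id,
        assigned_pattern=templates[best].pattern_id,
        best_cost=float(costs[best]),
        all_costs=costs,
        selected=bool(costs[best] < k))


def autolabel_cycles(cycles: Sequence[GaitCycle],
                     library: Sequence[Template],
                     k: float) -> list[AutoLabelResult]:
    return [autolabel_cycle(c, library, k) for c in cycles]


def postprocess(results: Sequence[AutoLabelResult],
                cycles: Sequence[GaitCycle]) -> list[AutoLabelResult]:
    """Flag both members of every disagreeing adjacent pair as suppressed.

    Suppression removes the pair's swing-phase windows from retraining
    (gait transitions occur in the swing phase); stance data is retained.
    """
    if len(results) != len(cycles):
        raise ValueError("results/cycles length mismatch")
    out = [dataclasses.replace(r, suppressed=False) for r in results]
    for a, b in zip(range(len(out) - 1), range(1, len(out))):
        if out[a].assigned_pattern != out[b].assigned_pattern:
            out[a].suppressed = True
            out[b].suppressed = True
    return out


def select_training_data(results: Sequence[AutoLabelResult],
                         cycles: Sequence[GaitCycle],
                         windows: Sequence[LabeledWindow],
                         k: float) -> tuple[list[LabeledWindow], float]:
    """Pseudo-labeled windows passing the threshold, plus DR.

    A window is kept when its cycle's best cost is below ``k`` and it is
    not a swing-phase window of a suppressed cycle; its label becomes the
    cycle's assigned pattern.  ``DR = D_C / D_I`` counts cycles below the
    threshold over all complete cycles.
    """
    if not results:
        raise ValueError("no auto-label results")
    if len(results) != len(cycles):
        raise ValueError("results/cycles length mismatch")
    below = [r.best_cost < k for r in results]
    dr = sum(below) / len(results)
    selected: list[LabeledWindow] = []
    for w in windows:
        ci = w.cycle_index
        if ci is None or not below[ci]:
            continue
        if results[ci].suppressed and w.phase == SWING:
            continue
        selected.append(dataclasses.replace(
            w, label=results[ci].assigned_pattern))
    return selected, dr


def autolabel_recording(rec: Recording, library: Sequence[Template],
                        k: float, with_postprocess: bool = True,
                        ) -> tuple[list[AutoLabelResult], list[GaitCycle]]:
    """Extract cycles from a recording and auto-label them."""
    cycles = extract_cycles(rec)
    results = autolabel_cycles(cycles, library, k)
    if with_postprocess:
        results = postprocess(results, cycles)
    return results, cycles


def tune_k(morning: Recording, afternoon: Recording,
           grid: Optional[Sequence[float]] = None,
           dr_min: float = DEFAULT_DR_MIN,
           ) -> tuple[float, pd.DataFrame]:
    """Pick the operating threshold by a morning/afternoon cross-test.

    Templates are built from the morning recording (manual labels); the
    afternoon cycles are auto-labeled once and SR/DR evaluated at every
    grid value (costs are threshold-independent, so one DTW pass serves
    the whole sweep).  When ``grid`` is omitted, 40 evenly spaced values
    spanning the observed best-cost range are swept — normalized DTW
    costs scale with the sensor noise level, so a self-calibrated grid is
    the robust default.  Returns ``(k_star, table)`` where ``k_star`` is
    the smallest grid value maximizing SR among those with DR >=
    ``dr_min``; if no value reaches the floor, the value with the highest
    DR is used.
    """
    library = build_template_library([morning])
    cycles = extract_cycles(afternoon)
    truth = [c.label for c in cycles]
    if any(t is None for t in truth):
        raise ValueError("afternoon recording must carry manual labels")
    base = autolabel_cycles(cycles, library, k=float("inf"))
    if grid is None:
        top = 1.05 * max(r.best_cost for r in base)
        grid = list(np.linspace(top / 40, top, 40))
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty k grid")
    rows = []
    for k in grid:
        results = [dataclasses.replace(r, selected=r.best_cost < k)
                   for r in base]
        sr = success_rate(results, truth)
        dr = sum(r.best_cost < k for r in base) / len(base)
        rows.append({"k": k, "sr": sr, "dr": dr})
    table = pd.DataFrame(rows)
    feasible = table[table.dr >= dr_min]
    if len(feasible):
        k_star = float(feasible.sort_values(
            ["sr", "k"], ascending=[False, True]).iloc[0].k)
    else:
        k_star = float(table.sort_values(
            ["dr", "sr"], ascending=[False, False]).iloc[0].k)
    return k_star, table
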