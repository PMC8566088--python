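"""Signal conditioning, gait-event detection and window segmentation.

Order of operations in the pipeline: (1) a limiting filter removes random
pulses from the four Euler-angle channels; (2) foot-contact (FC) and
foot-off (FO) events are detected from the footplate pressure with a
hysteresis threshold pair plus a debounce interval; (3) FC-to-FC gait
cycles are extracted, each split into stance and swing at the FO event;
(4) the IMU stream is cut into 300 ms sliding windows with a 10 ms step,
the classifier unit.  A window inherits the label and phase of the gait
cycle containing its *final* frame, mimicking a causal online recognizer
whose decision is made "now".
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .signal_model import (
    EULER_CHANNEL_INDICES,
    DataError,
    GaitCycle,
    Recording,
)

logger = logging.getLogger(__name__)

# Event-detection defaults: hysteresis thresholds as fractions of the
# per-recording maximum pressure, and a debounce interval.
DEFAULT_ON_FRAC = 0.2
DEFAULT_OFF_FRAC = 0.1
DEFAULT_MIN_PHASE_MS = 100.0

DEFAULT_WINDOW_MS = 300.0
DEFAULT_STEP_MS = 10.0

STANCE = "stance"
SWING = "swing"


@dataclasses.dataclass
class LabeledWindow:
    """One sliding-window segment, the unit the classifiers consume.

    ``features`` is a (frames, 10) matrix; QDA/SVM flatten it internally.
    ``label`` is the movement-pattern class of the cycle containing the
    window's final frame (None when that frame lies in no labeled cycle);
    ``phase`` is the gait phase at the final frame.
    """

    features: np.ndarray
    label: Optional[int]
    phase: Optional[str]
    start: int = 0
    cycle_index: Optional[int] = None

    def __len__(self) -> int:
        return len(self.features)


def limiting_filter(series: Sequence[float], threshold: float) -> np.ndarray:
    """Suppress single-sample pulses by hold-last-valid.

    Wherever a sample deviates from the previous *output* by more than
    ``threshold`` it is considered a random pulse and replaced by the
    previous output; otherwise it passes through.  Length-preserving,
    causal, and idempotent.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("limiting_filter: empty input")
    if threshold <= 0:
        raise ValueError("limiting_filter: threshold must be positive")
    out = np.empty_like(s)
    out[0] = s[0]
    prev = s[0]
    for i in range(1, len(s)):
        if abs(s[i] - prev) > threshold:
            out[i] = prev
        else:
            out[i] = s[i]
            prev = s[i]
    return out


def filter_recording(rec: Recording, euler_threshold: float) -> Recording:
    """Apply the limiting filter to the four Euler-angle channels only."""
    imu = rec.imu.copy()
    for c in EULER_CHANNEL_INDICES:
        imu[:, c] = limiting_filter(imu[:, c], euler_threshold)
    return Recording(
        t=rec.t.copy(), imu=imu, pressure=rec.pressure.copy(),
        sample_period_ms=rec.sample_period_ms, subject_id=rec.subject_id,
        session_id=rec.session_id, pattern_labels=rec.pattern_labels,
        frame_labels=None if rec.frame_labels is None else rec.frame_labels.copy(),
    )


FC = "FC"
FO = "FO"


def detect_gait_events(pressure: Sequence[float], on_thresh: float,
                       off_thresh: float, min_phase_ms: float = 0.0,
                       sample_period_ms: float = 10.0) -> list[tuple[str, int]]:
    """Foot-contact / foot-off events from the pressure trace.

    FC is emitted where pressure rises through ``on_thresh``, FO where it
    falls through ``off_thresh`` (``on_thresh >= off_thresh``, hysteresis).
    A crossing closer than ``min_phase_ms`` to the previously accepted
    event is treated as bounce: it is dropped together with the following
    crossing, which preserves FC/FO alternation.
    """
    if on_thresh < off_thresh:
        raise ValueError("detect_gait_events: on_thresh must be >= off_thresh")
    if min_phase_ms < 0:
        raise ValueError("detect_gait_events: min_phase_ms must be >= 0")
    p = np.asarray(pressure, dtype=float)
    raw: list[tuple[str, int]] = []
    high = bool(p[0] > on_thresh) if p.size else False
    for i in range(p.size):
        if not high and p[i] > on_thresh:
            raw.append((FC, i))
            high = True
        elif high and p[i] < off_thresh:
            raw.append((FO, i))
            high = False
    events: list[tuple[str, int]] = []
    min_frames = min_phase_ms / sample_period_ms
    i = 0
    while i < len(raw):
        if events and (raw[i][1] - events[-1][1]) < min_frames:
            i += 2  # drop the bounce pair
        else:
            events.append(raw[i])
            i += 1
    return events


def extract_cycles(rec: Recording, on_frac: float = DEFAULT_ON_FRAC,
                   off_frac: float = DEFAULT_OFF_FRAC,
                   min_phase_ms: float = DEFAULT_MIN_PHASE_MS) -> list[GaitCycle]:
    """FC-to-FC gait cycles with their interior FO event.

    Hysteresis thresholds are fractions of the recording's maximum
    pressure.  A consecutive FC pair lacking exactly one interior FO is
    dropped (and logged).  When ``rec.pattern_labels`` has one label per
    extracted cycle the labels are attached in order.
    """
    if len(rec) == 0:
        return []
    pmax = float(np.max(rec.pressure))
    if pmax <= 0:
        return []
    events = detect_gait_events(
        rec.pressure, on_thresh=on_frac * pmax, off_thresh=off_frac * pmax,
        min_phase_ms=min_phase_ms, sample_period_ms=rec.sample_period_ms)
    fc = [i for kind, i in events if kind == FC]
    fo = np.array([i for kind, i in events if kind == FO], dtype=int)
    cycles: list[GaitCycle] = []
    for a, b in zip(fc[:-1], fc[1:]):
        interior = fo[(fo > a) & (fo < b)]
        if len(interior) != 1:
            logger.warning("dropping cycle [%d, %d): %d interior FO events",
                           a, b, len(interior))
            continue
        cycles.append(GaitCycle(
            imu=rec.imu[a:b], pressure=rec.pressure[a:b],
            fo_index=int(interior[0]) - a, start_index=a,
            cycle_id=len(cycles)))
    labels = rec.pattern_labels
    if labels is not None:
        if len(labels) == len(cycles):
            for c, l in zip(cycles, labels):
                c.label = int(l)
        else:
            logger.warning(
                "pattern_labels count (%d) does not match extracted cycles "
                "(%d); cycles left unlabeled", len(labels), len(cycles))
    return cycles


def sliding_windows(rec: Recording, window_ms: float = DEFAULT_WINDOW_MS,
                    step_ms: float = DEFAULT_STEP_MS,
                    cycles: Optional[list[GaitCycle]] = None,
                    ) -> list[LabeledWindow]:
    """Cut the recording into fixed-length sliding windows.

    Windows are half-open frame ranges ``[start, start + W)`` with W =
    round(window_ms / sample_period_ms), starts one step apart.  When
    ``cycles`` is omitted they are extracted from the pressure trace.
    """
    if not (window_ms >= step_ms > 0):
        raise ValueError("require window_ms >= step_ms > 0")
    period = rec.sample_period_ms
    W = int(round(window_ms / period))
    step = max(1, int(round(step_ms / period)))
    n = len(rec)
    if n < W:
        return []
    if cycles is None:
        cycles = extract_cycles(rec)
    # frame -> (cycle index, phase) lookup
    cyc_of = np.full(n, -1, dtype=int)
    phase_of = np.zeros(n, dtype=np.uint8)  # 1 stance, 2 swing
    for ci, c in enumerate(cycles):
        cyc_of[c.start_index:c.end_index] = ci
        phase_of[c.start_index:c.start_index + c.fo_index] = 1
        phase_of[c.start_index + c.fo_index:c.end_index] = 2
    windows = []
    for start in range(0, n - W + 1, step):
        last = start + W - 1
        ci = int(cyc_of[last])
        if ci >= 0:
            label = cycles[ci].label
            phase = STANCE if phase_of[last] == 1 else SWING
        else:
            label, phase, ci = None, None, None
        windows.append(LabeledWindow(
            features=rec.imu[start:start + W], label=label, phase=phase,
            start=start, cycle_index=ci))
    return windows
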