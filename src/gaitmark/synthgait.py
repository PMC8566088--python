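"""Synthetic multi-day IMU + footplate gait generator with ground truth.

Real recordings for this task are quasi-periodic: each movement pattern has
a characteristic smooth multichannel waveform per gait cycle, cycle
durations vary stride to stride, the footplate is loaded during stance and
unloaded during swing, Euler-angle channels occasionally carry single-sample
pulses, and day-to-day wear introduces small per-channel offset/gain
changes.  The generator emulates exactly these features — and nothing more
biomechanical — so that every downstream module can be tested against exact
ground truth (cycle boundaries, foot-off indices, per-cycle labels).

Waveforms are sums of 2-4 harmonics over cycle phase.  Each pattern's
waveform is a mixture ``(1-s) * common + s * specific`` of a shared
component and a pattern-specific component, both unit-variance over phase;
``s`` (``pattern_separation``) dials how distinguishable the patterns are.
Acceleration channels have unit scale, Euler-angle channels scale 20
(degree-like units); ``noise_sd`` is relative to each channel's scale.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .signal_model import N_CHANNELS, GaitCycle, Recording

#: Per-channel amplitude scale (accelerations ~1, Euler angles ~20).
CHANNEL_SCALE = np.array([1.0, 1.0, 1.0, 20.0, 20.0,
                          1.0, 1.0, 1.0, 20.0, 20.0])

#: Limiting-filter threshold matched to these scales: well above the
#: largest smooth sample-to-sample change, well below a pulse.
DEFAULT_EULER_THRESHOLD = 40.0


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions for one synthetic subject.

    ``seed`` fixes the subject's waveforms; day-level randomness (cycle
    durations, noise, pulses, day shift) derives from ``seed`` and the day
    index, so the same (config, day) pair always regenerates identically.
    """

    n_patterns: int = 5
    n_harmonics: int = 3
    group_size: int = 4               # cycles per group in "grouped" schedule
    pattern_separation: float = 0.6
    cycle_ms_mean: float = 1000.0
    cycle_ms_sd: float = 100.0
    stance_fraction: float = 0.6
    noise_sd: float = 0.1
    pulse_rate: float = 0.002
    pulse_magnitude: float = 5.0      # in channel-scale units
    day_shift_offset: float = 0.0     # sd of per-channel offset, scale units
    day_shift_gain: float = 0.0       # sd of per-channel gain perturbation
    sample_period_ms: float = 10.0
    pressure_max: float = 100.0
    pressure_noise_sd: float = 0.0    # relative to pressure_max
    subject_id: str = "synth"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patterns < 2:
            raise ValueError("n_patterns must be >= 2")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must be in (0, 1)")
        if min(self.noise_sd, self.cycle_ms_sd, self.pulse_rate,
               self.pressure_noise_sd) < 0:
            raise ValueError("rates and standard deviations must be >= 0")
        if not (2 <= self.n_harmonics <= 4):
            raise ValueError("n_harmonics must be in 2..4")


def _harmonic_coeffs(rng: np.random.Generator, shape: tuple[int, ...],
                     n_harmonics: int) -> tuple[np.ndarray, np.ndarray]:
    """Random amplitudes/phases normalized to unit waveform variance."""
    amp = rng.normal(size=shape + (n_harmonics,)) / np.sqrt(
        np.arange(1, n_harmonics + 1))
    # var of sum_h A_h cos(2 pi h phi + theta_h) over phi is sum A_h^2 / 2
    norm = np.sqrt((amp ** 2).sum(axis=-1, keepdims=True) / 2.0)
    amp = amp / np.where(norm > 0, norm, 1.0)
    phase = rng.uniform(0, 2 * np.pi, size=shape + (n_harmonics,))
    return amp, phase


class _WaveBank:
    """Per-pattern, per-channel waveforms for one subject (one config)."""

    def __init__(self, cfg: GeneratorConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        H = cfg.n_harmonics
        self.h = np.arange(1, H + 1)
        self.common_amp, self.common_phase = _harmonic_coeffs(
            rng, (N_CHANNELS,), H)
        self.spec_amp, self.spec_phase = _harmonic_coeffs(
            rng, (cfg.n_patterns, N_CHANNELS), H)
        self.s = cfg.pattern_separation

    def eval(self, pattern: int, phi: np.ndarray) -> np.ndarray:
        """Waveform values at cycle phases ``phi`` -> (len(phi), 10)."""
        ang = 2 * np.pi * phi[:, None, None] * self.h  # (T, 1, H)
        common = (self.common_amp * np.cos(ang + self.common_phase)).sum(-1)
        spec = (self.spec_amp[pattern - 1]
                * np.cos(ang + self.spec_phase[pattern - 1])).sum(-1)
        return (1 - self.s) * common + self.s * spec


def _day_rng(cfg: GeneratorConfig, day: int, salt: int,
             seed: Optional[int]) -> np.random.Generator:
    if seed is not None:
        return np.random.default_rng(np.random.SeedSequence([seed, salt]))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, day, salt]))


def _schedule_labels(cfg: GeneratorConfig, n_cycles_per_pattern: int,
                     schedule: Union[str, Sequence[int]]) -> list[int]:
    if isinstance(schedule, str):
        if schedule == "blocked":
            return [p for p in range(1, cfg.n_patterns + 1)
                    for _ in range(n_cycles_per_pattern)]
        if schedule == "grouped":
            # Short per-pattern groups cycling through all patterns, the
            # way experiment sessions repeat groups through a day; every
            # session half then contains every pattern.
            g = cfg.group_size
            labels: list[int] = []
            remaining = {p: n_cycles_per_pattern
                         for p in range(1, cfg.n_patterns + 1)}
            while any(remaining.values()):
                for p in range(1, cfg.n_patterns + 1):
                    take = min(g, remaining[p])
                    labels.extend([p] * take)
                    remaining[p] -= take
            return labels
        raise ValueError(f"unknown schedule {schedule!r}")
    labels = [int(p) for p in schedule]
    if not labels:
        raise ValueError("empty schedule")
    if any(not (1 <= p <= cfg.n_patterns) for p in labels):
        raise ValueError("schedule labels must be in 1..n_patterns")
    return labels


def generate_day(cfg: GeneratorConfig, n_cycles_per_pattern: int = 10,
                 schedule: Union[str, Sequence[int]] = "blocked",
                 day: int = 0, seed: Optional[int] = None,
                 session_id: str = "",
                 ) -> tuple[Recording, pd.DataFrame]:
    """One session of labeled gait plus exact ground truth.

    Returns ``(recording, truth)`` where ``truth`` has columns
    ``cycle_id, start_idx, fo_idx, end_idx, label``.  The recording carries
    per-cycle ``pattern_labels`` and the per-frame label expansion.
    The pressure trace is >= 0.4 * max inside stance and 0 in swing, so the
    default hysteresis event detector recovers FC/FO exactly in the
    noise-free case.
    """
    labels = _schedule_labels(cfg, n_cycles_per_pattern, schedule)
    bank = _WaveBank(cfg)
    rng = _day_rng(cfg, day, 23, seed)
    shift_rng = _day_rng(cfg, day, 29, None if seed is None else seed)
    offset = shift_rng.normal(0, cfg.day_shift_offset, N_CHANNELS) * CHANNEL_SCALE
    gain = 1.0 + shift_rng.normal(0, cfg.day_shift_gain, N_CHANNELS)

    period = cfg.sample_period_ms
    imu_parts, press_parts, rows = [], [], []
    frame_labels_parts = []
    # Lead-in (unloaded footplate) so the first foot contact is a rising
    # edge, and a short loaded tail so the last cycle is closed by a final
    # foot contact; both lie outside every labeled cycle.
    lead_in, tail = 30, 10
    phi_lead = (cfg.stance_fraction
                + (1 - cfg.stance_fraction) * np.linspace(0.25, 1.0, lead_in,
                                                          endpoint=False))
    imu_lead = bank.eval(labels[0], phi_lead) * CHANNEL_SCALE
    imu_lead = imu_lead * gain + offset
    imu_lead += rng.normal(0, cfg.noise_sd, imu_lead.shape) * CHANNEL_SCALE
    imu_parts.append(imu_lead)
    press_parts.append(np.zeros(lead_in))
    frame_labels_parts.append(np.zeros(lead_in, dtype=int))
    start = lead_in
    for cid, label in enumerate(labels):
        dur = rng.normal(cfg.cycle_ms_mean, cfg.cycle_ms_sd)
        frames = max(int(round(dur / period)), 20)
        n_stance = int(round(cfg.stance_fraction * frames))
        n_stance = min(max(n_stance, 5), frames - 5)
        n_swing = frames - n_stance
        # phase grid: stance covers [0, sf), swing [sf, 1); FO at phase sf
        phi = np.concatenate([
            cfg.stance_fraction * np.arange(n_stance) / n_stance,
            cfg.stance_fraction
            + (1 - cfg.stance_fraction) * np.arange(n_swing) / n_swing,
        ])
        imu = bank.eval(label, phi) * CHANNEL_SCALE
        imu = imu * gain + offset
        imu += rng.normal(0, cfg.noise_sd, imu.shape) * CHANNEL_SCALE
        if cfg.pulse_rate > 0:
            for c in (3, 4, 8, 9):
                mask = rng.random(frames) < cfg.pulse_rate
                signs = rng.choice([-1.0, 1.0], size=int(mask.sum()))
                imu[mask, c] += signs * cfg.pulse_magnitude * CHANNEL_SCALE[c]
        progress = np.arange(n_stance) / n_stance
        press = np.zeros(frames)
        press[:n_stance] = cfg.pressure_max * (0.4 + 0.6 * np.sin(np.pi * progress))
        if cfg.pressure_noise_sd > 0:
            press = press + rng.normal(
                0, cfg.pressure_noise_sd * cfg.pressure_max, frames)
        press = np.clip(press, 0.0, None)
        imu_parts.append(imu)
        press_parts.append(press)
        frame_labels_parts.append(np.full(frames, label, dtype=int))
        rows.append((cid, start, start + n_stance, start + frames, label))
        start += frames

    phi_tail = cfg.stance_fraction * np.linspace(0.0, 0.1, tail, endpoint=False)
    imu_tail = bank.eval(labels[-1], phi_tail) * CHANNEL_SCALE
    imu_tail = imu_tail * gain + offset
    imu_tail += rng.normal(0, cfg.noise_sd, imu_tail.shape) * CHANNEL_SCALE
    imu_parts.append(imu_tail)
    press_parts.append(np.full(tail, 0.5 * cfg.pressure_max))
    frame_labels_parts.append(np.zeros(tail, dtype=int))
    start += tail

    n = start
    rec = Recording(
        t=np.arange(n) * period,
        imu=np.concatenate(imu_parts, axis=0),
        pressure=np.concatenate(press_parts),
        sample_period_ms=period,
        subject_id=cfg.subject_id,
        session_id=session_id or f"day{day}",
        pattern_labels=labels,
        frame_labels=np.concatenate(frame_labels_parts),
    )
    truth = pd.DataFrame(
        rows, columns=["cycle_id", "start_idx", "fo_idx", "end_idx", "label"])
    return rec, truth


def generate_transition_day(cfg: GeneratorConfig,
                            segments: Sequence[tuple[int, int]],
                            day: int = 0, seed: Optional[int] = None,
                            ) -> tuple[Recording, pd.DataFrame, list[int]]:
    """Concatenated pattern blocks with labeled transition boundaries.

    ``segments`` is a list of ``(pattern, n_cycles)``.  Returns
    ``(recording, truth, transitions)`` where ``transitions`` lists the
    cycle indices at which a new pattern starts (one per boundary,
    ``len(segments) - 1`` of them).
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    if any(n < 1 for _, n in segments):
        raise ValueError("empty segment")
    schedule: list[int] = []
    transitions: list[int] = []
    for pattern, n_cycles in segments:
        if schedule:
            transitions.append(len(schedule))
        schedule.extend([pattern] * n_cycles)
    rec, truth = generate_day(cfg, schedule=schedule, day=day, seed=seed)
    return rec, truth, transitions


def truth_cycles(rec: Recording, truth: pd.DataFrame) -> list[GaitCycle]:
    """Materialize ground-truth GaitCycles from a generated day."""
    from .signal_model import cycles_from_table

    return cycles_from_table(rec, truth)
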