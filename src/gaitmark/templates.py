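"""Phase normalization of gait cycles and per-pattern template averaging.

Gait cycles differ in length, so before averaging each cycle is resampled
onto a fixed phase grid: the stance frames onto ``n_stance`` points and the
swing frames onto ``n_swing`` points, each by per-channel cubic-spline
interpolation over normalized sub-phase time in [0, 1].  This aligns the
foot-off event at the same row in every normalized cycle.  Channels are
z-scored with statistics computed over the template-building set (test
data later reuses these statistics, so there is no leakage).  The template
of a movement pattern is the pointwise mean of its K normalized cycles,

    t_m = (1/K) * sum_n a_n ,

one template per pattern per subject.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import extract_cycles
from .signal_model import N_CHANNELS, GaitCycle, Recording

DEFAULT_N_STANCE = 60
DEFAULT_N_SWING = 40


class InterpolationError(ValueError):
    """A gait-cycle phase is too short for cubic-spline resampling."""


class MissingPatternError(ValueError):
    """A subject lacks labeled cycles for one or more patterns."""

    def __init__(self, missing: list[tuple[str, int]]):
        self.missing = missing
        super().__init__(
            "missing (subject, pattern) pairs: "
            + ", ".join(f"({s!r}, {p})" for s, p in missing))


@dataclasses.dataclass
class ChannelStats:
    """Per-channel mean and standard deviation used for z-scoring."""

    mean: np.ndarray  # (10,)
    sd: np.ndarray    # (10,)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (N_CHANNELS,) or self.sd.shape != (N_CHANNELS,):
            raise ValueError("channel stats must have one entry per channel")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.sd))
                and np.all(self.sd > 0)):
            raise ValueError("channel stats must be finite with sd > 0")

    def apply(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.mean) / self.sd

    @staticmethod
    def from_frames(frames: np.ndarray) -> "ChannelStats":
        """Stats over raw frames; zero-variance channels get sd = 1."""
        sd = frames.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return ChannelStats(mean=frames.mean(axis=0), sd=sd)


@dataclasses.dataclass
class Template:
    """Fixed-length normalized multichannel curve for one movement pattern."""

    pattern_id: int
    subject_id: str
    points: np.ndarray      # (n_stance + n_swing, 10), z-scored
    n_swing: int
    n_stance: int
    k_cycles: int
    channel_stats: ChannelStats

    def __post_init__(self) -> None:
        n = self.n_stance + self.n_swing
        if self.points.shape != (n, N_CHANNELS):
            raise ValueError(
                f"template must have {n} rows x {N_CHANNELS} channels")
        if self.k_cycles < 1:
            raise ValueError("k_cycles must be >= 1")


def _resample_phase(frames: np.ndarray, n_out: int) -> np.ndarray:
    m = len(frames)
    if m < 4:
        raise InterpolationError(
            f"phase has {m} samples; cubic spline needs at least 4")
    x_old = np.linspace(0.0, 1.0, m)
    x_new = np.linspace(0.0, 1.0, n_out)
    return CubicSpline(x_old, frames, axis=0)(x_new)


def normalize_cycle(cycle: GaitCycle, n_swing: int, n_stance: int,
                    stats: ChannelStats) -> np.ndarray:
    """Resample one cycle onto the fixed phase grid and z-score it.

    Stance and swing are interpolated separately so the foot-off event
    falls at row ``n_stance`` in every normalized cycle.  Output rows are
    ordered stance-then-swing.
    """
    if n_swing < 4 or n_stance < 4:
        raise ValueError("n_swing and n_stance must each be >= 4")
    try:
        stance = _resample_phase(cycle.stance, n_stance)
        swing = _resample_phase(cycle.swing, n_swing)
    except InterpolationError as e:
        raise InterpolationError(f"cycle {cycle.cycle_id}: {e}") from None
    return stats.apply(np.vstack([stance, swing]))


def build_template(cycles: list[GaitCycle], n_swing: int = DEFAULT_N_SWING,
                   n_stance: int = DEFAULT_N_STANCE,
                   stats: Optional[ChannelStats] = None,
                   subject_id: str = "") -> Template:
    """Average K phase-normalized cycles of one pattern into a template.

    When ``stats`` is omitted the z-scoring statistics are computed over
    all supplied cycles' raw frames.
    """
    if not cycles:
        raise ValueError("build_template: no cycles supplied")
    patterns = {c.label for c in cycles}
    if len(patterns) != 1:
        raise ValueError(f"build_template: mixed patterns {sorted(patterns)}")
    if stats is None:
        stats = ChannelStats.from_frames(
            np.concatenate([c.imu for c in cycles], axis=0))
    normalized = np.stack(
        [normalize_cycle(c, n_swing, n_stance, stats) for c in cycles])
    (pattern,) = patterns
    return Template(
        pattern_id=0 if pattern is None else int(pattern),
        subject_id=subject_id,
        points=normalized.mean(axis=0),
        n_swing=n_swing, n_stance=n_stance,
        k_cycles=len(cycles), channel_stats=stats)


def build_template_library(recordings: Iterable[Recording],
                           n_swing: int = DEFAULT_N_SWING,
                           n_stance: int = DEFAULT_N_STANCE,
                           n_patterns: Optional[int] = None,
                           ) -> list[Template]:
    """One template per pattern per subject, with shared per-subject stats.

    Every subject must supply at least one labeled cycle for every pattern
    in ``{1..S}`` (S = ``n_patterns``, or the maximum label seen);
    otherwise :class:`MissingPatternError` lists the absent pairs.
    """
    by_subject: dict[str, list[GaitCycle]] = defaultdict(list)
    for rec in recordings:
        cycles = [c for c in extract_cycles(rec) if c.label is not None]
        by_subject[rec.subject_id].extend(cycles)
    if not any(by_subject.values()):
        raise ValueError("no labeled cycles in the supplied recordings")
    if n_patterns is None:
        n_patterns = max(c.label for cs in by_subject.values() for c in cs)
    missing = []
    for subject, cycles in by_subject.items():
        present = {c.label for c in cycles}
        missing.extend((subject, p) for p in range(1, n_patterns + 1)
                       if p not in present)
    if missing:
        raise MissingPatternError(sorted(missing))
    library: list[Template] = []
    for subject, cycles in by_subject.items():
        stats = ChannelStats.from_frames(
            np.concatenate([c.imu for c in cycles], axis=0))
        for p in range(1, n_patterns + 1):
            library.append(build_template(
                [c for c in cycles if c.label == p],
                n_swing=n_swing, n_stance=n_stance,
                stats=stats, subject_id=subject))
    return library


# ---------------------------------------------------------------------------
# Serialization: one CSV per template plus a JSON manifest.

def save_library(library: list[Template], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for tpl in library:
        fname = f"template_{tpl.subject_id or 'default'}_p{tpl.pattern_id}.csv"
        np.savetxt(directory / fname, tpl.points, delimiter=",", fmt="%.12g")
        manifest.append({
            "file": fname,
            "pattern_id": tpl.pattern_id,
            "subject_id": tpl.subject_id,
            "n_swing": tpl.n_swing,
            "n_stance": tpl.n_stance,
            "k_cycles": tpl.k_cycles,
            "channel_mean": tpl.channel_stats.mean.tolist(),
            "channel_sd": tpl.channel_stats.sd.tolist(),
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_library(directory) -> list[Template]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    library = []
    for entry in manifest:
        points = np.loadtxt(directory / entry["file"], delimiter=",")
        library.append(Template(
            pattern_id=entry["pattern_id"], subject_id=entry["subject_id"],
            points=np.atleast_2d(points),
            n_swing=entry["n_swing"], n_stance=entry["n_stance"],
            k_cycles=entry["k_cycles"],
            channel_stats=ChannelStats(mean=np.array(entry["channel_mean"]),
                                       sd=np.array(entry["channel_sd"]))))
    return library
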