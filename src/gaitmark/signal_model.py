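"""Core domain types and CSV I/O for IMU + footplate gait recordings.

A recording is a uniformly sampled multichannel time series: ten IMU
channels (triaxial acceleration, pitch and roll for each of two units
worn on the leg) plus one footplate pressure channel used to segment
gait cycles.  Every other module consumes these types; the channel
order is fixed here and nowhere else.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Fixed IMU channel order used by every module.
CHANNELS: tuple[str, ...] = (
    "imu1_ax", "imu1_ay", "imu1_az", "imu1_pitch", "imu1_roll",
    "imu2_ax", "imu2_ay", "imu2_az", "imu2_pitch", "imu2_roll",
)
N_CHANNELS = len(CHANNELS)

#: Column indices of the four Euler-angle channels (pitch/roll of both IMUs);
#: the limiting filter is applied to these only.
EULER_CHANNEL_INDICES: tuple[int, ...] = (3, 4, 8, 9)

#: Canonical CSV column order (an optional trailing ``label`` column holds
#: per-frame pattern labels, 0 meaning unlabeled).
CSV_COLUMNS: tuple[str, ...] = ("t_ms",) + CHANNELS + ("pressure",)

#: Default number of movement-pattern classes.
DEFAULT_N_PATTERNS = 5


class FormatError(ValueError):
    """A file does not follow the expected CSV schema."""


class DataError(ValueError):
    """A recording violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class SignalRecord:
    """One timestamped sample: time in ms, 10 IMU channels, pressure."""

    t: float
    imu: np.ndarray  # shape (10,)
    pressure: float

    def __post_init__(self) -> None:
        imu = np.asarray(self.imu, dtype=float)
        if imu.shape != (N_CHANNELS,):
            raise DataError(f"imu must have {N_CHANNELS} entries, got {imu.shape}")
        if not np.all(np.isfinite(imu)):
            raise DataError("imu channels must be finite")
        if self.pressure < 0:
            raise DataError("pressure must be >= 0")
        object.__setattr__(self, "imu", imu)


@dataclasses.dataclass
class Recording:
    """An ordered, uniformly sampled gait recording.

    Stored array-backed for efficiency: ``t`` (n,), ``imu`` (n, 10) and
    ``pressure`` (n,).  ``pattern_labels`` are optional *per-cycle* labels in
    ``{1..S}`` (one per gait cycle, in temporal order); ``frame_labels`` is
    the optional per-frame expansion (0 = unlabeled frame) that round-trips
    through the CSV ``label`` column.
    """

    t: np.ndarray
    imu: np.ndarray
    pressure: np.ndarray
    sample_period_ms: float = 10.0
    subject_id: str = ""
    session_id: str = ""
    pattern_labels: Optional[list[int]] = None
    frame_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.imu = np.asarray(self.imu, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if self.imu.shape != (n, N_CHANNELS):
            raise DataError(
                f"imu must be (n, {N_CHANNELS}); got {self.imu.shape} for n={n}"
            )
        if self.pressure.shape != (n,):
            raise DataError("pressure length mismatch")
        if self.sample_period_ms <= 0:
            raise DataError("sample_period_ms must be positive")
        if n:
            if self.t[0] < 0:
                raise DataError("timestamps must be non-negative")
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("timestamps must be strictly increasing")
            # uniformity to within 1% of the nominal period
            if dt.size and np.any(np.abs(dt - self.sample_period_ms)
                                  > 0.01 * self.sample_period_ms):
                raise DataError("timestamps not uniform to 1% of sample period")
        if not np.all(np.isfinite(self.imu)):
            raise DataError("imu channels must be finite")
        if np.any(self.pressure < 0):
            raise DataError("pressure must be >= 0")
        if self.pattern_labels is not None:
            if any((not isinstance(l, (int, np.integer))) or l < 1
                   for l in self.pattern_labels):
                raise DataError("pattern labels must be integers >= 1")
        if self.frame_labels is not None and self.frame_labels.shape != (n,):
            raise DataError("frame_labels length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> float:
        return len(self) * self.sample_period_ms

    @property
    def records(self) -> list[SignalRecord]:
        return [SignalRecord(t=float(self.t[i]), imu=self.imu[i],
                             pressure=float(self.pressure[i]))
                for i in range(len(self))]

    def slice(self, start: int, stop: int, session_id: Optional[str] = None,
              pattern_labels: Optional[list[int]] = None) -> "Recording":
        """Frame-range sub-recording; per-cycle labels must be supplied anew."""
        return Recording(
            t=self.t[start:stop].copy(),
            imu=self.imu[start:stop].copy(),
            pressure=self.pressure[start:stop].copy(),
            sample_period_ms=self.sample_period_ms,
            subject_id=self.subject_id,
            session_id=self.session_id if session_id is None else session_id,
            pattern_labels=pattern_labels,
            frame_labels=None if self.frame_labels is None
            else self.frame_labels[start:stop].copy(),
        )

    def equals(self, other: "Recording", rtol: float = 1e-9) -> bool:
        if len(self) != len(other):
            return False
        same = (np.allclose(self.t, other.t, rtol=rtol)
                and np.allclose(self.imu, other.imu, rtol=rtol)
                and np.allclose(self.pressure, other.pressure, rtol=rtol))
        if self.frame_labels is None or other.frame_labels is None:
            same = same and (self.frame_labels is None) == (other.frame_labels is None)
        else:
            same = same and np.array_equal(self.frame_labels, other.frame_labels)
        return bool(same)


@dataclasses.dataclass
class GaitCycle:
    """One foot-contact-to-foot-contact stride.

    ``fo_index`` marks the foot-off event inside the slice: frames
    ``[0:fo_index]`` are stance (foot loaded), ``[fo_index:]`` are swing.
    """

    imu: np.ndarray        # (m, 10) raw channel values
    pressure: np.ndarray   # (m,)
    fo_index: int
    start_index: int = 0   # frame offset within the parent recording
    cycle_id: int = 0
    label: Optional[int] = None

    def __post_init__(self) -> None:
        m = len(self.imu)
        if not (0 < self.fo_index < m):
            raise DataError(
                f"fo_index must split the cycle into non-empty stance and "
                f"swing; got fo_index={self.fo_index} for {m} frames"
            )

    def __len__(self) -> int:
        return len(self.imu)

    @property
    def stance(self) -> np.ndarray:
        return self.imu[: self.fo_index]

    @property
    def swing(self) -> np.ndarray:
        return self.imu[self.fo_index:]

    @property
    def end_index(self) -> int:
        return self.start_index + len(self)


# ---------------------------------------------------------------------------
# CSV I/O

def read_recording(path, schema: Sequence[str] = CSV_COLUMNS,
                   sample_period_ms: Optional[float] = None,
                   subject_id: str = "", session_id: str = "") -> Recording:
    """Read a recording from CSV (one row per sample, header required).

    The expected columns are ``t_ms``, the ten IMU channels in canonical
    order, ``pressure``, and optionally ``label`` (per-frame labels).
    When ``sample_period_ms`` is omitted it is taken from the median time
    step.  Raises :class:`FormatError` on missing columns and
    :class:`DataError` on non-monotone time or invariant violations.
    """
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["t_ms"].to_numpy(dtype=float)
    if sample_period_ms is None:
        sample_period_ms = float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    frame_labels = (df["label"].to_numpy(dtype=int)
                    if "label" in df.columns else None)
    return Recording(
        t=t,
        imu=df[list(CHANNELS)].to_numpy(dtype=float),
        pressure=df["pressure"].to_numpy(dtype=float),
        sample_period_ms=sample_period_ms,
        subject_id=subject_id,
        session_id=session_id,
        frame_labels=frame_labels,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV readable by :func:`read_recording`.

    Values are preserved to at least 9 significant digits (``%.12g``).
    """
    data = {"t_ms": rec.t}
    for j, name in enumerate(CHANNELS):
        data[name] = rec.imu[:, j] if len(rec) else np.empty(0)
    data["pressure"] = rec.pressure
    df = pd.DataFrame(data, columns=list(CSV_COLUMNS))
    if rec.frame_labels is not None:
        df["label"] = rec.frame_labels
    df.to_csv(path, index=False, float_format="%.12g")


def write_cycle_table(cycles_or_truth, path) -> None:
    """Serialize per-cycle ground truth / labels.

    Accepts either a list of :class:`GaitCycle` or a DataFrame with columns
    ``cycle_id,start_idx,fo_idx,end_idx,label``.
    """
    if isinstance(cycles_or_truth, pd.DataFrame):
        df = cycles_or_truth[["cycle_id", "start_idx", "fo_idx", "end_idx", "label"]]
    else:
        df = pd.DataFrame(
            {
                "cycle_id": [c.cycle_id for c in cycles_or_truth],
                "start_idx": [c.start_index for c in cycles_or_truth],
                "fo_idx": [c.start_index + c.fo_index for c in cycles_or_truth],
                "end_idx": [c.end_index for c in cycles_or_truth],
                "label": [0 if c.label is None else c.label for c in cycles_or_truth],
            }
        )
    df.to_csv(path, index=False)


def read_cycle_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cycle_id", "start_idx", "fo_idx", "end_idx", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def cycles_from_table(rec: Recording, table: pd.DataFrame) -> list[GaitCycle]:
    """Materialize GaitCycles from a recording plus a cycle table."""
    out = []
    for row in table.itertuples(index=False):
        start, fo, end = int(row.start_idx), int(row.fo_idx), int(row.end_idx)
        out.append(GaitCycle(
            imu=rec.imu[start:end],
            pressure=rec.pressure[start:end],
            fo_index=fo - start,
            start_index=start,
            cycle_id=int(row.cycle_id),
            label=None if int(row.label) == 0 else int(row.label),
        ))
    return out
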