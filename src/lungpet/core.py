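"""Core domain types for dynamic PET kinetic analysis.

Times are stored in seconds internally; kinetic rate constants elsewhere in
the package are per minute, and the seconds->minutes conversion happens at a
single boundary (the kinetics grid builder).  Activity concentrations are
kBq/mL and are assumed decay-corrected to injection time — that is an input
contract, not something this module can verify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FrameSchedule",
    "TimeActivityCurve",
    "BloodSeries",
    "make_frame_schedule",
    "truncate_schedule",
    "truncate_tac",
    "frame_midpoints",
    "read_tac",
    "write_tac",
    "read_blood",
    "write_blood",
    "PAPER_FRAMING",
]

#: 50-frame / 60-min dynamic thoracic acquisition: 24 x 5 s, 6 x 10 s,
#: 3 x 20 s, 2 x 30 s, 5 x 60 s, 10 x 5 min.
PAPER_FRAMING = [(24, 5.0), (6, 10.0), (3, 20.0), (2, 30.0), (5, 60.0), (10, 300.0)]

TAC_COLUMNS = ["frame_start_s", "frame_end_s", "activity_kBq_per_mL"]
BLOOD_COLUMNS = ["time_s", "wholeblood_kBq_per_mL", "plasma_kBq_per_mL", "parent_fraction"]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frames (start_s, end_s)."""

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValidationError("schedule must hold at least one (start, end) frame")
        if start[0] != 0.0:
            raise ValidationError("first frame must start at t=0")
        if np.any(end <= start):
            raise ValidationError("every frame duration must be positive")
        if start.size > 1 and not np.allclose(end[:-1], start[1:], rtol=0, atol=1e-9):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1])

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start_s, other.start_s) and np.array_equal(
            self.end_s, other.end_s
        )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/mL) on a FrameSchedule.

    ``noisy`` flags curves carrying a measurement-noise realisation, in which
    case negative frame values are permitted.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""
    noisy: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValidationError(
                f"TAC has {values.size} values for {self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("TAC values must be finite")
        if not self.noisy and np.any(values < 0):
            raise ValidationError("negative TAC values only permitted on noisy curves")

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.schedule.midpoints_s


@dataclass(frozen=True)
class BloodSeries:
    """Venous blood samples: whole-blood/plasma activity and parent fraction."""

    sample_times_s: np.ndarray
    wholeblood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_times_s, dtype=float)
        wb = np.asarray(self.wholeblood, dtype=float)
        pl = np.asarray(self.plasma, dtype=float)
        pf = np.asarray(self.parent_fraction, dtype=float)
        for name, arr in (("sample_times_s", t), ("wholeblood", wb),
                          ("plasma", pl), ("parent_fraction", pf)):
            object.__setattr__(self, name, arr)
            if arr.shape != t.shape or arr.ndim != 1 or arr.size == 0:
                raise ValidationError("blood series columns must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("blood sample times must be strictly increasing")
        if np.any((pf < 0) | (pf > 1)):
            raise ValidationError("parent_fraction must lie in [0, 1]")
        # Small inversions happen in measured parent-fraction series; warn only.
        if pf.size > 1 and np.any(np.diff(pf) > 1e-6):
            warnings.warn(
                "parent_fraction is not non-increasing; check metabolite data",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return int(self.sample_times_s.size)


def make_frame_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from (count, duration_s) blocks.

    ``[(24, 5), (6, 10), ...]`` reads as 24 frames of 5 s, then 6 of 10 s, ...
    """
    if not spec:
        raise ValidationError("frame-schedule spec is empty")
    durations = []
    for count, dur in spec:
        if int(count) != count or count < 1:
            raise ValidationError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ValidationError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    end = np.cumsum(durations)
    start = np.concatenate([[0.0], end[:-1]])
    return FrameSchedule(start, end)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Midpoint time (s) of each frame."""
    return schedule.midpoints_s


def truncate_schedule(schedule: FrameSchedule, t_max_s: float) -> FrameSchedule:
    """Keep exactly the frames ending at or before ``t_max_s``."""
    if t_max_s <= 0:
        raise ValidationError("t_max_s must be positive")
    keep = schedule.end_s <= t_max_s + 1e-9
    if not np.any(keep):
        raise ValidationError(
            f"t_max_s={t_max_s} precedes the end of the first frame "
            f"({schedule.end_s[0]} s)"
        )
    return FrameSchedule(schedule.start_s[keep], schedule.end_s[keep])


def truncate_tac(tac: TimeActivityCurve, t_max_s: float) -> TimeActivityCurve:
    """Truncate a TAC and its schedule together, keeping values aligned."""
    sub = truncate_schedule(tac.schedule, t_max_s)
    return replace(tac, schedule=sub, values=tac.values[: sub.n_frames])


# ---------------------------------------------------------------------------
# CSV I/O.  Comma-separated, dot decimal, required header, UTF-8.


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_tac(path) -> TimeActivityCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TAC_COLUMNS, path)
    start = df["frame_start_s"].to_numpy(float)
    end = df["frame_end_s"].to_numpy(float)
    if np.any(np.diff(start) <= 0):
        bad = int(np.argmax(np.diff(start) <= 0)) + 2  # 1-based + header line
        raise ValidationError(f"{path}: frame starts not increasing at data line {bad}")
    noisy = bool(df.attrs.get("noisy", False)) or bool(np.any(df["activity_kBq_per_mL"] < 0))
    return TimeActivityCurve(
        FrameSchedule(start, end),
        df["activity_kBq_per_mL"].to_numpy(float),
        label=str(df["label"].iloc[0]) if "label" in df.columns else "",
        noisy=noisy,
    )


def write_tac(tac: TimeActivityCurve, path) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.start_s,
            "frame_end_s": tac.schedule.end_s,
            "activity_kBq_per_mL": tac.values,
        }
    )
    if tac.label:
        df["label"] = tac.label
    df.to_csv(path, index=False, float_format="%.17g")


def read_blood(path) -> BloodSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BLOOD_COLUMNS, path)
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise ValidationError(f"{path}: sample times not increasing at data line {bad}")
    return BloodSeries(
        t,
        df["wholeblood_kBq_per_mL"].to_numpy(float),
        df["plasma_kBq_per_mL"].to_numpy(float),
        df["parent_fraction"].to_numpy(float),
    )


def write_blood(bs: BloodSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": bs.sample_times_s,
            "wholeblood_kBq_per_mL": bs.wholeblood,
            "plasma_kBq_per_mL": bs.plasma,
            "parent_fraction": bs.parent_fraction,
        }
    ).to_csv(path, index=False, float_format="%.17g")
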