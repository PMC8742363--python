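"""Core skeleton data model, coordinate conventions, file I/O and body geometry.

Coordinate convention (documented, fixed throughout the package):

* ``y`` is vertical, positive up;
* ``x`` is lateral, positive toward the skeleton's anatomical **left**;
* ``z`` is anterior, positive forward;
* all positions are in meters, timestamps in seconds.

A motion stream is a :class:`MotionSequence`: an ordered set of time-stamped
frames, each holding the 3-D positions of the 25 joints of the Kinect-V2-style
skeletal model plus a per-joint validity flag.  Sequences are stored
array-backed (``positions`` has shape ``(n_frames, 25, 3)``) for efficient
vectorised processing; :class:`SkeletonFrame` offers a per-frame view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "JointId",
    "SkeletonFrame",
    "MotionSequence",
    "BodyGeometry",
    "read_skeleton",
    "write_skeleton",
    "center_pelvis",
    "estimate_height",
    "CONTRALATERAL",
]


class JointId(IntEnum):
    """The 25 joints of the Kinect V2 skeletal model, in canonical order."""

    SpineBase = 0  # pelvis
    SpineMid = 1
    Neck = 2
    Head = 3
    ShoulderLeft = 4
    ElbowLeft = 5
    WristLeft = 6
    HandLeft = 7
    ShoulderRight = 8
    ElbowRight = 9
    WristRight = 10
    HandRight = 11
    HipLeft = 12
    KneeLeft = 13
    AnkleLeft = 14
    FootLeft = 15
    HipRight = 16
    KneeRight = 17
    AnkleRight = 18
    FootRight = 19
    SpineShoulder = 20
    HandTipLeft = 21
    ThumbLeft = 22
    HandTipRight = 23
    ThumbRight = 24

    @property
    def contralateral(self) -> "JointId":
        """The mirror-image joint (self for midline joints)."""
        return CONTRALATERAL[self]


def _build_contralateral() -> dict[JointId, JointId]:
    pairs = {}
    for j in JointId:
        name = j.name
        if name.endswith("Left"):
            pairs[j] = JointId[name[:-4] + "Right"]
        elif name.endswith("Right"):
            pairs[j] = JointId[name[:-5] + "Left"]
        else:
            pairs[j] = j
    return pairs


CONTRALATERAL: dict[JointId, JointId] = _build_contralateral()

N_JOINTS = len(JointId)
PELVIS = JointId.SpineBase

# column order of the CSV/JSONL dialect: timestamp, then x/y/z per joint
_COORD_SUFFIXES = ("x", "y", "z")
COLUMNS = ["timestamp"] + [
    f"{j.name}_{c}" for j in JointId for c in _COORD_SUFFIXES
]


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped skeleton pose.

    ``positions`` is a ``(25, 3)`` array of x/y/z coordinates in meters;
    ``validity`` flags which joints were tracked.  Invalid joints hold NaN.
    """

    timestamp: float
    positions: np.ndarray
    validity: np.ndarray

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise DataError(f"negative timestamp {self.timestamp}")
        if self.positions.shape != (N_JOINTS, 3):
            raise DataError(
                f"positions must be (25, 3), got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions[self.validity])):
            raise DataError("valid joints must have finite positions")


@dataclass
class MotionSequence:
    """An ordered 25-joint skeleton stream at a nominal sampling rate.

    Attributes
    ----------
    timestamps : (n,) array of seconds, strictly increasing.
    positions : (n, 25, 3) array of meters; NaN where invalid.
    validity : (n, 25) boolean array.
    nominal_rate : nominal sampling rate in Hz (metadata; default 30).
    participant : optional participant identifier.
    session : optional session index (1..6 in the study design).
    """

    timestamps: np.ndarray
    positions: np.ndarray
    validity: np.ndarray | None = None
    nominal_rate: float = 30.0
    participant: str | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.timestamps)
        if self.positions.shape != (n, N_JOINTS, 3):
            raise DataError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} timestamps"
            )
        if self.validity is None:
            self.validity = np.all(np.isfinite(self.positions), axis=2)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.shape != (n, N_JOINTS):
                raise DataError("validity shape mismatch")
        if self.nominal_rate <= 0:
            raise DataError("nominal_rate must be positive")
        if n and self.timestamps[0] < 0:
            raise DataError("timestamps must be non-negative")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps must be strictly increasing")

    # -- basic container protocol -------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def __len__(self) -> int:
        return self.n_frames

    @property
    def duration(self) -> float:
        """Span of the timestamps in seconds (0 for < 2 frames)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def frames(self) -> Iterator[SkeletonFrame]:
        for i in range(self.n_frames):
            yield SkeletonFrame(
                float(self.timestamps[i]),
                self.positions[i],
                self.validity[i],
            )

    def copy(self) -> "MotionSequence":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            positions=self.positions.copy(),
            validity=self.validity.copy(),
        )

    def slice_frames(self, start: int, end: int) -> "MotionSequence":
        """Sub-sequence over the half-open frame range [start, end)."""
        return replace(
            self,
            timestamps=self.timestamps[start:end].copy(),
            positions=self.positions[start:end].copy(),
            validity=self.validity[start:end].copy(),
        )

    def joint(self, joint: JointId) -> np.ndarray:
        """(n, 3) trajectory of one joint."""
        return self.positions[:, int(joint), :]

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[SkeletonFrame],
        nominal_rate: float = 30.0,
        participant: str | None = None,
        session: int | None = None,
    ) -> "MotionSequence":
        ts = np.array([f.timestamp for f in frames], dtype=float)
        pos = np.array([f.positions for f in frames], dtype=float).reshape(
            len(frames), N_JOINTS, 3
        )
        val = np.array([f.validity for f in frames], dtype=bool).reshape(
            len(frames), N_JOINTS
        )
        return cls(ts, pos, val, nominal_rate, participant, session)


@dataclass(frozen=True)
class BodyGeometry:
    """Body-size normalizer: standing height in meters.

    Used to express efficiency measures as fractions of stature so that
    scores are comparable across participants of different sizes.
    """

    height: float

    def __post_init__(self) -> None:
        if not (self.height > 0 and np.isfinite(self.height)):
            raise DataError(f"height must be positive, got {self.height}")


# ---------------------------------------------------------------------------
# File I/O — documented CSV / JSONL dialect
# ---------------------------------------------------------------------------
#
# CSV: header ``timestamp,<JOINT>_x,<JOINT>_y,<JOINT>_z`` for the 25 canonical
# joint names (75 coordinate columns), one row per frame, '.' decimal
# separator, empty cell = invalid joint.
#
# JSONL: one frame object per line with the same keys; a missing or null key
# marks the joint coordinate invalid.


def _seq_from_table(ts: np.ndarray, coords: np.ndarray, rate: float) -> MotionSequence:
    n = len(ts)
    if n > 1 and not np.all(np.diff(ts) > 0):
        bad = int(np.argmin(np.diff(ts) > 0))
        raise FormatError(
            f"timestamps not strictly increasing at row {bad + 1}"
        )
    positions = coords.reshape(n, N_JOINTS, 3)
    validity = np.all(np.isfinite(positions), axis=2)
    positions = positions.copy()
    positions[~validity] = np.nan
    return MotionSequence(ts, positions, validity, nominal_rate=rate)


def read_skeleton(
    path: str | Path, format: str | None = None, nominal_rate: float = 30.0
) -> MotionSequence:
    """Read a skeleton stream from CSV or JSONL.

    ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".json") else "csv"
    if format == "csv":
        df = pd.read_csv(path, dtype=float)
        missing = [c for c in COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in COLUMNS]
        if missing or extra:
            raise FormatError(
                f"{path}: bad columns (missing {missing[:3]}, extra {extra[:3]})"
            )
        df = df[COLUMNS]
        ts = df["timestamp"].to_numpy()
        coords = df.iloc[:, 1:].to_numpy()
    elif format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        ts = np.array([float(r["timestamp"]) for r in rows])
        coords = np.full((len(rows), N_JOINTS * 3), np.nan)
        for i, r in enumerate(rows):
            for k, col in enumerate(COLUMNS[1:]):
                v = r.get(col)
                if v is not None:
                    coords[i, k] = float(v)
    else:
        raise FormatError(f"unknown format {format!r}")
    return _seq_from_table(ts, coords, nominal_rate)


def write_skeleton(
    seq: MotionSequence, path: str | Path, format: str | None = None
) -> None:
    """Write a sequence in the documented dialect (≥ 9 significant digits)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".json") else "csv"
    coords = seq.positions.reshape(seq.n_frames, N_JOINTS * 3)
    if format == "csv":
        df = pd.DataFrame(
            np.column_stack([seq.timestamps, coords]) if seq.n_frames else
            np.empty((0, len(COLUMNS))),
            columns=COLUMNS,
        )
        df.to_csv(path, index=False, float_format="%.9g", na_rep="")
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for i in range(seq.n_frames):
                rec: dict[str, float | None] = {
                    "timestamp": round(float(seq.timestamps[i]), 9)
                }
                for k, col in enumerate(COLUMNS[1:]):
                    v = coords[i, k]
                    rec[col] = None if not np.isfinite(v) else float(f"{v:.9g}")
                fh.write(json.dumps(rec) + "\n")
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def center_pelvis(seq: MotionSequence) -> MotionSequence:
    """Translate every frame so the pelvic joint (SpineBase) sits at the origin.

    Removes the participant's position in the capture volume while preserving
    all inter-joint distances.  Idempotent.
    """
    bad = np.nonzero(~seq.validity[:, int(PELVIS)])[0]
    if bad.size:
        raise DataError(f"pelvis joint invalid in frame {int(bad[0])}")
    out = seq.copy()
    out.positions -= out.positions[:, int(PELVIS) : int(PELVIS) + 1, :]
    return out


def estimate_height(seq: MotionSequence) -> BodyGeometry:
    """Estimate standing height from the skeleton itself.

    Height is the median, over frames where head and both ankles are valid,
    of the head vertical coordinate minus the mean of the two ankle vertical
    coordinates.  A measured stature supplied via configuration overrides
    this estimate downstream.
    """
    head = seq.positions[:, int(JointId.Head), 1]
    ank_l = seq.positions[:, int(JointId.AnkleLeft), 1]
    ank_r = seq.positions[:, int(JointId.AnkleRight), 1]
    ok = (
        seq.validity[:, int(JointId.Head)]
        & seq.validity[:, int(JointId.AnkleLeft)]
        & seq.validity[:, int(JointId.AnkleRight)]
    )
    if not np.any(ok):
        raise DataError("no frame with valid head and both ankles")
    gap = head[ok] - 0.5 * (ank_l[ok] + ank_r[ok])
    h = float(np.median(gap))
    if h <= 0:
        raise DataError(f"non-positive height estimate {h:.3f} m")
    return BodyGeometry(height=h)
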