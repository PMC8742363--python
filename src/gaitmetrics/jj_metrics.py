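"""Quantification of jumping-jack performance: 11 measures in 3 categories.

Given a jumping-jack segment of a 25-joint skeleton stream, the module
computes:

**Efficiency** — how far the distal limbs travel, as fractions of stature:

* ``K1``: maximum wrist elevation above the same-side shoulder, / height;
* ``K2``: widest horizontal ankle-to-ankle separation, / height.

**Synchrony** — how tightly the four limb drives are coordinated:

* ``H1``: sample variance (Hz²) of the four dominant frequencies of the
  shoulder/hip abduction angles θ1..θ4 (left/right shoulder, left/right
  hip);
* ``H2``: mean absolute relative phase (MARP, radians in [0, π]) between a
  configurable signal pair (default: left vs. right shoulder angle), from
  phase-plane angles;
* ``H3``: continuous-relative-phase standard deviation (CRP-SD, radians)
  of the same pair;
* ``H4``/``H5``: mean absolute left–right difference (seconds) of hand
  (resp. leg) stop instants — the moments a limb's speed reaches a
  near-zero local minimum, e.g. the apex of each jack.

**Symmetry** — how mirror-like the two hands move about the body midline:

* ``M1``/``M2``: time-mean and time-SD (meters) of the absolute difference
  between the two hands' absolute lateral offsets from the pelvis;
* ``M3``/``M4``: time-mean absolute difference (m/s) between the absolute
  horizontal (resp. vertical) hand velocities.

All measures operate on pelvis-centered, 3 Hz zero-lag smoothed channels,
so they are invariant to where the participant stood and to whole-body
drift, and they are bilateral-symmetric: mirroring the skeleton leaves
every measure unchanged.  Degenerate inputs (constant channels, fewer than
two stop events per side) yield NaN — an explicit "undefined", never a
silent zero — so session averages are taken over defined values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateSignalError,
    ParameterError,
    UndefinedFrequencyError,
)
from .preprocess import smooth_jj, velocity
from .segmentation import ActionLabel, Segment
from .skeleton import BodyGeometry, JointId, MotionSequence, estimate_height

__all__ = [
    "LimbAngleSet",
    "PhaseSeries",
    "StopEvents",
    "JJMetrics",
    "compute_limb_angles",
    "dominant_frequency",
    "phase_angle",
    "detect_stops",
    "synchrony_measures",
    "efficiency_measures",
    "symmetry_measures",
    "compute_all",
    "metrics_frame",
    "MEASURES",
]

logger = logging.getLogger(__name__)

J = JointId
MEASURES = ("K1", "K2", "H1", "H2", "H3", "H4", "H5", "M1", "M2", "M3", "M4")

VALIDITY_THRESHOLD = 0.95


@dataclass
class LimbAngleSet:
    """Abduction-angle series θ1..θ4 (radians): left/right shoulder,
    left/right hip, on a common time base, 3 Hz-smoothed."""

    shoulder_left: np.ndarray
    shoulder_right: np.ndarray
    hip_left: np.ndarray
    hip_right: np.ndarray
    rate: float

    def all(self) -> tuple[np.ndarray, ...]:
        return (
            self.shoulder_left,
            self.shoulder_right,
            self.hip_left,
            self.hip_right,
        )

    def by_name(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass(frozen=True)
class PhaseSeries:
    """Phase-plane angle series in (−π, π] for one signal."""

    values: np.ndarray
    rate: float


@dataclass(frozen=True)
class StopEvents:
    """Stop instants (seconds from segment start) of one limb channel."""

    times: np.ndarray

    @property
    def count(self) -> int:
        return len(self.times)


@dataclass
class JJMetrics:
    """The 11 per-segment jumping-jack measures (NaN = undefined)."""

    K1: float
    K2: float
    H1: float
    H2: float
    H3: float
    H4: float
    H5: float
    M1: float
    M2: float
    M3: float
    M4: float
    segment_index: int | None = None
    participant: str | None = None
    session: int | None = None

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


# ---------------------------------------------------------------------------
# Channel plumbing
# ---------------------------------------------------------------------------


def _check_validity(
    seq: MotionSequence, segment: Segment, joints: Sequence[JointId]
) -> None:
    val = seq.validity[segment.start_frame : segment.end_frame]
    for j in joints:
        frac = float(np.mean(val[:, int(j)]))
        if frac < VALIDITY_THRESHOLD:
            raise DataError(
                f"joint {j.name} only {frac:.0%} valid in segment "
                f"[{segment.start_frame},{segment.end_frame}) "
                f"(threshold {VALIDITY_THRESHOLD:.0%})"
            )


def _fill_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over isolated invalid samples of one channel."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    idx = np.arange(len(x))
    return np.interp(idx, idx[~bad], x[~bad])


def _centered_channels(
    seq: MotionSequence, segment: Segment
) -> tuple[np.ndarray, float]:
    """Pelvis-centered (n, 25, 3) positions of one segment + sampling rate."""
    sub = seq.slice_frames(segment.start_frame, segment.end_frame)
    pos = sub.positions - sub.positions[:, int(J.SpineBase) : int(J.SpineBase) + 1]
    return pos, sub.nominal_rate


def _smooth_joint_channel(
    pos: np.ndarray, joint: JointId, axis: int, rate: float
) -> np.ndarray:
    return smooth_jj(_fill_nan(pos[:, int(joint), axis]), rate)


# ---------------------------------------------------------------------------
# Limb angles and spectra
# ---------------------------------------------------------------------------


def _vec_angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Per-frame angle (radians) between two (n, 3) vector series."""
    cross = np.linalg.norm(np.cross(v1, v2), axis=1)
    dot = np.einsum("ij,ij->i", v1, v2)
    return np.arctan2(cross, dot)


def compute_limb_angles(
    seq: MotionSequence, segment: Segment
) -> LimbAngleSet:
    """Shoulder and hip abduction angles over a segment.

    Shoulder abduction is the angle between the torso down-axis of that
    side (shoulder → same-side hip) and the upper arm (shoulder → elbow);
    hip abduction is the angle between the pelvis down-axis (spine-mid →
    spine-base, extended) and the thigh (hip → knee).  Each series is
    3 Hz-smoothed.
    """
    needed = [
        J.ShoulderLeft, J.ShoulderRight, J.ElbowLeft, J.ElbowRight,
        J.HipLeft, J.HipRight, J.KneeLeft, J.KneeRight,
        J.SpineBase, J.SpineMid,
    ]
    _check_validity(seq, segment, needed)
    pos, rate = _centered_channels(seq, segment)
    pos = pos.copy()
    for j in needed:
        for ax in range(3):
            pos[:, int(j), ax] = _fill_nan(pos[:, int(j), ax])

    def series(prox: JointId, dist: JointId, ref: np.ndarray) -> np.ndarray:
        limb = pos[:, int(dist)] - pos[:, int(prox)]
        return smooth_jj(_vec_angle(ref, limb), rate)

    down = pos[:, int(J.SpineBase)] - pos[:, int(J.SpineMid)]
    sh_l = pos[:, int(J.HipLeft)] - pos[:, int(J.ShoulderLeft)]
    sh_r = pos[:, int(J.HipRight)] - pos[:, int(J.ShoulderRight)]
    return LimbAngleSet(
        shoulder_left=series(J.ShoulderLeft, J.ElbowLeft, sh_l),
        shoulder_right=series(J.ShoulderRight, J.ElbowRight, sh_r),
        hip_left=series(J.HipLeft, J.KneeLeft, down),
        hip_right=series(J.HipRight, J.KneeRight, down),
        rate=rate,
    )


def dominant_frequency(channel: np.ndarray, rate: float) -> float:
    """Positive frequency of maximal magnitude in the mean-removed DFT
    spectrum (resolution rate/N)."""
    x = np.asarray(channel, dtype=float)
    n = len(x)
    if n < 30:
        raise DataError(f"dominant_frequency needs >= 30 samples, got {n}")
    x = x - np.mean(x)
    if np.max(np.abs(x)) < 1e-12:
        raise UndefinedFrequencyError("flat signal has no dominant frequency")
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    k = int(np.argmax(spec[1:])) + 1  # skip the (zeroed) DC bin
    return float(freqs[k])


# ---------------------------------------------------------------------------
# Phase-plane analysis
# ---------------------------------------------------------------------------


def phase_angle(channel: np.ndarray, rate: float) -> PhaseSeries:
    """Phase-plane angle of a cyclic signal.

    Position is centered and amplitude-normalized to [−1, 1]; velocity
    (central differences) is normalized by its peak magnitude; the phase
    angle is the four-quadrant arctangent ``atan2(v_norm, s_norm)``.  The
    standard construction behind continuous-relative-phase coordination
    measures.
    """
    s = np.asarray(channel, dtype=float)
    lo, hi = np.min(s), np.max(s)
    if hi - lo < 1e-12:
        raise DegenerateSignalError("constant signal has no phase angle")
    s_n = 2.0 * (s - lo) / (hi - lo) - 1.0
    v = velocity(s, rate)
    vmax = np.max(np.abs(v))
    v_n = v / vmax if vmax > 0 else v
    return PhaseSeries(values=np.arctan2(v_n, s_n), rate=rate)


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (−π, π]."""
    return np.pi - np.mod(np.pi - a, 2.0 * np.pi)


def relative_phase(
    s1: np.ndarray, s2: np.ndarray, rate: float
) -> np.ndarray:
    """Continuous relative phase PA(s1) − PA(s2), wrapped to (−π, π]."""
    pa1 = phase_angle(s1, rate).values
    pa2 = phase_angle(s2, rate).values
    return _wrap(pa1 - pa2)


# ---------------------------------------------------------------------------
# Stop events
# ---------------------------------------------------------------------------


def detect_stops(
    channel: np.ndarray, rate: float, speed_floor: float = 0.05
) -> StopEvents:
    """Instants at which a limb channel stops moving.

    A stop is a near-zero local minimum of |velocity|: either a velocity
    sign change (stop time refined by linear interpolation of the zero
    crossing) or a dwell — a run of samples with speed below
    ``speed_floor`` × peak speed, contributing its single minimum-speed
    instant.  Events closer than two frame periods are merged.
    """
    v = velocity(channel, rate)
    speed = np.abs(v)
    peak = float(np.max(speed))
    if peak < 1e-12:
        return StopEvents(times=np.empty(0))
    floor = speed_floor * peak
    events: list[float] = []
    # sign changes with sub-frame zero-crossing refinement
    s = np.sign(v)
    for i in np.nonzero(s[:-1] * s[1:] < 0)[0]:
        frac = v[i] / (v[i] - v[i + 1])
        events.append((i + frac) / rate)
    # exact zeros and low-speed dwells
    below = speed <= floor
    i = 0
    n = len(v)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            k = i + int(np.argmin(speed[i : j + 1]))
            events.append(k / rate)
            i = j + 1
        else:
            i += 1
    events.sort()
    merged: list[float] = []
    for t in events:
        if merged and t - merged[-1] < 2.0 / rate:
            continue
        merged.append(t)
    return StopEvents(times=np.asarray(merged))


def _paired_stop_diff(
    left: StopEvents, right: StopEvents, max_offset: int = 2
) -> float:
    """Mean |ΔT| over sequentially paired left/right stop events.

    Events are paired in order and truncated to the shorter side.  The
    alignment carries free leading offsets: one list may skip up to
    ``max_offset`` leading events (spurious or missed boundary detections
    otherwise shift every pair by half a cycle), and the offset minimizing
    the mean absolute difference is used.  NaN when fewer than two pairs
    remain on either side.
    """
    best = float("nan")
    for off_l, off_r in [(0, 0)] + [
        (i, 0) for i in range(1, max_offset + 1)
    ] + [(0, j) for j in range(1, max_offset + 1)]:
        k = min(left.count - off_l, right.count - off_r)
        if k < 2:
            continue
        m = float(
            np.mean(
                np.abs(
                    left.times[off_l : off_l + k]
                    - right.times[off_r : off_r + k]
                )
            )
        )
        if not (m >= best):  # also true when best is NaN
            best = m
    return best


# ---------------------------------------------------------------------------
# The three measure families
# ---------------------------------------------------------------------------


def efficiency_measures(
    seq: MotionSequence, segment: Segment, geom: BodyGeometry
) -> tuple[float, float]:
    """(K1, K2): peak wrist elevation and peak ankle spread, / height."""
    if geom.height <= 0:
        raise ParameterError("geometry height must be positive")
    _check_validity(
        seq, segment,
        [J.WristLeft, J.WristRight, J.ShoulderLeft, J.ShoulderRight,
         J.AnkleLeft, J.AnkleRight],
    )
    pos, rate = _centered_channels(seq, segment)
    ch = lambda j, ax: _smooth_joint_channel(pos, j, ax, rate)
    elev_l = ch(J.WristLeft, 1) - ch(J.ShoulderLeft, 1)
    elev_r = ch(J.WristRight, 1) - ch(J.ShoulderRight, 1)
    k1 = max(float(np.max(elev_l)), float(np.max(elev_r))) / geom.height
    dx = ch(J.AnkleLeft, 0) - ch(J.AnkleRight, 0)
    dz = ch(J.AnkleLeft, 2) - ch(J.AnkleRight, 2)
    k2 = float(np.max(np.hypot(dx, dz))) / geom.height
    return k1, k2


def synchrony_measures(
    angles: LimbAngleSet,
    seq: MotionSequence,
    segment: Segment,
    rate: float | None = None,
    pair: tuple[str, str] = ("shoulder_left", "shoulder_right"),
    speed_floor: float = 0.05,
) -> tuple[float, float, float, float, float]:
    """(H1, H2, H3, H4, H5).

    H1 is the sample variance of the four dominant frequencies; H2/H3 are
    MARP and CRP-SD of the configured signal pair; H4/H5 are mean absolute
    left–right stop-time differences of the hand vertical and ankle lateral
    channels.
    """
    rate = rate or angles.rate
    freqs = []
    for theta in angles.all():
        try:
            freqs.append(dominant_frequency(theta, rate))
        except UndefinedFrequencyError:
            freqs.append(float("nan"))
    freqs = np.asarray(freqs)
    h1 = float(np.var(freqs, ddof=1)) if np.all(np.isfinite(freqs)) else float("nan")

    try:
        crp = relative_phase(
            angles.by_name(pair[0]), angles.by_name(pair[1]), rate
        )
        h2 = float(np.mean(np.abs(crp)))
        h3 = float(np.std(np.unwrap(crp)))
    except DegenerateSignalError:
        h2 = h3 = float("nan")

    _check_validity(
        seq, segment,
        [J.HandLeft, J.HandRight, J.AnkleLeft, J.AnkleRight],
    )
    pos, seg_rate = _centered_channels(seq, segment)
    hand_l = _smooth_joint_channel(pos, J.HandLeft, 1, seg_rate)
    hand_r = _smooth_joint_channel(pos, J.HandRight, 1, seg_rate)
    ankle_l = _smooth_joint_channel(pos, J.AnkleLeft, 0, seg_rate)
    ankle_r = _smooth_joint_channel(pos, J.AnkleRight, 0, seg_rate)
    h4 = _paired_stop_diff(
        detect_stops(hand_l, seg_rate, speed_floor),
        detect_stops(hand_r, seg_rate, speed_floor),
    )
    h5 = _paired_stop_diff(
        detect_stops(ankle_l, seg_rate, speed_floor),
        detect_stops(ankle_r, seg_rate, speed_floor),
    )
    return h1, h2, h3, h4, h5


def symmetry_measures(
    seq: MotionSequence, segment: Segment, rate: float | None = None
) -> tuple[float, float, float, float]:
    """(M1, M2, M3, M4): bilateral hand position/velocity symmetry.

    ``c1``/``c2`` are the absolute lateral offsets of the right/left hand
    from the pelvis midline; M1/M2 are the time-mean and time-SD of
    |c1 − c2|; M3/M4 compare the absolute horizontal/vertical hand speeds.
    A perfectly mirrored movement scores 0 on all four.
    """
    _check_validity(seq, segment, [J.HandLeft, J.HandRight])
    pos, seg_rate = _centered_channels(seq, segment)
    rate = rate or seg_rate
    x_l = _smooth_joint_channel(pos, J.HandLeft, 0, rate)
    x_r = _smooth_joint_channel(pos, J.HandRight, 0, rate)
    y_l = _smooth_joint_channel(pos, J.HandLeft, 1, rate)
    y_r = _smooth_joint_channel(pos, J.HandRight, 1, rate)
    c1, c2 = np.abs(x_r), np.abs(x_l)
    gap = np.abs(c1 - c2)
    m1 = float(np.mean(gap))
    m2 = float(np.std(gap))
    vx_l, vx_r = velocity(x_l, rate), velocity(x_r, rate)
    vy_l, vy_r = velocity(y_l, rate), velocity(y_r, rate)
    m3 = float(np.mean(np.abs(np.abs(vx_r) - np.abs(vx_l))))
    m4 = float(np.mean(np.abs(np.abs(vy_r) - np.abs(vy_l))))
    return m1, m2, m3, m4


def compute_all(
    seq: MotionSequence,
    segments: Sequence[Segment],
    geom: BodyGeometry | None = None,
    pair: tuple[str, str] = ("shoulder_left", "shoulder_right"),
) -> list[JJMetrics]:
    """All 11 measures for every jumping-jack segment of a sequence.

    Non-jumping-jack segments are skipped with a logged notice.  The height
    normalizer defaults to the skeleton-based estimate over the whole
    sequence; a measured stature can be passed instead.
    """
    if geom is None:
        geom = estimate_height(seq)
    out: list[JJMetrics] = []
    for i, segment in enumerate(segments):
        if segment.label is not ActionLabel.JUMPING_JACK:
            logger.info(
                "segment %d (%s) skipped: metrics are defined for jumping "
                "jacks only", i, segment.label.value,
            )
            continue
        try:
            angles = compute_limb_angles(seq, segment)
            k1, k2 = efficiency_measures(seq, segment, geom)
            h1, h2, h3, h4, h5 = synchrony_measures(
                angles, seq, segment, pair=pair
            )
            m1, m2, m3, m4 = symmetry_measures(seq, segment)
        except DataError as exc:
            raise DataError(f"segment {i}: {exc}") from exc
        out.append(
            JJMetrics(
                K1=k1, K2=k2, H1=h1, H2=h2, H3=h3, H4=h4, H5=h5,
                M1=m1, M2=m2, M3=m3, M4=m4,
                segment_index=i,
                participant=seq.participant,
                session=seq.session,
            )
        )
    return out


def metrics_frame(metrics: Sequence[JJMetrics]) -> pd.DataFrame:
    """Tabulate per-segment metrics (one row per jumping jack)."""
    rows = []
    for m in metrics:
        row = {
            "participant": m.participant,
            "session": m.session,
            "segment_index": m.segment_index,
        }
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["participant", "session", "segment_index", *MEASURES]
    )
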