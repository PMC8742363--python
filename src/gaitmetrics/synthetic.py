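"""Parametric generator of ground-truthed 25-joint skeleton motion.

Stands in for unpublished participant recordings: every one of the 10
scripted actions (jumping jack, directional jumps/steps, walk, touch nose,
idle) is synthesized from a 2-segment forward-kinematic limb model whose
segment lengths are standard anthropometric fractions of stature (upper
arm 0.186·h, forearm 0.146·h, thigh 0.245·h, shank 0.246·h).  Because limb
trajectories are driven by explicit abduction-angle cycles, the generator
knows its own answers — peak wrist elevation, peak ankle spread, the
injected right-left lag — and records them in a :class:`GroundTruth`
object so downstream metrics can be validated by parameter recovery.

Controllable imperfections emulate real movers:

* ``rl_amplitude_ratio`` scales the right-side movement amplitude
  (1 = symmetric);
* ``rl_lag`` delays all right-limb drive signals by a fixed time;
* ``armleg_phase`` de-phases the leg cycle from the arm cycle;
* ``timing_jitter`` multiplies each cycle's period by ``1 + U(−j, +j)``,
  emulating tempo variability;
* ``noise_sd`` adds Gaussian tracking noise band-limited above 6 Hz, the
  kind of physically impossible high-frequency content a pose tracker
  produces and the 3 Hz cleaning filter is meant to remove.

One convention worth noting: the head joint is placed so that the vertical
head-to-ankle gap of the neutral pose equals the profile's stature, matching
the pipeline's skeleton-based height estimator exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .errors import ParameterError
from .segmentation import ActionLabel, Segment
from .skeleton import JointId, MotionSequence, N_JOINTS

__all__ = [
    "ParticipantProfile",
    "GroundTruth",
    "generate_jumping_jack",
    "generate_action",
    "generate_session",
    "DEFAULT_SESSION_SCRIPT",
]

# anthropometric fractions of stature
_ANKLE_H = 0.039
_THIGH = 0.245
_SHANK = 0.246
_LEG = _THIGH + _SHANK
_HIP_HALF = 0.0955
_UPPER_ARM = 0.186
_FOREARM = 0.146
_HAND = 0.030
_HANDTIP = 0.020
_ARM_MIN = 0.06  # resting shoulder abduction, radians
_BOUNCE = 0.04  # whole-body vertical hop amplitude during a JJ, meters

J = JointId


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one synthetic mover.

    Doubles as the ground truth for parameter-recovery tests.  Defaults
    describe a plausible adolescent mover: stature near the study cohort's
    mean, a relaxed 0.5 Hz jumping-jack tempo, near-full arm abduction,
    mild asymmetry and tempo jitter, and millimeter-scale tracking noise.
    """

    height: float = 1.58  # m
    jj_frequency: float = 0.5  # Hz, jumping-jack cycle rate
    arm_amplitude: float = 150.0  # degrees of peak shoulder abduction
    max_ankle_spread: float = 0.55  # m, peak ankle separation
    rl_amplitude_ratio: float = 1.0  # right/left amplitude ratio
    rl_lag: float = 0.0  # s, right limbs lag left
    armleg_phase: float = 0.0  # rad, leg cycle phase offset vs arms
    noise_sd: float = 0.0  # m, additive high-frequency noise
    timing_jitter: float = 0.0  # fraction of cycle period
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ParameterError("height must be positive")
        if self.jj_frequency <= 0:
            raise ParameterError("jj_frequency must be positive")
        if not (0 < self.rl_amplitude_ratio <= 2):
            raise ParameterError("rl_amplitude_ratio must be in (0, 2]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not (0 <= self.timing_jitter < 0.5):
            raise ParameterError("timing_jitter must be in [0, 0.5)")
        if not (0 < self.arm_amplitude <= 180):
            raise ParameterError("arm_amplitude must be in (0, 180] degrees")
        if self.max_ankle_spread <= 2 * _HIP_HALF * self.height:
            raise ParameterError(
                "max_ankle_spread must exceed the standing ankle separation "
                f"({2 * _HIP_HALF * self.height:.3f} m)"
            )


@dataclass
class GroundTruth:
    """True segmentation and per-segment analytic targets of a generated clip."""

    segments: list[Segment] = field(default_factory=list)
    targets: list[dict] = field(default_factory=list)

    def validate(self, n_frames: int) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start_frame < prev_end or seg.end_frame > n_frames:
                raise ParameterError("ground-truth segments out of order/bounds")
            prev_end = seg.end_frame


# ---------------------------------------------------------------------------
# Static pose
# ---------------------------------------------------------------------------


def neutral_pose(height: float) -> np.ndarray:
    """(25, 3) neutral standing pose, pelvis above the lateral/anterior origin."""
    n1 = np.zeros(1)
    return _pose_frames(height, n1 + _ARM_MIN, n1 + _ARM_MIN, n1, n1)[0]


def _limb_sides():
    # (sign, shoulder, elbow, wrist, hand, handtip, thumb, hip, knee, ankle, foot)
    return (
        (+1.0, J.ShoulderLeft, J.ElbowLeft, J.WristLeft, J.HandLeft,
         J.HandTipLeft, J.ThumbLeft, J.HipLeft, J.KneeLeft, J.AnkleLeft,
         J.FootLeft),
        (-1.0, J.ShoulderRight, J.ElbowRight, J.WristRight, J.HandRight,
         J.HandTipRight, J.ThumbRight, J.HipRight, J.KneeRight, J.AnkleRight,
         J.FootRight),
    )


def _pose_frames(
    height: float,
    alpha_l: np.ndarray,
    alpha_r: np.ndarray,
    phi_l: np.ndarray,
    phi_r: np.ndarray,
) -> np.ndarray:
    """Forward kinematics: (n, 25, 3) poses from shoulder/hip abduction
    angle series (radians, measured from the torso down-axis in the frontal
    plane).  Arms and legs are modeled straight (2-segment chains with the
    distal segments riding rigidly)."""
    h = height
    n = len(alpha_l)
    pos = np.zeros((n, N_JOINTS, 3))
    pelvis_y = (_ANKLE_H + _LEG) * h
    shoulder_y = 0.790 * h
    pos[:, J.SpineBase] = (0.0, pelvis_y, 0.0)
    pos[:, J.SpineMid] = (0.0, 0.655 * h, 0.0)
    pos[:, J.SpineShoulder] = (0.0, shoulder_y, 0.0)
    pos[:, J.Neck] = (0.0, 0.845 * h, 0.0)
    pos[:, J.Head] = (0.0, _ANKLE_H * h + h, 0.0)
    for (sgn, sh, el, wr, ha, ht, th, hip, kn, an, ft) in _limb_sides():
        alpha = alpha_l if sgn > 0 else alpha_r
        phi = phi_l if sgn > 0 else phi_r
        # shoulders sit directly above the hips so the torso down-axis of
        # each side is vertical and measured abduction equals the drive angle
        sh_pos = np.array([sgn * _HIP_HALF * h, shoulder_y, 0.0])
        pos[:, sh] = sh_pos
        arm_dir = np.stack(
            [sgn * np.sin(alpha), -np.cos(alpha), np.zeros(n)], axis=1
        )
        pos[:, el] = sh_pos + _UPPER_ARM * h * arm_dir
        pos[:, wr] = pos[:, el] + _FOREARM * h * arm_dir
        pos[:, ha] = pos[:, wr] + _HAND * h * arm_dir
        pos[:, ht] = pos[:, ha] + _HANDTIP * h * arm_dir
        pos[:, th] = pos[:, ha] + 0.02 * h * np.array([0.0, 0.0, 1.0])
        hip_pos = np.array([sgn * _HIP_HALF * h, pelvis_y, 0.0])
        pos[:, hip] = hip_pos
        leg_dir = np.stack(
            [sgn * np.sin(phi), -np.cos(phi), np.zeros(n)], axis=1
        )
        pos[:, kn] = hip_pos + _THIGH * h * leg_dir
        pos[:, an] = pos[:, kn] + _SHANK * h * leg_dir
        pos[:, ft] = pos[:, an] + np.array([0.0, -0.013 * h, 0.05 * h])
    return pos


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _jittered_phase(
    n_cycles: int, freq: float, jitter: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Phase function ψ(t) in radians with per-cycle period jitter.

    Returns (knot times, knot phases) for interpolation; cycle k spans
    2π·k .. 2π·(k+1) over a period (1 + u_k)/freq, u_k ~ U(−j, +j).
    """
    periods = (1.0 + rng.uniform(-jitter, jitter, size=n_cycles)) / freq
    knots_t = np.concatenate([[-periods[0], 0.0], np.cumsum(periods)])
    knots_psi = 2 * np.pi * np.arange(-1, n_cycles + 1)
    return knots_t, knots_psi


def _phase_at(knots_t, knots_psi, t):
    return np.interp(t, knots_t, knots_psi)


def _hf_noise(rng, shape, sd: float, rate: float) -> np.ndarray:
    """Gaussian noise band-limited above 6 Hz with per-channel sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if shape[0] > 18 and rate > 13:
        sos = sps.butter(4, 6.0, btype="high", fs=rate, output="sos")
        filt = sps.sosfiltfilt(sos, white, axis=0)
    else:
        filt = white
    scale = np.std(filt)
    if scale > 0:
        filt = filt * (sd / scale)
    return filt


def _finish(
    pos: np.ndarray,
    rate: float,
    profile: ParticipantProfile,
    rng,
) -> MotionSequence:
    n = pos.shape[0]
    noise = _hf_noise(rng, (n, N_JOINTS * 3), profile.noise_sd, rate)
    pos = pos + noise.reshape(n, N_JOINTS, 3)
    ts = np.arange(n) / rate
    return MotionSequence(ts, pos, nominal_rate=rate)


def _leg_amplitude(profile: ParticipantProfile) -> tuple[float, float]:
    """Peak hip-abduction angles (left, right) hitting the requested spread.

    Solves ``2·hip_half·h + leg·h·(sin φ_L + sin(r·φ_L)) = spread`` so that
    the peak ankle separation equals ``max_ankle_spread`` when the two sides
    peak together (ratio 1, lag 0); with asymmetry the true peak is recorded
    numerically in the ground truth instead.
    """
    h = profile.height
    r = profile.rl_amplitude_ratio
    target = (profile.max_ankle_spread - 2 * _HIP_HALF * h) / (_LEG * h)

    def f(phi):
        return np.sin(phi) + np.sin(r * phi) - target

    hi = np.pi / 2
    if f(hi) < 0:
        raise ParameterError("max_ankle_spread unreachable for this height")
    phi_l = brentq(f, 0.0, hi)
    return phi_l, r * phi_l


# ---------------------------------------------------------------------------
# Jumping jack
# ---------------------------------------------------------------------------


def generate_jumping_jack(
    profile: ParticipantProfile,
    n_cycles: int = 5,
    rate: float = 30.0,
    rng: np.random.Generator | None = None,
) -> tuple[MotionSequence, GroundTruth]:
    """Synthesize ``n_cycles`` jumping jacks.

    Shoulder and hip abduction follow raised-cosine cycles; the right side
    is amplitude-scaled by ``rl_amplitude_ratio`` and delayed by ``rl_lag``.
    A small whole-body vertical hop at twice the cycle rate emulates the
    airborne phases (it cancels under pelvis centering and leaves the
    head-to-ankle height gap untouched).
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    f = profile.jj_frequency
    h = profile.height
    knots_t, knots_psi = _jittered_phase(n_cycles, f, profile.timing_jitter, rng)
    total = knots_t[-1]
    n = int(round(total * rate))
    t = np.arange(n) / rate

    psi_l = _phase_at(knots_t, knots_psi, t)
    psi_r = _phase_at(knots_t, knots_psi, t - profile.rl_lag)
    cyc_l = 0.5 * (1.0 - np.cos(psi_l))
    cyc_r = 0.5 * (1.0 - np.cos(psi_r))
    psi_leg_l = _phase_at(knots_t, knots_psi, t) + profile.armleg_phase
    psi_leg_r = (
        _phase_at(knots_t, knots_psi, t - profile.rl_lag) + profile.armleg_phase
    )
    cyc_leg_l = 0.5 * (1.0 - np.cos(psi_leg_l))
    cyc_leg_r = 0.5 * (1.0 - np.cos(psi_leg_r))

    a_max = np.radians(profile.arm_amplitude)
    r = profile.rl_amplitude_ratio
    alpha_l = _ARM_MIN + (a_max - _ARM_MIN) * cyc_l
    alpha_r = _ARM_MIN + r * (a_max - _ARM_MIN) * cyc_r
    phi_max_l, phi_max_r = _leg_amplitude(profile)
    phi_l = phi_max_l * cyc_leg_l
    phi_r = phi_max_r * cyc_leg_r

    pos = _pose_frames(h, alpha_l, alpha_r, phi_l, phi_r)
    # whole-body hop: two jumps per cycle
    bounce = 0.5 * _BOUNCE * (1.0 - np.cos(2.0 * psi_l))
    pos[:, :, 1] += bounce[:, None]

    # analytic targets measured on the noise-free trajectories
    wrist_elev = max(
        float(np.max(pos[:, J.WristLeft, 1] - pos[:, J.ShoulderLeft, 1])),
        float(np.max(pos[:, J.WristRight, 1] - pos[:, J.ShoulderRight, 1])),
    )
    ankle_sep = np.linalg.norm(
        pos[:, J.AnkleLeft, [0, 2]] - pos[:, J.AnkleRight, [0, 2]], axis=1
    )
    truth = GroundTruth(
        segments=[Segment(ActionLabel.JUMPING_JACK, 0, n)],
        targets=[
            {
                "label": ActionLabel.JUMPING_JACK.value,
                "n_cycles": n_cycles,
                "max_wrist_elevation": wrist_elev,
                "max_ankle_spread": float(np.max(ankle_sep)),
                "rl_lag": profile.rl_lag,
                "rl_amplitude_ratio": profile.rl_amplitude_ratio,
                "armleg_phase": profile.armleg_phase,
                "arm_amplitude": profile.arm_amplitude,
                "jj_frequency": profile.jj_frequency,
            }
        ],
    )
    return _finish(pos, rate, profile, rng), truth


# ---------------------------------------------------------------------------
# Other scripted actions
# ---------------------------------------------------------------------------

_JUMP_DIRECTIONS = {
    ActionLabel.JUMP_FORWARD: np.array([0.0, 0.0, 1.0]),
    ActionLabel.JUMP_BACKWARD: np.array([0.0, 0.0, -1.0]),
    ActionLabel.JUMP_LEFT: np.array([1.0, 0.0, 0.0]),
    ActionLabel.JUMP_RIGHT: np.array([-1.0, 0.0, 0.0]),
}


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_action(
    label: ActionLabel | str,
    profile: ParticipantProfile,
    rate: float = 30.0,
    rng: np.random.Generator | None = None,
    displacement: float = 0.35,
    n_strides: int | None = None,
) -> tuple[MotionSequence, GroundTruth]:
    """Synthesize one non-jumping-jack scripted action.

    * directional jumps translate the whole body by ``displacement``
      (≥ 0.30 m for a valid jump) with an airborne hop;
    * steps translate by 0.30 m without a hop, more slowly;
    * ``walk`` contains 3–4 strides of alternating leg swing;
    * ``touch nose`` brings the right hand to the head and back;
    * ``idle`` is quiet standing with centimeter-scale sway.
    """
    label = ActionLabel(label)
    if label is ActionLabel.JUMPING_JACK:
        raise ParameterError(
            "jumping jack has its own generator: generate_jumping_jack"
        )
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    h = profile.height
    zeros = lambda n: np.zeros(n)
    const = lambda n, v: np.full(n, v)

    if label is ActionLabel.IDLE:
        n = int(round(2.0 * rate))
        tt = np.arange(n) / rate
        alpha = const(n, _ARM_MIN)
        pos = _pose_frames(h, alpha, alpha, zeros(n), zeros(n))
        pos[:, :, 0] += (0.01 * np.sin(2 * np.pi * 0.3 * tt))[:, None]
        targets = {"label": label.value, "max_excursion": 0.02}
    elif label in _JUMP_DIRECTIONS:
        if displacement < 0.30:
            raise ParameterError("a jump must displace at least 0.30 m")
        n = int(round(1.5 * rate))
        tt = np.arange(n) / rate
        u = tt / tt[-1]
        swing = 0.35 * np.sin(np.pi * u) ** 2
        alpha = _ARM_MIN + swing
        pos = _pose_frames(h, alpha, alpha, zeros(n), zeros(n))
        direction = _JUMP_DIRECTIONS[label]
        travel = _smoothstep((u - 0.25) / 0.5)
        hop = 0.12 * np.sin(np.pi * np.clip((u - 0.25) / 0.5, 0, 1)) ** 2
        pos += (displacement * travel)[:, None, None] * direction[None, None, :]
        pos[:, :, 1] += hop[:, None]
        targets = {"label": label.value, "displacement": displacement,
                   "direction": direction.tolist()}
    elif label in (ActionLabel.STEP_FORWARD, ActionLabel.STEP_BACK):
        step = 0.30 if label is ActionLabel.STEP_FORWARD else -0.30
        n = int(round(2.0 * rate))
        tt = np.arange(n) / rate
        u = tt / tt[-1]
        pos = _pose_frames(
            h, const(n, _ARM_MIN), const(n, _ARM_MIN), zeros(n), zeros(n)
        )
        travel = _smoothstep((u - 0.2) / 0.6)
        pos[:, :, 2] += (step * travel)[:, None]
        # leading leg swings anteriorly ahead of the trunk
        lead = 0.18 * np.sin(np.pi * np.clip(u / 0.7, 0, 1)) ** 2 * np.sign(step)
        for jn in (J.KneeRight, J.AnkleRight, J.FootRight):
            pos[:, jn, 2] += lead
        targets = {"label": label.value, "displacement": step}
    elif label is ActionLabel.WALK:
        if n_strides is None:
            n_strides = int(rng.integers(3, 5))
        if n_strides not in (3, 4):
            raise ParameterError("a walk comprises 3 or 4 strides")
        stride_rate = 0.9  # Hz
        speed = 0.5  # m/s
        n = int(round(n_strides / stride_rate * rate))
        tt = np.arange(n) / rate
        # quarter-cycle offset keeps ankle zero crossings interior to the clip
        phase = 2 * np.pi * stride_rate * tt + np.pi / 2
        pos = _pose_frames(
            h,
            _ARM_MIN + 0.15 * (1 + np.sin(phase)) / 2,
            _ARM_MIN + 0.15 * (1 - np.sin(phase)) / 2,
            zeros(n),
            zeros(n),
        )
        pos[:, :, 2] += (speed * tt)[:, None]
        # alternating anterior leg swing about the advancing pelvis
        sw = 0.22 * np.sin(phase)
        for jn in (J.KneeLeft, J.AnkleLeft, J.FootLeft):
            pos[:, jn, 2] += sw
        for jn in (J.KneeRight, J.AnkleRight, J.FootRight):
            pos[:, jn, 2] -= sw
        targets = {"label": label.value, "n_strides": n_strides,
                   "stride_rate": stride_rate}
    elif label is ActionLabel.TOUCH_NOSE:
        n = int(round(2.0 * rate))
        tt = np.arange(n) / rate
        u = tt / tt[-1]
        reach = np.sin(np.pi * u) ** 2  # 0 → 1 → 0
        pos = _pose_frames(
            h, const(n, _ARM_MIN), const(n, _ARM_MIN), zeros(n), zeros(n)
        )
        head = pos[0, J.Head].copy()
        nose = head + np.array([0.0, -0.02 * h, 0.05 * h])
        for jn, frac in (
            (J.ElbowRight, 0.45),
            (J.WristRight, 0.92),
            (J.HandRight, 1.0),
            (J.HandTipRight, 1.05),
            (J.ThumbRight, 0.98),
        ):
            rest = pos[0, jn].copy()
            target = rest + frac * (nose - pos[0, J.HandRight])
            pos[:, jn] = rest + reach[:, None] * (target - rest)[None, :]
        targets = {"label": label.value}
    else:  # pragma: no cover - exhaustive enum
        raise ParameterError(f"unknown label {label!r}")

    n = pos.shape[0]
    truth = GroundTruth(
        segments=[Segment(label, 0, n)], targets=[targets]
    )
    return _finish(pos, rate, profile, rng), truth


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

#: one exemplar of every scripted move, jumping jack first
DEFAULT_SESSION_SCRIPT: tuple[ActionLabel, ...] = tuple(ActionLabel)


def generate_session(
    script: Sequence[ActionLabel | str],
    profile: ParticipantProfile,
    rate: float = 30.0,
    transition_frames: int = 15,
    jj_cycles: int = 3,
) -> tuple[MotionSequence, GroundTruth]:
    """Concatenate scripted action clips with short idle transitions.

    Ground-truth segments cover the action clips (transitions are unlabeled);
    the same profile/seed always produces the identical sequence.
    """
    if not script:
        raise ParameterError("empty session script")
    rng = np.random.default_rng(profile.seed)
    clips: list[np.ndarray] = []
    truth = GroundTruth()
    cursor = 0
    trans_pose = None
    for i, raw in enumerate(script):
        label = ActionLabel(raw)
        if label is ActionLabel.JUMPING_JACK:
            seq, gt = generate_jumping_jack(
                profile, n_cycles=jj_cycles, rate=rate, rng=rng
            )
        else:
            seq, gt = generate_action(label, profile, rate=rate, rng=rng)
        n = seq.n_frames
        clips.append(seq.positions)
        truth.segments.append(Segment(label, cursor, cursor + n))
        truth.targets.append(gt.targets[0])
        cursor += n
        if i < len(script) - 1 and transition_frames > 0:
            # hold the last pose briefly between moves
            hold = np.repeat(
                seq.positions[-1][None, :, :], transition_frames, axis=0
            )
            clips.append(hold)
            cursor += transition_frames
    pos = np.concatenate(clips, axis=0)
    ts = np.arange(pos.shape[0]) / rate
    seq = MotionSequence(ts, pos, nominal_rate=rate)
    truth.validate(seq.n_frames)
    return seq, truth
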