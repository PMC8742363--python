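"""Sliding-window action recognition, segment assembly, and dataset augmentation.

A continuous skeleton stream is scanned with a 60-frame window advanced every
15 frames (0.5 s at 30 Hz).  Each window is classified into one of 10 scripted
action labels; maximal runs of equal labels become :class:`Segment` objects
that downstream metric computation consumes.

The reference recognizer is a deterministic nearest-template classifier:
per label, a centroid feature trajectory is fitted from labeled exemplars
(pelvis-centered, height-normalized, uniformly resampled to the window
length), and windows are scored by dynamic-time-warping (DTW) distance.
A recurrent-network recognizer with the same window contract can be slotted
in via :func:`recurrent_recognizer_spec`, which declares the architecture;
training such a network is deliberately out of scope here.

Augmentation doubles a clip set by sagittal mirroring (left/right swap) and
then expands each clip into six time-warped variants, the two-step scheme
that turns 2 000 raw clips into 24 000 training samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ParameterError,
    StateError,
    TrainingError,
    ValidationError,
)
from .skeleton import (
    CONTRALATERAL,
    JointId,
    MotionSequence,
    N_JOINTS,
    center_pelvis,
    estimate_height,
)

__all__ = [
    "ActionLabel",
    "Segment",
    "Window",
    "TemplateModel",
    "featurize",
    "sliding_windows",
    "fit_templates",
    "recognize_stream",
    "apply_manual_corrections",
    "mirror_flip",
    "time_warp",
    "augment_dataset",
    "recurrent_recognizer_spec",
    "DEFAULT_WARP_FACTORS",
    "WINDOW_LENGTH",
    "WINDOW_HOP",
]

WINDOW_LENGTH = 60
WINDOW_HOP = 15

#: the six speed factors of the second augmentation step (±5/10/15 %)
DEFAULT_WARP_FACTORS = (0.85, 0.90, 0.95, 1.05, 1.10, 1.15)


class ActionLabel(str, Enum):
    """The 10 scripted action labels."""

    JUMPING_JACK = "jumping jack"
    JUMP_FORWARD = "jump forward"
    JUMP_BACKWARD = "jump backward"
    JUMP_RIGHT = "jump right"
    JUMP_LEFT = "jump left"
    WALK = "walk"
    STEP_FORWARD = "step forward"
    STEP_BACK = "step back"
    TOUCH_NOSE = "touch nose"
    IDLE = "idle"


@dataclass
class Segment:
    """A half-open, 0-based frame interval carrying one action label."""

    label: ActionLabel
    start_frame: int
    end_frame: int
    source: str = "auto"  # {auto, manual}

    def __post_init__(self) -> None:
        self.label = ActionLabel(self.label)
        if not (0 <= self.start_frame < self.end_frame):
            raise ValidationError(
                f"bad segment bounds [{self.start_frame}, {self.end_frame})"
            )
        if self.source not in ("auto", "manual"):
            raise ValidationError(f"bad segment source {self.source!r}")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class Window:
    """One recognizer input: ``length`` consecutive frames of features."""

    start: int
    features: np.ndarray  # (length, F)

    @property
    def length(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def featurize(
    seq: MotionSequence,
    joints: Sequence[JointId] | None = None,
    height: float | None = None,
) -> np.ndarray:
    """Per-frame feature matrix: pelvis-centered, height-normalized
    coordinates plus the pelvis trajectory.

    The default feature set is all 25 joints × 3 coordinates relative to
    the per-frame pelvis (75 per frame, invariant to where the participant
    stands) followed by 3 columns of pelvis frame-to-frame displacement
    (scaled by ``PELVIS_VEL_GAIN``).  Per-frame centering alone would erase
    whole-body translation — the very thing that distinguishes a jump
    forward from a jump left from quiet standing — so the displacement
    block restores it in a local, translation-invariant form.
    """
    centered = center_pelvis(seq)
    if height is None:
        height = estimate_height(seq).height
    pos = centered.positions / height
    if joints is not None:
        pos = pos[:, [int(j) for j in joints], :]
    rel = pos.reshape(seq.n_frames, -1)
    pelvis = seq.positions[:, int(JointId.SpineBase), :] / height
    delta = np.vstack([np.zeros((1, 3)), np.diff(pelvis, axis=0)])
    feats = np.concatenate([rel, PELVIS_VEL_GAIN * delta], axis=1)
    return np.nan_to_num(feats, nan=0.0)


#: balances the pelvis-displacement block (≈0.01 h/frame during locomotion)
#: against the limb-coordinate block (≈0.1–0.3 h excursions)
PELVIS_VEL_GAIN = 20.0


def sliding_windows(
    seq: MotionSequence,
    length: int = WINDOW_LENGTH,
    hop: int = WINDOW_HOP,
    joints: Sequence[JointId] | None = None,
) -> list[Window]:
    """Cut a stream into windows starting at 0, hop, 2·hop, ...

    The number of windows is ``floor((N - length)/hop) + 1`` for streams of
    at least ``length`` frames, otherwise 0.
    """
    if length <= 0 or hop <= 0:
        raise ParameterError("length and hop must be positive")
    n = seq.n_frames
    if n < length:
        return []
    feats = featurize(seq, joints=joints)
    starts = range(0, n - length + 1, hop)
    return [Window(s, feats[s : s + length]) for s in starts]


# ---------------------------------------------------------------------------
# Template model
# ---------------------------------------------------------------------------


def _resample_rows(mat: np.ndarray, n_rows: int) -> np.ndarray:
    """Linear resampling of a (m, F) trajectory to n_rows rows."""
    m = mat.shape[0]
    if m == n_rows:
        return mat.copy()
    src = np.linspace(0.0, 1.0, m)
    dst = np.linspace(0.0, 1.0, n_rows)
    out = np.empty((n_rows, mat.shape[1]))
    for k in range(mat.shape[1]):
        out[:, k] = np.interp(dst, src, mat[:, k])
    return out


@dataclass
class TemplateModel:
    """Per-label centroid feature trajectories for nearest-template matching."""

    templates: dict[ActionLabel, np.ndarray]
    length: int = WINDOW_LENGTH
    joints: tuple[int, ...] | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "length": self.length,
            "joints": list(self.joints) if self.joints is not None else None,
            "templates": {
                lbl.value: tpl.tolist() for lbl, tpl in self.templates.items()
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "TemplateModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            templates={
                ActionLabel(k): np.asarray(v)
                for k, v in obj["templates"].items()
            },
            length=obj["length"],
            joints=tuple(obj["joints"]) if obj["joints"] is not None else None,
        )


def fit_templates(
    labeled: Iterable[tuple[MotionSequence, "SegmentsLike"]],
    length: int = WINDOW_LENGTH,
    joints: Sequence[JointId] | None = None,
    labels: Sequence[ActionLabel] | None = None,
) -> TemplateModel:
    """Fit one centroid trajectory per label from labeled exemplar clips.

    ``labeled`` pairs a sequence with its ground-truth/annotation object,
    anything exposing ``.segments`` as a list of :class:`Segment`.  Every
    exemplar is featurized, uniformly resampled to ``length`` rows, and
    averaged per label.  ``labels`` restricts the coverage the model must
    provide (default: all ten actions); exemplars of other labels still
    contribute templates when present.
    """
    required = tuple(labels) if labels is not None else tuple(ActionLabel)
    by_label: dict[ActionLabel, list[np.ndarray]] = {}
    for seq, truth in labeled:
        feats = featurize(seq, joints=joints)
        for seg in truth.segments:
            clip = feats[seg.start_frame : seg.end_frame]
            if clip.shape[0] < 2:
                continue
            by_label.setdefault(seg.label, []).append(
                _resample_rows(clip, length)
            )
    missing = [lbl.value for lbl in required if lbl not in by_label]
    if missing:
        raise TrainingError(f"no exemplars for labels: {missing}")
    templates = {
        lbl: np.mean(np.stack(clips), axis=0) for lbl, clips in by_label.items()
    }
    return TemplateModel(
        templates,
        length=length,
        joints=tuple(int(j) for j in joints) if joints is not None else None,
    )


# ---------------------------------------------------------------------------
# DTW scoring and stream recognition
# ---------------------------------------------------------------------------


def dtw_distance(
    a: np.ndarray,
    b: np.ndarray,
    subsequence: bool = False,
    coverage_penalty: float = 0.05,
) -> float:
    """Dynamic-time-warping distance between two (n, F) feature
    trajectories with euclidean local cost.

    With ``subsequence=True`` the start and end are free along the second
    (template) axis, so a query may align to any contiguous portion of the
    template — a 2 s window of a longer action matches the corresponding
    stretch of its whole-action template instead of being forced across
    all of it.  ``coverage_penalty`` is added per unmatched template
    fraction, discouraging trivial matches to a tiny template prefix (a
    near-static window would otherwise match the resting first frames of
    every action template equally well).  The accumulated cost is
    normalized by the query length (subsequence mode) or the alignment
    path length (plain mode).
    """
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    n, m = cost.shape
    if not subsequence:
        acc = np.full((n, m), np.inf)
        acc[0, :] = np.cumsum(cost[0, :])
        for i in range(1, n):
            prev = acc[i - 1]
            row = acc[i]
            ci = cost[i]
            row[0] = prev[0] + ci[0]
            for j in range(1, m):
                row[j] = ci[j] + min(prev[j], row[j - 1], prev[j - 1])
        return float(acc[n - 1, m - 1]) / (n + m)
    acc = cost[0, :].copy()
    start = np.arange(m)
    for i in range(1, n):
        ci = cost[i]
        new = np.empty(m)
        new_start = np.empty(m, dtype=int)
        new[0] = acc[0] + ci[0]
        new_start[0] = start[0]
        for j in range(1, m):
            up, left, diag = acc[j], new[j - 1], acc[j - 1]
            if diag <= up and diag <= left:
                new[j] = ci[j] + diag
                new_start[j] = start[j - 1]
            elif up <= left:
                new[j] = ci[j] + up
                new_start[j] = start[j]
            else:
                new[j] = ci[j] + left
                new_start[j] = new_start[j - 1]
        acc, start = new, new_start
    coverage = (np.arange(m) - start + 1) / m
    scores = acc / n + coverage_penalty * (1.0 - coverage)
    return float(np.min(scores))


def classify_window(window: Window, model: TemplateModel) -> ActionLabel:
    """Nearest template by subsequence-DTW distance; deterministic
    tie-break by label order."""
    if not model.templates:
        raise StateError("empty template model")
    best_lbl, best_d = None, np.inf
    for lbl in ActionLabel:
        tpl = model.templates.get(lbl)
        if tpl is None:
            continue
        d = dtw_distance(window.features, tpl, subsequence=True)
        if d < best_d:
            best_lbl, best_d = lbl, d
    return best_lbl


def recognize_stream(
    seq: MotionSequence,
    model: TemplateModel,
    length: int = WINDOW_LENGTH,
    hop: int = WINDOW_HOP,
    smoothing: str | None = None,
    refine_boundaries: bool = True,
) -> list[Segment]:
    """Classify every window and merge runs of equal labels into segments.

    Label changes are attributed to the trailing hop of the first window of
    each new run — in the streaming setting a window's label describes the
    action recognized once its newest ``hop`` frames have arrived — so the
    boundary between consecutive segments falls at ``start + length − hop``
    of the run's first window.  The first segment extends back to frame 0
    and the last to the end of the stream, yielding a contiguous
    segmentation.  ``smoothing='majority3'`` optionally replaces each
    window label by the majority of itself and its two neighbours before
    merging.
    """
    joints = (
        [JointId(j) for j in model.joints] if model.joints is not None else None
    )
    windows = sliding_windows(seq, length=length, hop=hop, joints=joints)
    if not windows:
        return []
    labels = [classify_window(w, model) for w in windows]
    if smoothing == "majority3":
        labels = _majority3(labels)
    elif smoothing is not None:
        raise ParameterError(f"unknown smoothing {smoothing!r}")
    run_first = [0] + [
        i for i in range(1, len(labels)) if labels[i] != labels[i - 1]
    ]
    boundaries = [0] + [
        windows[i].start + length - hop for i in run_first[1:]
    ] + [seq.n_frames]
    if refine_boundaries and len(run_first) > 1:
        feats = featurize(seq, joints=joints)
        for k in range(1, len(run_first)):
            tpl_a = model.templates[labels[run_first[k - 1]]]
            tpl_b = model.templates[labels[run_first[k]]]
            boundaries[k] = _refine_boundary(
                feats, boundaries[k], tpl_a, tpl_b, hop, length,
                lo=boundaries[k - 1] + 1, hi=boundaries[k + 1] - 1,
            )
    return [
        Segment(labels[i], boundaries[k], boundaries[k + 1])
        for k, i in enumerate(run_first)
        if boundaries[k + 1] > boundaries[k]
    ]


def _refine_boundary(
    feats: np.ndarray,
    provisional: int,
    tpl_a: np.ndarray,
    tpl_b: np.ndarray,
    hop: int,
    length: int,
    lo: int,
    hi: int,
) -> int:
    """Sharpen a label-change boundary to sub-window resolution.

    Short (hop-length) feature blocks around the provisional boundary are
    scored against the two adjacent templates; the boundary moves to the
    end of the last block still explained better by the outgoing template.
    The window label itself is eager — a window containing any stretch of
    an active movement tends to adopt its label — so the provisional
    window-level boundary can sit almost a full window away from the
    actual transition.
    """
    n = feats.shape[0]
    start0 = max(lo, provisional - length)
    starts = list(range(start0, min(provisional + hop, hi, n - hop) + 1, hop))
    if not starts:
        return provisional
    last_a_end = None
    for c in starts:
        block = feats[c : c + hop]
        if block.shape[0] < 2:
            continue
        da = dtw_distance(block, tpl_a, subsequence=True)
        db = dtw_distance(block, tpl_b, subsequence=True)
        if da < db:
            last_a_end = c + hop
    if last_a_end is None:
        refined = starts[0]
    else:
        refined = last_a_end
    return int(np.clip(refined, lo, hi))


def _majority3(labels: list[ActionLabel]) -> list[ActionLabel]:
    out = list(labels)
    for i in range(1, len(labels) - 1):
        trio = labels[i - 1 : i + 2]
        for cand in trio:
            if trio.count(cand) >= 2:
                out[i] = cand
                break
    return out


def window_accuracy(
    seq: MotionSequence,
    truth_segments: Sequence[Segment],
    model: TemplateModel,
    length: int = WINDOW_LENGTH,
    hop: int = WINDOW_HOP,
) -> float:
    """Per-window accuracy against ground-truth segments.

    A window's true label is the label covering the majority of its frames
    (ties broken by earlier segment).  Windows not covered by any ground
    truth are skipped.
    """
    joints = (
        [JointId(j) for j in model.joints] if model.joints is not None else None
    )
    windows = sliding_windows(seq, length=length, hop=hop, joints=joints)
    n_ok = n_tot = 0
    for w in windows:
        cover: dict[ActionLabel, int] = {}
        for seg in truth_segments:
            ov = min(seg.end_frame, w.start + length) - max(
                seg.start_frame, w.start
            )
            if ov > 0:
                cover[seg.label] = cover.get(seg.label, 0) + ov
        if not cover:
            continue
        true_lbl = max(cover, key=cover.get)
        n_tot += 1
        if classify_window(w, model) == true_lbl:
            n_ok += 1
    if n_tot == 0:
        raise ValidationError("no window overlaps the ground truth")
    return n_ok / n_tot


# ---------------------------------------------------------------------------
# Manual corrections
# ---------------------------------------------------------------------------


def apply_manual_corrections(
    segments: Sequence[Segment], edits: Sequence[dict]
) -> list[Segment]:
    """Apply reviewer edits to an automatic segmentation.

    Each edit is a dict with ``op`` in {``update``, ``delete``, ``insert``}:

    * ``update``: ``index`` plus any of ``label``/``start_frame``/``end_frame``;
    * ``delete``: ``index``;
    * ``insert``: ``label``, ``start_frame``, ``end_frame``.

    Edited/inserted segments are marked ``source='manual'``.  The resulting
    list is re-sorted and validated for overlaps.
    """
    result: list[Segment | None] = [replace(s) for s in segments]
    for edit in edits:
        op = edit.get("op")
        if op == "update":
            idx = edit["index"]
            if result[idx] is None:
                raise ValidationError(f"segment {idx} was deleted")
            seg = result[idx]
            result[idx] = Segment(
                label=ActionLabel(edit.get("label", seg.label)),
                start_frame=edit.get("start_frame", seg.start_frame),
                end_frame=edit.get("end_frame", seg.end_frame),
                source="manual",
            )
        elif op == "delete":
            idx = edit["index"]
            if result[idx] is None:
                raise ValidationError(f"segment {idx} already deleted")
            result[idx] = None
        elif op == "insert":
            result.append(
                Segment(
                    label=ActionLabel(edit["label"]),
                    start_frame=edit["start_frame"],
                    end_frame=edit["end_frame"],
                    source="manual",
                )
            )
        else:
            raise ValidationError(f"unknown edit op {op!r}")
    final = sorted(
        (s for s in result if s is not None), key=lambda s: s.start_frame
    )
    for a, b in zip(final, final[1:]):
        if b.start_frame < a.end_frame:
            raise ValidationError(
                f"segments overlap: [{a.start_frame},{a.end_frame}) and "
                f"[{b.start_frame},{b.end_frame})"
            )
    return final


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

_MIRROR_PERM = np.array(
    [int(CONTRALATERAL[j]) for j in JointId], dtype=int
)


def mirror_flip(seq: MotionSequence) -> MotionSequence:
    """Sagittal-plane mirror: negate lateral (x) coordinates and swap the
    left/right joint roles, yielding an anatomically valid mirrored motion.

    An involution: applying it twice returns the original sequence.
    """
    out = seq.copy()
    out.positions = out.positions[:, _MIRROR_PERM, :]
    out.positions[:, :, 0] *= -1.0
    out.validity = out.validity[:, _MIRROR_PERM]
    return out


def time_warp(seq: MotionSequence, speed_factor: float) -> MotionSequence:
    """Replay a clip ``speed_factor`` times faster, resampled back to the
    nominal frame grid by linear interpolation.

    Duration scales by ``1/speed_factor``: a 300-frame clip at factor 1.2
    becomes 250 frames.
    """
    if not (0 < speed_factor <= 2):
        raise ParameterError(f"speed_factor must be in (0, 2], got {speed_factor}")
    if speed_factor == 1.0:
        return seq.copy()
    n = seq.n_frames
    if n < 2:
        return seq.copy()
    dt = 1.0 / seq.nominal_rate
    t0 = seq.timestamps[0]
    rel = seq.timestamps - t0
    span = rel[-1]
    n_new = int(np.floor(span / speed_factor / dt)) + 1
    # positions are sampled from the original timeline at speeded-up times
    src_t = np.arange(n_new) * dt * speed_factor
    flat = seq.positions.reshape(n, -1)
    new_flat = np.empty((n_new, flat.shape[1]))
    for k in range(flat.shape[1]):
        new_flat[:, k] = np.interp(src_t, rel, flat[:, k])
    nearest = np.clip(np.searchsorted(rel, src_t), 0, n - 1)
    out = seq.copy()
    out.timestamps = t0 + np.arange(n_new) * dt
    out.positions = new_flat.reshape(n_new, N_JOINTS, 3)
    out.validity = seq.validity[nearest]
    return out


def augment_dataset(
    samples: Sequence[MotionSequence],
    warp_factors: Sequence[float] = DEFAULT_WARP_FACTORS,
    allow_any_factors: bool = False,
) -> list[MotionSequence]:
    """Two-step augmentation: mirror doubling, then 6-way time warping.

    Step 1 appends the sagittal mirror of every clip (|samples| → 2×).
    Step 2 replaces each clip of the doubled set with one time-warped copy
    per factor (2× → 12×).  With the canonical six factors, 2 000 raw clips
    become 24 000 augmented clips.
    """
    if not samples:
        raise ParameterError("empty sample list")
    if len(warp_factors) != 6 and not allow_any_factors:
        raise ParameterError(
            f"expected 6 warp factors, got {len(warp_factors)} "
            "(pass allow_any_factors=True to override)"
        )
    step1 = list(samples) + [mirror_flip(s) for s in samples]
    return [time_warp(s, f) for s in step1 for f in warp_factors]


# ---------------------------------------------------------------------------
# Optional recurrent recognizer (declarative description only)
# ---------------------------------------------------------------------------


def recurrent_recognizer_spec(per_frame_features: int = 52) -> dict:
    """Declarative description of the recurrent-network recognizer.

    Returns the architecture and training protocol of the LSTM classifier
    that can replace the template recognizer: a 60 × ``per_frame_features``
    input window, three LSTM layers of 20 units, and a 10-way softmax
    output.  Training uses a 20 % held-out split with early stopping after
    50 epochs without test-accuracy improvement.
    """
    if per_frame_features <= 0:
        raise ParameterError("per_frame_features must be positive")
    return {
        "input_shape": (WINDOW_LENGTH, per_frame_features),
        "layers": [
            {"type": "lstm", "units": 20},
            {"type": "lstm", "units": 20},
            {"type": "lstm", "units": 20},
            {"type": "softmax", "units": len(ActionLabel)},
        ],
        "training": {
            "test_fraction": 0.20,
            "early_stopping_patience_epochs": 50,
            "selection": "highest validation accuracy",
        },
    }


class SegmentsLike:  # pragma: no cover - typing helper
    segments: list[Segment]
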