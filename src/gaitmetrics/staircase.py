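"""Adaptive difficulty control: transformed 3-down/1-up staircase simulation.

The intervention adapts movement difficulty across 5 levels so that the
player keeps succeeding on roughly 75–85 % of trials.  A transformed
3-down/1-up rule is used here: three consecutive correct responses raise
the level by one, any incorrect response lowers it by one, clamped to the
level range.  Its analytic convergence point is the success probability p
with p³ = 1/2, i.e. p ≈ 0.794 — centrally inside the 75–85 % band — which
is why this staircase family is the natural fit for that target.

A :class:`ResponderModel` plays the virtual participant: a monotone
non-increasing psychometric function mapping level to probability correct,
by default a logistic interpolation between an easy floor and a hard
ceiling that brackets the convergence point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "StaircaseState",
    "ResponderModel",
    "update_staircase",
    "simulate_loop",
    "CONVERGENCE_P",
]

#: analytic convergence probability of a 3-down/1-up rule: p = 2^(-1/3)
CONVERGENCE_P = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class StaircaseState:
    """Current level, the consecutive-correct counter and the trial history."""

    level: int = 1
    n_levels: int = 5
    correct_streak: int = 0
    history: tuple[tuple[int, bool], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (1 <= self.level <= self.n_levels):
            raise ParameterError(
                f"level {self.level} outside 1..{self.n_levels}"
            )


def update_staircase(
    state: StaircaseState, correct: bool, n_up: int = 3
) -> StaircaseState:
    """One trial of the transformed n_up-down/1-up rule (default 3-down/1-up).

    ``n_up`` consecutive correct responses raise the level (and reset the
    counter); any incorrect response lowers it.  The level is clamped to
    1..n_levels.  History is append-only.
    """
    history = state.history + ((state.level, bool(correct)),)
    if correct:
        streak = state.correct_streak + 1
        if streak >= n_up:
            return replace(
                state,
                level=min(state.level + 1, state.n_levels),
                correct_streak=0,
                history=history,
            )
        return replace(state, correct_streak=streak, history=history)
    return replace(
        state,
        level=max(state.level - 1, 1),
        correct_streak=0,
        history=history,
    )


@dataclass(frozen=True)
class ResponderModel:
    """Virtual participant: probability of a correct trial per level."""

    p_by_level: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.p_by_level)
        if np.any((p < 0) | (p > 1)):
            raise ParameterError("probabilities must lie in [0, 1]")
        if np.any(np.diff(p) > 1e-12):
            raise ParameterError(
                "psychometric function must be non-increasing in level"
            )

    @classmethod
    def logistic(
        cls, p_easy: float = 0.95, p_hard: float = 0.45, n_levels: int = 5
    ) -> "ResponderModel":
        """Logit-linear interpolation from ``p_easy`` (level 1) down to
        ``p_hard`` (top level)."""
        if not (0 < p_hard < p_easy < 1):
            raise ParameterError("need 0 < p_hard < p_easy < 1")
        logit = lambda p: np.log(p / (1.0 - p))
        levels = np.arange(n_levels)
        z = logit(p_easy) + (logit(p_hard) - logit(p_easy)) * levels / (
            n_levels - 1
        )
        return cls(tuple(1.0 / (1.0 + np.exp(-z))))

    def p_correct(self, level: int) -> float:
        return self.p_by_level[level - 1]


def simulate_loop(
    responder: ResponderModel,
    n_trials: int,
    seed: int,
    n_up: int = 3,
    state: StaircaseState | None = None,
) -> tuple[float, np.ndarray]:
    """Closed-loop simulation of the staircase driving a responder.

    Returns the proportion correct over the final half of the trials (the
    steady-state performance band, discarding the approach transient) and
    the per-trial level trace.  Fully reproducible per seed.
    """
    if n_trials < 100:
        raise ParameterError("n_trials must be >= 100")
    rng = np.random.default_rng(seed)
    if state is None:
        state = StaircaseState(n_levels=len(responder.p_by_level))
    trace = np.empty(n_trials, dtype=int)
    correct = np.empty(n_trials, dtype=bool)
    for i in range(n_trials):
        trace[i] = state.level
        ok = rng.random() < responder.p_correct(state.level)
        correct[i] = ok
        state = update_staircase(state, ok, n_up=n_up)
    tail = correct[n_trials // 2 :]
    return float(np.mean(tail)), trace
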