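"""2-up-1-down adaptive difficulty procedure for hard problems.

The level rises after two successive correct answers (capped at 7) and
falls after a single error (floored at 2).  The rule equilibrates where
p(step up) = p(step down), i.e. p^2 = 1/2, giving an asymptotic accuracy
of sqrt(1/2) ~ 70.7%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

START_LEVEL = 4
MIN_HARD_LEVEL = 2
MAX_HARD_LEVEL = 7


@dataclass
class StaircaseState:
    level: int
    streak: int
    min_level: int
    max_level: int
    history: list = field(default_factory=list)  # ordered (level, correct) pairs

    def __post_init__(self):
        if not self.min_level <= self.level <= self.max_level:
            raise InvalidArgumentError(
                f"level {self.level} outside [{self.min_level}, {self.max_level}]"
            )
        if self.streak not in (0, 1):
            raise InvalidArgumentError(f"streak must be 0 or 1, got {self.streak}")


def init_staircase(
    start_level: int = START_LEVEL,
    min_level: int = MIN_HARD_LEVEL,
    max_level: int = MAX_HARD_LEVEL,
) -> StaircaseState:
    """Fresh staircase: level 4, empty history, bounds [2, 7]."""
    return StaircaseState(level=start_level, streak=0, min_level=min_level, max_level=max_level)


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one hard-solve outcome; returns a new state, input untouched.

    A level change (up or down) resets the streak.
    """
    history = list(state.history)
    history.append((state.level, bool(correct)))
    if correct:
        if state.streak == 1:
            level = min(state.level + 1, state.max_level)
            streak = 0
        else:
            level = state.level
            streak = 1
    else:
        level = max(state.level - 1, state.min_level)
        streak = 0
    return StaircaseState(level, streak, state.min_level, state.max_level, history)


def convergence_accuracy(rule: str) -> float:
    """Theoretical asymptotic proportion correct at the staircase equilibrium.

    For n-up-1-down the equilibrium solves p^n = 1/2.
    """
    if rule in ("2up1down", "2-up-1-down"):
        return math.sqrt(0.5)
    if rule in ("1up1down", "1-up-1-down"):
        return 0.5
    raise NotImplementedError(f"unsupported staircase rule {rule!r}")


def run_staircase(p_correct_by_level, n_trials: int, rng, state: StaircaseState | None = None) -> StaircaseState:
    """Simulate ``n_trials`` consecutive hard solves under the staircase.

    ``p_correct_by_level`` maps a level to the agent's probability of
    answering correctly at that level.  Used for calibration checks and
    the long-run convergence oracle.
    """
    if state is None:
        state = init_staircase()
    for _ in range(n_trials):
        correct = rng.random() < p_correct_by_level(state.level)
        state = update(state, correct)
    return state


def observed_accuracy(state: StaircaseState) -> float:
    """Proportion correct over the recorded history."""
    if not state.history:
        raise InvalidArgumentError("empty staircase history")
    return sum(c for _, c in state.history) / len(state.history)
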