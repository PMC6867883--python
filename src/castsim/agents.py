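"""Generative model of a simulated participant.

Three pieces: a psychometric solving model (3-alternative logistic with a
guessing floor of 1/3 and a lapse ceiling), an effort-cost choice model in
which math effort cost scales with math anxiety, and log-normal response
time sampling with a fast-guessing mode that kicks in once the subjective
cost of a hard problem exceeds a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidArgumentError
from .problems import latent_difficulty_of_level

CHANCE = 1.0 / 3.0  # three-alternative guessing floor


@dataclass
class RTParams:
    """Log-normal location/scale for choose- and solve-phase RTs (seconds)."""

    choose_median: float = 1.2
    choose_sigma: float = 0.30
    solve_median: float = 3.5
    solve_sigma: float = 0.40
    #: multiplier on the solve median under the fast-guessing policy
    guess_speedup: float = 0.45


@dataclass
class AgentParams:
    """A simulated participant. Trait scores plus behavioural parameters.

    Costs are in reward units (cents) so subjective-value comparisons are
    dimensionally coherent; effort is linear in difficulty level.
    """

    math_anxiety: float = 1.0      # 1..5
    reading_anxiety: float = 1.0   # 1..5
    trait_anxiety: float = 20.0    # 20..80
    test_anxiety: float = 20.0     # 20..80
    competence_math: float = 4.0   # psychometric location (latent-difficulty units)
    competence_word: float = 4.0
    psychometric_slope: float = 1.0
    lapse: float = 0.02            # in [0, 0.1]
    cost_base_math: float = 0.0    # cents per effort unit
    cost_base_word: float = 0.0
    anxiety_cost_slope: float = 0.0  # extra math cents per effort unit per anxiety unit
    choice_temperature: float = 0.5
    perceived_acc_easy: float = 0.95
    perceived_acc_hard: float = 0.70
    guess_threshold: float = math.inf  # subjective cost above which hard answers are guessed
    choice_timeout_prob: float = 0.01
    rt_params: RTParams = field(default_factory=RTParams)

    def __post_init__(self):
        if not 0.0 <= self.lapse <= 0.1:
            raise InvalidArgumentError(f"lapse {self.lapse} outside [0, 0.1]")
        if self.choice_temperature <= 0:
            raise InvalidArgumentError("choice_temperature must be > 0")
        if self.psychometric_slope <= 0:
            raise InvalidArgumentError("psychometric_slope must be > 0")
        for name in ("perceived_acc_easy", "perceived_acc_hard", "choice_timeout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name}={v} outside [0, 1]")
        if min(self.cost_base_math, self.cost_base_word) < 0:
            raise InvalidArgumentError("cost bases must be >= 0")


def effort(level: int) -> float:
    """Effort of engaging a problem; linear in its difficulty level."""
    return float(level)


def subjective_cost(agent: AgentParams, domain: str, level: int) -> float:
    """Effort cost in cents; math cost grows with math anxiety."""
    if domain == "math":
        per_unit = agent.cost_base_math + agent.anxiety_cost_slope * (agent.math_anxiety - 1.0)
    else:
        per_unit = agent.cost_base_word
    return per_unit * effort(level)


def accuracy_from_latent(agent: AgentParams, domain: str, latent: float) -> float:
    """P(correct) for an item with the given latent difficulty."""
    competence = agent.competence_math if domain == "math" else agent.competence_word
    z = agent.psychometric_slope * (competence - latent)
    p_know = 1.0 / (1.0 + math.exp(-z))
    return CHANCE + (1.0 - CHANCE - agent.lapse) * p_know


def solve_accuracy(agent: AgentParams, domain: str, level: int) -> float:
    """P(correct) at a difficulty level; decreasing in level, floor 1/3, ceiling 1 - lapse."""
    if not 1 <= level <= 7:
        raise InvalidArgumentError(f"level {level} outside [1, 7]")
    return accuracy_from_latent(agent, domain, latent_difficulty_of_level(level))


def is_guessing(agent: AgentParams, domain: str, level: int) -> bool:
    """Whether the agent answers a hard problem by fast guessing."""
    return subjective_cost(agent, domain, level) > agent.guess_threshold


def hard_choice_probability(agent: AgentParams, offer, current_level: int) -> float:
    """Deterministic P(choose hard | not a timeout) for a two-card offer.

    SV_easy = perceived_acc_easy * easy_reward - cost(level 1)
    SV_hard = perceived_acc_hard * hard_reward - cost(current hard level)
    sampled through a logistic with the agent's choice temperature.
    """
    sv_easy = agent.perceived_acc_easy * offer.easy_reward - subjective_cost(agent, offer.domain, 1)
    sv_hard = agent.perceived_acc_hard * offer.hard_reward - subjective_cost(
        agent, offer.domain, current_level
    )
    z = (sv_hard - sv_easy) / agent.choice_temperature
    if z > 35:
        return 1.0
    if z < -35:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


def choose(agent: AgentParams, offer, current_level: int, rng) -> str:
    """Resolve a two-card offer: 'easy', 'hard', or 'timeout'."""
    if offer.is_no_choice:
        raise InvalidArgumentError("no-choice offers bypass the choose op")
    if rng.random() < agent.choice_timeout_prob:
        return "timeout"
    return "hard" if rng.random() < hard_choice_probability(agent, offer, current_level) else "easy"


def _raw_rt(median: float, sigma: float, rng) -> float:
    return median * math.exp(sigma * rng.gauss(0.0, 1.0))


def raw_solve_rt(agent: AgentParams, domain: str, level: int, rng) -> float:
    """Unclipped solve RT; may exceed the limit (=> solve timeout)."""
    p = agent.rt_params
    median = p.solve_median
    if is_guessing(agent, domain, level):
        median *= p.guess_speedup
    return _raw_rt(median, p.solve_sigma, rng)


def sample_rt(
    agent: AgentParams,
    phase: str,
    domain: str,
    level: int,
    rng,
    lockout: float = 1.5,
    limit: float = 7.0,
    choose_limit: float = 3.0,
) -> float:
    """Sample one response time, clipped to the phase's legal window."""
    p = agent.rt_params
    if phase == "choose":
        return min(_raw_rt(p.choose_median, p.choose_sigma, rng), choose_limit)
    if phase == "solve":
        return min(max(raw_solve_rt(agent, domain, level, rng), lockout), limit)
    raise InvalidArgumentError(f"unknown phase {phase!r}")
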