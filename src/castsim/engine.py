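"""Session engine: schedule trials, resolve choices and solves, emit records.

Timing rules: 3 s to choose (timeout reroutes to a 1-cent easy problem),
7 s to solve, responses locked out for the first 1.5 s of the solve phase.
Easy problems are always level 1; hard-problem difficulty follows a
per-domain 2-up-1-down staircase persisting from the practice warm-up.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import agents as ag
from . import staircase as sc
from .errors import InvalidArgumentError
from .problems import LATENT_SD, BankSampler, ProblemBank, latent_difficulty_of_level

HARD_REWARDS = (2, 3, 4, 5, 6)
STUDIES = ("study1", "study1R", "study2")


@dataclass(frozen=True)
class SessionDesign:
    study: str
    blocks: int
    choice_trials_per_domain: int       # per block, per domain
    no_choice_easy_per_domain: int = 0  # per block, per domain
    no_choice_hard_per_domain: int = 0
    hard_rewards: tuple = HARD_REWARDS
    easy_reward: int = 2
    no_choice_easy_reward: int = 2
    no_choice_hard_reward: int = 5
    choose_limit: float = 3.0
    solve_limit: float = 7.0
    response_lockout: float = 1.5
    timeout_fallback_reward: int = 1
    practice_trials: int = 20

    @property
    def trials_per_block(self) -> int:
        return 2 * (
            self.choice_trials_per_domain
            + self.no_choice_easy_per_domain
            + self.no_choice_hard_per_domain
        )

    @property
    def total_trials(self) -> int:
        return self.blocks * self.trials_per_block

    @property
    def total_no_choice(self) -> int:
        return 2 * self.blocks * (self.no_choice_easy_per_domain + self.no_choice_hard_per_domain)


@dataclass(frozen=True)
class ChoiceOffer:
    domain: str
    easy_reward: int
    hard_reward: int | None
    hard_side: str = "left"
    is_no_choice: bool = False
    forced_option: str | None = None

    def __post_init__(self):
        if self.is_no_choice and self.forced_option not in ("easy", "hard"):
            raise InvalidArgumentError("no-choice offer needs a forced option")


@dataclass
class TrialRecord:
    participant_id: str
    study: str
    block_index: int      # 1-based; 0 marks the practice warm-up
    trial_index: int      # 1-based within block
    domain: str
    is_practice: bool
    is_no_choice: bool
    hard_reward_offered: int | None
    choice: str           # easy | hard | timeout
    choice_rt: float | None
    difficulty_level: int
    solve_correct: bool
    solve_rt: float | None
    solve_timeout: bool
    reward_earned: int
    extra: dict = field(default_factory=dict)


def build_design(study: str) -> SessionDesign:
    """Preset designs: 200 / 100 / 140 main trials for study1 / 1R / 2."""
    if study == "study1":
        return SessionDesign(study, blocks=2, choice_trials_per_domain=50, practice_trials=20)
    if study == "study1R":
        return SessionDesign(study, blocks=5, choice_trials_per_domain=10, practice_trials=20)
    if study == "study2":
        return SessionDesign(
            study,
            blocks=5,
            choice_trials_per_domain=10,
            no_choice_easy_per_domain=2,
            no_choice_hard_per_domain=2,
            practice_trials=28,
        )
    raise InvalidArgumentError(f"unknown study preset {study!r}; expected one of {STUDIES}")


def _balanced_rewards(n: int, values: tuple, rng) -> list[int]:
    """n rewards with equal counts per value; remainder assigned at random."""
    base, rem = divmod(n, len(values))
    out = list(values) * base + list(rng.sample(values, rem))
    rng.shuffle(out)
    return out


def _counterbalanced_sides(n: int, rng) -> list[str]:
    sides = ["left"] * (n // 2) + ["right"] * (n - n // 2)
    rng.shuffle(sides)
    return sides


def schedule_block(design: SessionDesign, block_index: int, rng) -> list[ChoiceOffer]:
    """One block's offers: balanced hard rewards, counterbalanced sides, shuffled order."""
    if block_index < 1 or block_index > design.blocks:
        raise InvalidArgumentError(f"block index {block_index} outside [1, {design.blocks}]")
    offers: list[ChoiceOffer] = []
    for domain in ("math", "word"):
        rewards = _balanced_rewards(design.choice_trials_per_domain, design.hard_rewards, rng)
        sides = _counterbalanced_sides(design.choice_trials_per_domain, rng)
        offers.extend(
            ChoiceOffer(domain, design.easy_reward, r, s) for r, s in zip(rewards, sides)
        )
        nc_sides = _counterbalanced_sides(
            design.no_choice_easy_per_domain + design.no_choice_hard_per_domain, rng
        )
        for i in range(design.no_choice_easy_per_domain):
            offers.append(
                ChoiceOffer(
                    domain,
                    design.no_choice_easy_reward,
                    None,
                    nc_sides[i],
                    is_no_choice=True,
                    forced_option="easy",
                )
            )
        for i in range(design.no_choice_hard_per_domain):
            offers.append(
                ChoiceOffer(
                    domain,
                    design.easy_reward,
                    design.no_choice_hard_reward,
                    nc_sides[design.no_choice_easy_per_domain + i],
                    is_no_choice=True,
                    forced_option="hard",
                )
            )
    rng.shuffle(offers)
    return offers


def _latent_of(sampler: BankSampler | None, domain: str, level: int, rng) -> float:
    if sampler is not None:
        return sampler.draw(domain, level, rng).latent_difficulty
    return latent_difficulty_of_level(level) + LATENT_SD * rng.gauss(0.0, 1.0)


def _run_trial(agent, design, offer, stair, sampler, rng):
    """Resolve one offer; returns (record fields dict, updated staircase)."""
    if offer.is_no_choice:
        choice = offer.forced_option
        # self-paced acceptance key press; no 3-s deadline applies
        choice_rt = ag._raw_rt(agent.rt_params.choose_median, agent.rt_params.choose_sigma, rng)
    else:
        choice = ag.choose(agent, offer, stair.level, rng)
        choice_rt = (
            None
            if choice == "timeout"
            else ag.sample_rt(agent, "choose", offer.domain, 1, rng, choose_limit=design.choose_limit)
        )

    if choice == "hard":
        level = stair.level
        offered = offer.hard_reward
    elif choice == "timeout":
        level = 1
        offered = design.timeout_fallback_reward
    else:
        level = 1
        offered = offer.easy_reward if not offer.is_no_choice else design.no_choice_easy_reward

    latent = _latent_of(sampler, offer.domain, level, rng)
    guessing = choice == "hard" and ag.is_guessing(agent, offer.domain, level)
    p_correct = ag.CHANCE if guessing else ag.accuracy_from_latent(agent, offer.domain, latent)

    raw_rt = ag.raw_solve_rt(agent, offer.domain, level, rng)
    if raw_rt > design.solve_limit:
        solve_timeout = True
        solve_rt = None
        correct = False
    else:
        solve_timeout = False
        solve_rt = max(raw_rt, design.response_lockout)
        correct = rng.random() < p_correct

    if choice == "hard":
        stair = sc.update(stair, correct)  # timeouts count as incorrect
        if len(stair.history) > 1:  # levels live in the records; keep update O(1)
            del stair.history[:-1]

    return (
        dict(
            domain=offer.domain,
            is_no_choice=offer.is_no_choice,
            hard_reward_offered=offer.hard_reward,
            choice=choice,
            choice_rt=choice_rt,
            difficulty_level=level,
            solve_correct=correct,
            solve_rt=solve_rt,
            solve_timeout=solve_timeout,
            reward_earned=offered if correct else 0,
        ),
        stair,
    )


def run_session(
    agent: ag.AgentParams,
    design: SessionDesign,
    bank: ProblemBank | None = None,
    seed: int = 0,
    participant_id: str = "agent",
    include_practice: bool = True,
) -> list[TrialRecord]:
    """Run one full session; one TrialRecord per scheduled trial.

    Per-domain staircases start at level 4 and persist from the practice
    warm-up (block_index 0, flagged ``is_practice``, no reward) through
    the main blocks.  When ``bank`` is None, latent difficulties are
    sampled parametrically instead of drawn from an item pool.
    Deterministic given ``seed``.
    """
    rng = random.Random(seed)
    sampler = bank.sampler() if bank is not None else None
    stairs = {"math": sc.init_staircase(), "word": sc.init_staircase()}
    records: list[TrialRecord] = []

    blocks: list[tuple[int, bool, list[ChoiceOffer]]] = []
    if include_practice and design.practice_trials > 0:
        warmup = schedule_block(design, 1, rng)
        while len(warmup) < design.practice_trials:
            warmup = warmup + schedule_block(design, 1, rng)
        blocks.append((0, True, warmup[: design.practice_trials]))
    for b in range(1, design.blocks + 1):
        blocks.append((b, False, schedule_block(design, b, rng)))

    for block_index, is_practice, offers in blocks:
        for trial_index, offer in enumerate(offers, start=1):
            fields_, stairs[offer.domain] = _run_trial(
                agent, design, offer, stairs[offer.domain], sampler, rng
            )
            if is_practice:
                fields_["reward_earned"] = 0
            records.append(
                TrialRecord(
                    participant_id=participant_id,
                    study=design.study,
                    block_index=block_index,
                    trial_index=trial_index,
                    is_practice=is_practice,
                    **fields_,
                )
            )
    return records


def main_records(records: list[TrialRecord]) -> list[TrialRecord]:
    """Drop practice warm-up rows."""
    return [r for r in records if not r.is_practice]
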