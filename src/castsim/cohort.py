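"""Synthetic cohorts: correlated trait profiles, trait->agent mapping, and
calibration of the anxiety->math-cost slope to a target population effect.

Traits are generated from a latent multivariate normal, affinely mapped to
their questionnaire scales and clipped — the simplest mechanism that gives
a controllable correlation matrix.  Math anxiety is positively correlated
with test, trait and reading anxiety by default (qualitative structure
only; the defaults are assumptions, not published covariances).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine, scoring
from .agents import AgentParams, RTParams
from .errors import CalibrationError, InvalidArgumentError

TRAITS = ("math_anxiety", "reading_anxiety", "trait_anxiety", "test_anxiety")
TRAIT_BOUNDS = {
    "math_anxiety": (1.0, 5.0),
    "reading_anxiety": (1.0, 5.0),
    "trait_anxiety": (20.0, 80.0),
    "test_anxiety": (20.0, 80.0),
}
AGE_BANDS = ("18-25", "26-35", "36-50", "51+")
GENDERS = ("female", "male", "other")

DEFAULT_TRAIT_MEANS = {
    "math_anxiety": 2.2,
    "reading_anxiety": 1.8,
    "trait_anxiety": 40.0,
    "test_anxiety": 45.0,
}
DEFAULT_TRAIT_SDS = {
    "math_anxiety": 0.9,
    "reading_anxiety": 0.7,
    "trait_anxiety": 10.0,
    "test_anxiety": 12.0,
}


def default_trait_corr() -> np.ndarray:
    """Qualitative default: math anxiety positively tied to the other anxieties."""
    # order: math, reading, trait, test
    return np.array(
        [
            [1.00, 0.30, 0.35, 0.50],
            [0.30, 1.00, 0.25, 0.20],
            [0.35, 0.25, 1.00, 0.60],
            [0.50, 0.20, 0.60, 1.00],
        ]
    )


@dataclass(frozen=True)
class TraitProfile:
    math_anxiety: float
    reading_anxiety: float
    trait_anxiety: float
    test_anxiety: float
    age_band: str = "26-35"
    gender: str = "other"


@dataclass
class CohortConfig:
    n: int
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    trait_corr: np.ndarray = field(default_factory=default_trait_corr)
    anxiety_cost_slope: float | None = None
    target_r: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.anxiety_cost_slope is not None and self.target_r is not None:
            raise InvalidArgumentError("set exactly one of anxiety_cost_slope / target_r")


def generate_traits(config: CohortConfig) -> list[TraitProfile]:
    """Sample n trait profiles from the latent-normal model (clip after sampling)."""
    corr = np.asarray(config.trait_corr, dtype=float)
    if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
        raise InvalidArgumentError("trait correlation matrix must be symmetric 4x4")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise InvalidArgumentError(f"trait correlation matrix not PSD (min eigenvalue {eigvals.min():.3g})")
    rng = np.random.default_rng(config.seed)
    if config.n == 0:
        return []
    z = rng.multivariate_normal(np.zeros(4), corr, size=config.n, method="eigh")
    profiles = []
    for i in range(config.n):
        vals = {}
        for j, t in enumerate(TRAITS):
            lo, hi = TRAIT_BOUNDS[t]
            vals[t] = float(np.clip(config.trait_means[t] + config.trait_sds[t] * z[i, j], lo, hi))
        profiles.append(
            TraitProfile(
                age_band=AGE_BANDS[rng.integers(len(AGE_BANDS))],
                gender=GENDERS[rng.integers(len(GENDERS))],
                **vals,
            )
        )
    return profiles


@dataclass
class AgentCalibration:
    """Trait -> agent-parameter mapping used by :func:`traits_to_agents`."""

    competence_mean: float = 4.0
    competence_sd: float = 0.6
    #: shift of math competence per math-anxiety unit (negative reproduces
    #: the anxiety -> lower-ADL link); applied around mid-scale anxiety 3.
    competence_anxiety_coupling: float = 0.0
    psychometric_slope: float = 1.0
    lapse: float = 0.02
    cost_base_math: float = 0.0
    cost_base_word: float = 0.0
    #: SD of a per-agent half-normal effort-cost offset shared by both
    #: domains; gives stable, anxiety-independent individual differences
    #: in choice behaviour (needed for realistic test-retest reliability).
    cost_base_sd: float = 0.0
    anxiety_cost_slope: float = 0.0
    choice_temperature: float = 0.5
    guess_threshold: float = math.inf
    choice_timeout_prob: float = 0.01
    rt_params: RTParams = field(default_factory=RTParams)


def traits_to_agents(
    profiles: list[TraitProfile], calibration: AgentCalibration, seed: int = 0
) -> list[AgentParams]:
    """One agent per profile; deterministic given seed."""
    rng = np.random.default_rng(seed)
    agents = []
    c = calibration
    for p in profiles:
        comp_math = (
            c.competence_mean
            + c.competence_anxiety_coupling * (p.math_anxiety - 3.0)
            + c.competence_sd * rng.standard_normal()
        )
        comp_word = c.competence_mean + c.competence_sd * rng.standard_normal()
        cost_jitter = abs(c.cost_base_sd * rng.standard_normal())
        agents.append(
            AgentParams(
                math_anxiety=p.math_anxiety,
                reading_anxiety=p.reading_anxiety,
                trait_anxiety=p.trait_anxiety,
                test_anxiety=p.test_anxiety,
                competence_math=float(comp_math),
                competence_word=float(comp_word),
                psychometric_slope=c.psychometric_slope,
                lapse=c.lapse,
                cost_base_math=c.cost_base_math + cost_jitter,
                cost_base_word=c.cost_base_word + cost_jitter,
                anxiety_cost_slope=c.anxiety_cost_slope,
                choice_temperature=c.choice_temperature,
                guess_threshold=c.guess_threshold,
                choice_timeout_prob=c.choice_timeout_prob,
                rt_params=c.rt_params,
            )
        )
    return agents


def simulate_cohort(
    agents: list[AgentParams],
    design: engine.SessionDesign,
    seed: int = 0,
    bank=None,
    include_practice: bool = True,
    with_blocks: bool = False,
) -> pd.DataFrame:
    """Run every agent through a session and return the summary frame.

    Trait scores are merged into the summary rows so correlation and
    regression layers can run directly on the result.
    """
    rows = []
    for i, agent in enumerate(agents):
        records = engine.run_session(
            agent,
            design,
            bank=bank,
            seed=seed + i,
            participant_id=f"p{i:05d}",
            include_practice=include_practice,
        )
        s = scoring.summarize_participant(records, f"p{i:05d}", with_blocks)
        row = s.to_row()
        for t in TRAITS:
            row[t] = getattr(agent, t)
        rows.append(row)
    return pd.DataFrame(rows)


def _hcp_fast(records, domain: str) -> float:
    """Mean-of-conditions math/word HCP straight off a record list (no pandas).

    Matches :func:`castsim.scoring.compute_hcp`; kept lean because the
    calibration bisection evaluates thousands of sessions per step.
    """
    chosen = {4: [0, 0], 5: [0, 0], 6: [0, 0]}
    for r in records:
        if (
            r.is_practice
            or r.is_no_choice
            or r.domain != domain
            or r.choice == "timeout"
            or r.hard_reward_offered not in chosen
        ):
            continue
        cell = chosen[r.hard_reward_offered]
        cell[1] += 1
        if r.choice == "hard":
            cell[0] += 1
    props = [k / m for k, m in chosen.values() if m > 0]
    if len(props) < 3:
        return float("nan")
    return sum(props) / 3.0


def _cohort_r(slope: float, profiles, calibration, design, seed: int) -> float:
    """r(math_anxiety, math HCP) of a simulated cohort at a given cost slope."""
    agents = traits_to_agents(profiles, replace(calibration, anxiety_cost_slope=slope), seed=seed)
    anx, hcp = [], []
    for i, agent in enumerate(agents):
        records = engine.run_session(agent, design, seed=seed + i, include_practice=False)
        h = _hcp_fast(records, "math")
        if not np.isnan(h):
            anx.append(agent.math_anxiety)
            hcp.append(h)
    return float(np.corrcoef(anx, hcp)[0, 1])


def calibrate_effect(
    target_r: float,
    design: engine.SessionDesign,
    base_config: CohortConfig,
    calibration: AgentCalibration | None = None,
    n: int = 2000,
    tol: float = 0.01,
    max_iter: int = 24,
) -> dict:
    """Find the anxiety->cost slope whose simulated r(math anxiety, math HCP)
    matches ``target_r``, by monotone bisection with common random numbers.

    Returns a report dict: slope, target_r, achieved_r, iterations, n.
    """
    if not (-1.0 < target_r <= 0.0):
        raise InvalidArgumentError("target_r must be in (-1, 0]")
    calibration = calibration or AgentCalibration()
    config = replace(base_config, n=max(n, base_config.n))
    profiles = generate_traits(config)
    seed = config.seed + 7919

    if target_r == 0.0:
        return {"slope": 0.0, "target_r": 0.0, "achieved_r": _cohort_r(0.0, profiles, calibration, design, seed), "iterations": 0, "n": config.n}

    lo, r_lo = 0.0, _cohort_r(0.0, profiles, calibration, design, seed)
    hi = 0.2
    r_hi = _cohort_r(hi, profiles, calibration, design, seed)
    expansions = 0
    while r_hi > target_r:
        hi *= 2.0
        expansions += 1
        if hi > 25.0:
            raise CalibrationError(
                f"target_r={target_r} unattainable; achievable range is about [{r_hi:.3f}, {r_lo:.3f}]"
            )
        r_hi = _cohort_r(hi, profiles, calibration, design, seed)
    if target_r > r_lo:
        raise CalibrationError(
            f"target_r={target_r} above the zero-slope correlation {r_lo:.3f}"
        )

    iterations = expansions + 2
    mid, r_mid = hi, r_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = _cohort_r(mid, profiles, calibration, design, seed)
        iterations += 1
        if abs(r_mid - target_r) < tol:
            break
        if r_mid > target_r:  # effect too weak, need more cost
            lo = mid
        else:
            hi = mid
    return {
        "slope": float(mid),
        "target_r": float(target_r),
        "achieved_r": float(r_mid),
        "iterations": iterations,
        "n": config.n,
    }


def cohort_to_frame(profiles: list[TraitProfile], agents: list[AgentParams] | None = None) -> pd.DataFrame:
    """Cohort CSV payload: traits, strata and (optionally) agent parameters."""
    rows = []
    for i, p in enumerate(profiles):
        row = {"participant_id": f"p{i:05d}", **p.__dict__}
        if agents is not None:
            a = agents[i]
            for k, v in a.__dict__.items():
                if k in TRAITS:
                    continue
                if isinstance(v, RTParams):
                    row.update({f"rt_{kk}": vv for kk, vv in v.__dict__.items()})
                else:
                    row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_agents(df: pd.DataFrame) -> list[AgentParams]:
    """Rebuild agents from a cohort frame produced by :func:`cohort_to_frame`."""
    agents = []
    agent_fields = {f for f in AgentParams.__dataclass_fields__ if f != "rt_params"}
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in agent_fields if k in row and pd.notna(row[k])}
        rt_kwargs = {
            k[3:]: row[k] for k in row.index if k.startswith("rt_") and pd.notna(row[k])
        }
        if rt_kwargs:
            kwargs["rt_params"] = RTParams(**rt_kwargs)
        agents.append(AgentParams(**kwargs))
    return agents
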