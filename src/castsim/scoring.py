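"""Reduce trial logs to per-participant measures and apply exclusion rules.

Measures
--------
HCP (hard choice probability)
    Mean over the 4-, 5- and 6-cent reward conditions of the per-condition
    proportion of hard-card selections (equal-weight mean of three
    proportions; a pooled variant is also exposed — the two coincide
    under balanced schedules).  Choice-timeout, no-choice and practice
    trials never enter HCP.
ADL (average difficulty level)
    Arithmetic mean difficulty level of all hard problems encountered
    (chosen-hard and no-choice-hard), practice excluded.

Accuracy denominators include solve timeouts (counted as incorrect,
consistent with staircase handling); RT summaries use answered trials
only.  Choice-timeout fallback solves are excluded from the easy-accuracy
denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedMeasureError

HCP_REWARDS = (4, 5, 6)

_COLUMNS = [
    "participant_id",
    "study",
    "block_index",
    "trial_index",
    "domain",
    "is_practice",
    "is_no_choice",
    "hard_reward_offered",
    "choice",
    "choice_rt",
    "difficulty_level",
    "solve_correct",
    "solve_rt",
    "solve_timeout",
    "reward_earned",
]


def records_to_frame(records) -> pd.DataFrame:
    """Normalize a list of TrialRecord (or an existing frame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [{c: getattr(r, c) for c in _COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=_COLUMNS)


def _main(df: pd.DataFrame) -> pd.DataFrame:
    return df[~df["is_practice"].astype(bool)]


def expected_value(reward: float, accuracy: float) -> float:
    """Expected reward of a card: offered reward times P(correct)."""
    if reward < 0:
        raise InvalidArgumentError("reward must be >= 0")
    if not 0.0 <= accuracy <= 1.0:
        raise InvalidArgumentError("accuracy must be in [0, 1]")
    return reward * accuracy


def compute_hcp(records, domain: str, method: str = "mean_of_conditions") -> float:
    """Hard choice probability for one participant in one domain."""
    df = _main(records_to_frame(records))
    elig = df[
        (df["domain"] == domain)
        & ~df["is_no_choice"].astype(bool)
        & (df["choice"] != "timeout")
        & df["hard_reward_offered"].isin(HCP_REWARDS)
    ]
    if method == "pooled":
        if len(elig) == 0:
            raise UndefinedMeasureError(f"no eligible {domain} trials in the 4/5/6-cent cells")
        return float((elig["choice"] == "hard").mean())
    if method != "mean_of_conditions":
        raise InvalidArgumentError(f"unknown HCP method {method!r}")
    props = []
    for reward in HCP_REWARDS:
        cell = elig[elig["hard_reward_offered"] == reward]
        if len(cell) == 0:
            raise UndefinedMeasureError(f"empty {domain} {reward}-cent cell: HCP undefined")
        props.append((cell["choice"] == "hard").mean())
    return float(np.mean(props))


def compute_adl(records, domain: str) -> float:
    """Average difficulty level of all hard problems encountered."""
    df = _main(records_to_frame(records))
    hard = df[(df["domain"] == domain) & (df["choice"] == "hard")]
    if len(hard) == 0:
        raise UndefinedMeasureError(f"no hard {domain} trials: ADL undefined")
    return float(hard["difficulty_level"].mean())


def timeout_proportion(records, domain: str) -> float:
    """Proportion of hard solves in which the agent ran out of time."""
    df = _main(records_to_frame(records))
    hard = df[(df["domain"] == domain) & (df["choice"] == "hard")]
    if len(hard) == 0:
        raise UndefinedMeasureError(f"no hard {domain} trials")
    return float(hard["solve_timeout"].astype(bool).mean())


def _acc_rt(sub: pd.DataFrame) -> tuple[float, float]:
    """(accuracy incl. timeouts-as-wrong, mean RT over answered trials)."""
    if len(sub) == 0:
        return float("nan"), float("nan")
    acc = float(sub["solve_correct"].astype(bool).mean())
    answered = sub[~sub["solve_timeout"].astype(bool)]
    rt = float(answered["solve_rt"].mean()) if len(answered) else float("nan")
    return acc, rt


@dataclass
class ParticipantSummary:
    participant_id: str
    hcp_math: float = float("nan")
    hcp_word: float = float("nan")
    adl_math: float = float("nan")
    adl_word: float = float("nan")
    easy_accuracy_math: float = float("nan")
    easy_accuracy_word: float = float("nan")
    hard_accuracy_math: float = float("nan")
    hard_accuracy_word: float = float("nan")
    easy_rt_math: float = float("nan")
    easy_rt_word: float = float("nan")
    hard_rt_math: float = float("nan")
    hard_rt_word: float = float("nan")
    hard_timeout_prop_math: float = float("nan")
    hard_timeout_prop_word: float = float("nan")
    total_reward: float = 0.0
    excluded: bool = False
    block_series: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "block_series"}
        return d


def summarize_participant(
    records, participant_id: str | None = None, with_blocks: bool = True
) -> ParticipantSummary:
    """All per-participant measures from one trial log.

    ``with_blocks=False`` skips the per-block HCP/ADL series (a
    substantial cost on large simulated cohorts).
    """
    df = _main(records_to_frame(records))
    if participant_id is None:
        participant_id = str(df["participant_id"].iloc[0]) if len(df) else "unknown"
    s = ParticipantSummary(participant_id=participant_id)

    for domain in ("math", "word"):
        sub = df[df["domain"] == domain]
        easy = sub[(sub["choice"] == "easy")]
        hard = sub[(sub["choice"] == "hard")]
        acc, rt = _acc_rt(easy)
        setattr(s, f"easy_accuracy_{domain}", acc)
        setattr(s, f"easy_rt_{domain}", rt)
        acc, rt = _acc_rt(hard)
        setattr(s, f"hard_accuracy_{domain}", acc)
        setattr(s, f"hard_rt_{domain}", rt)
        try:
            setattr(s, f"hcp_{domain}", compute_hcp(df, domain))
        except UndefinedMeasureError:
            pass
        try:
            setattr(s, f"adl_{domain}", compute_adl(df, domain))
            setattr(s, f"hard_timeout_prop_{domain}", timeout_proportion(df, domain))
        except UndefinedMeasureError:
            pass

    s.total_reward = float(df["reward_earned"].sum())
    if with_blocks:
        s.block_series = _block_series(df)
    s.excluded = not (s.easy_accuracy_math >= 0.70 and s.easy_accuracy_word >= 0.70)
    return s


def _block_series(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for block, bdf in df.groupby("block_index"):
        row = {"block_index": int(block)}
        for domain in ("math", "word"):
            for measure, fn in (("hcp", compute_hcp), ("adl", compute_adl)):
                try:
                    row[f"{measure}_{domain}"] = fn(bdf, domain)
                except UndefinedMeasureError:
                    row[f"{measure}_{domain}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(logs: dict | list, with_blocks: bool = True) -> pd.DataFrame:
    """One summary row per participant from a mapping id -> records (or list of logs)."""
    if isinstance(logs, dict):
        summaries = [summarize_participant(v, str(k), with_blocks) for k, v in logs.items()]
    else:
        summaries = [summarize_participant(v, None, with_blocks) for v in logs]
    return pd.DataFrame([s.to_row() for s in summaries])


def apply_exclusions(summaries) -> tuple:
    """Partition summaries by the easy-accuracy rule (strict < 0.70 excludes).

    Undefined easy accuracy is treated as excluded with a warning.  Works
    on a summary DataFrame or a list of :class:`ParticipantSummary`.
    """
    if isinstance(summaries, pd.DataFrame):
        acc_m = summaries["easy_accuracy_math"]
        acc_w = summaries["easy_accuracy_word"]
        undefined = acc_m.isna() | acc_w.isna()
        if undefined.any():
            warnings.warn(
                f"{int(undefined.sum())} participant(s) with undefined easy accuracy excluded"
            )
        keep = (acc_m >= 0.70) & (acc_w >= 0.70) & ~undefined
        return summaries[keep], summaries[~keep]
    kept, excluded = [], []
    for s in summaries:
        if np.isnan(s.easy_accuracy_math) or np.isnan(s.easy_accuracy_word):
            warnings.warn(f"participant {s.participant_id}: undefined easy accuracy; excluded")
            excluded.append(s)
        elif s.easy_accuracy_math >= 0.70 and s.easy_accuracy_word >= 0.70:
            kept.append(s)
        else:
            excluded.append(s)
    return kept, excluded


def verify_reward_conservation(records) -> bool:
    """Independent re-tally: earned reward must equal offered x correct."""
    df = records_to_frame(records)
    offered = np.where(
        df["choice"] == "hard",
        df["hard_reward_offered"].astype(float),
        np.where(df["choice"] == "timeout", 1.0, 2.0),
    )
    expected = np.where(
        df["solve_correct"].astype(bool) & ~df["is_practice"].astype(bool), offered, 0.0
    )
    return bool(np.allclose(expected, df["reward_earned"].astype(float)))


def block_slopes(summaries, measures=("hcp_math", "hcp_word", "adl_math", "adl_word")) -> pd.DataFrame:
    """Per-participant OLS slope of each measure against block index.

    Returns one row per measure with the cohort mean slope and a two-sided
    sign-test p-value on the per-participant slope signs.  Needs >= 2
    blocks per participant.
    """
    from scipy.stats import binomtest

    if not isinstance(summaries, (list, tuple)):
        summaries = [summaries]
    per_measure: dict[str, list[float]] = {m: [] for m in measures}
    for s in summaries:
        series = s.block_series if isinstance(s, ParticipantSummary) else s
        for m in measures:
            sub = series[["block_index", m]].dropna()
            if len(sub) < 2:
                continue
            slope = np.polyfit(sub["block_index"], sub[m], 1)[0]
            per_measure[m].append(float(slope))
    rows = []
    for m, slopes in per_measure.items():
        if not slopes:
            raise UndefinedMeasureError(f"fewer than 2 blocks for measure {m}")
        arr = np.asarray(slopes)
        nonzero = arr[arr != 0]
        p = binomtest((nonzero > 0).sum(), len(nonzero), 0.5).pvalue if len(nonzero) else 1.0
        rows.append({"measure": m, "mean_slope": arr.mean(), "n": len(arr), "sign_test_p": float(p)})
    return pd.DataFrame(rows)
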