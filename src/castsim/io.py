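"""CSV dialects for trial logs, cohorts and summaries, plus bundled fixtures.

All tabular artifacts are plain CSV; money is integer cents and times are
seconds with three decimals.  Session provenance (design, seed, agent id)
goes in a JSON sidecar next to each trial log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .engine import TrialRecord
from .errors import SchemaError
from .scoring import _COLUMNS as TRIAL_COLUMNS

FORMAT_VERSION = "castsim-log-v1"


def write_trial_log(records: list[TrialRecord], path) -> None:
    """One row per trial; unknown (``extra``) columns appended after the core set."""
    rows = []
    extra_cols: list[str] = []
    for r in records:
        row = {c: getattr(r, c) for c in TRIAL_COLUMNS}
        for k, v in r.extra.items():
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS + extra_cols)
    for col in ("choice_rt", "solve_rt"):
        if col in df and len(df):
            df[col] = df[col].round(3)
    df.to_csv(path, index=False)


def read_trial_log(path) -> list[TrialRecord]:
    """Lossless counterpart of :func:`write_trial_log`; validates the header."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log {path} missing mandatory column(s): {missing}")
    extras = [c for c in df.columns if c not in TRIAL_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            TrialRecord(
                participant_id=str(d["participant_id"]),
                study=str(d["study"]),
                block_index=int(d["block_index"]),
                trial_index=int(d["trial_index"]),
                domain=str(d["domain"]),
                is_practice=bool(d["is_practice"]),
                is_no_choice=bool(d["is_no_choice"]),
                hard_reward_offered=None if pd.isna(d["hard_reward_offered"]) else int(d["hard_reward_offered"]),
                choice=str(d["choice"]),
                choice_rt=None if pd.isna(d["choice_rt"]) else float(d["choice_rt"]),
                difficulty_level=int(d["difficulty_level"]),
                solve_correct=bool(d["solve_correct"]),
                solve_rt=None if pd.isna(d["solve_rt"]) else float(d["solve_rt"]),
                solve_timeout=bool(d["solve_timeout"]),
                reward_earned=int(d["reward_earned"]),
                extra={k: d[k] for k in extras},
            )
        )
    return records


def write_sidecar(path, design, seed: int, participant_id: str, extra: dict | None = None) -> None:
    payload = {
        "format": FORMAT_VERSION,
        "participant_id": participant_id,
        "seed": seed,
        "design": dataclasses.asdict(design),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Fixtures: small hand-checkable inputs used by the test suite.


def make_fixtures(seed: int = 0) -> dict:
    """Toy inputs with hand-computable answers.

    * ``exclusion_cohort`` — 6 summaries; the easy-accuracy rule keeps 4
      and excludes 2.
    * ``hcp_log`` — 9 math choice trials with unbalanced reward cells:
      per-condition hard proportions (3/4, 1/3, 1/2), so the
      mean-of-conditions HCP is 19/36 while the pooled proportion is 5/9.
    * ``mini_cohort`` — 20 agents with a known anxiety->cost slope.
    """
    from . import cohort as co

    easy_math = [0.95, 0.71, 0.69, 0.70, 0.50, 0.90]
    exclusion_cohort = pd.DataFrame(
        {
            "participant_id": [f"t{i}" for i in range(6)],
            "easy_accuracy_math": easy_math,
            "easy_accuracy_word": [0.9] * 6,
        }
    )

    chosen = {4: ["hard", "hard", "hard", "easy"], 5: ["hard", "easy", "easy"], 6: ["hard", "easy"]}
    hcp_log = []
    i = 0
    for reward, choices in chosen.items():
        for choice in choices:
            i += 1
            level = 4 if choice == "hard" else 1
            hcp_log.append(
                TrialRecord(
                    participant_id="fixture",
                    study="study2",
                    block_index=1,
                    trial_index=i,
                    domain="math",
                    is_practice=False,
                    is_no_choice=False,
                    hard_reward_offered=reward,
                    choice=choice,
                    choice_rt=1.0,
                    difficulty_level=level,
                    solve_correct=True,
                    solve_rt=3.0,
                    solve_timeout=False,
                    reward_earned=reward if choice == "hard" else 2,
                )
            )

    config = co.CohortConfig(n=20, seed=seed)
    profiles = co.generate_traits(config)
    calibration = co.AgentCalibration(anxiety_cost_slope=0.1)
    agents = co.traits_to_agents(profiles, calibration, seed=seed)
    mini_cohort = co.cohort_to_frame(profiles, agents)

    return {
        "exclusion_cohort": exclusion_cohort,
        "hcp_log": hcp_log,
        "mini_cohort": mini_cohort,
        "mini_cohort_slope": 0.1,
    }


def write_fixtures(out_dir, seed: int = 0) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures(seed)
    fx["exclusion_cohort"].to_csv(out / "exclusion_cohort.csv", index=False)
    write_trial_log(fx["hcp_log"], out / "hcp_log.csv")
    fx["mini_cohort"].to_csv(out / "mini_cohort.csv", index=False)
    return fx
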