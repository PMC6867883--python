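# castsim

Simulator and analysis toolkit for an effort-based *choose-and-solve* task:
on every trial an agent chooses between an easy low-reward problem and a
hard high-reward problem, then solves it under a time limit while a
2-up-1-down staircase continuously adapts hard-problem difficulty toward
~70% accuracy. The package generates synthetic cohorts of agents with
correlated anxiety traits, runs full sessions, reduces trial logs to the
standard derived measures, and provides the statistical layer used to
analyze them.

## Modules

| module | contents |
|---|---|
| `castsim.problems` | difficulty-sorted synthetic item banks (7 levels), without-replacement sampling, missing-digit multiplication rendering |
| `castsim.staircase` | 2-up-1-down rule (start 4, bounds [2, 7]), theoretical equilibrium (sqrt 0.5 ≈ 70.7%), long-run simulation |
| `castsim.engine` | session designs (`study1`/`study1R`/`study2` presets: 200/100/140 trials), block scheduling, choose/solve/timing rules, trial records |
| `castsim.agents` | psychometric solving model (1/3 floor, lapse ceiling), effort-cost choice with anxiety-scaled math cost, log-normal RTs, fast-guessing mode |
| `castsim.cohort` | correlated trait generation, trait→agent mapping, bisection calibration of the anxiety→cost slope to a target population correlation |
| `castsim.scoring` | HCP (mean of the 4/5/6-cent condition proportions), ADL, accuracies/RTs/timeout proportions, exclusion rule (easy accuracy < 70%), block slopes |
| `castsim.analysis` | Fisher-z Pearson CIs, sample-size arithmetic, domain×anxiety interaction regression, binomial choice-count regression, test-retest reliability |
| `castsim.io` / `castsim.cli` | trial-log / cohort / summary CSV dialects, JSON sidecars, bundled toy fixtures, `castsim` command line |

## CLI

```sh
castsim simulate --study study2 --n 20 --seed 1 --out logs/   # one CSV+JSON per agent
castsim score logs/ --out summaries.csv
castsim analyze summaries.csv --model corr --out report.json  # corr | interaction | binomial
castsim power --rho 0.2 --power 0.80                          # -> 194
castsim calibrate --target-r -0.34 --study study1 --n 2000 --seed 0 --out cal.json
castsim fixtures --seed 0 --out fixtures/
```

All commands are deterministic given `--seed`.

## Notes on the simulation model

- Choice follows a softmax over subjective values
  `SV = perceived accuracy × reward − effort cost`, with effort linear in
  difficulty level and the math cost increasing in math anxiety.
- Default agent beliefs are the design constants (95% easy / 70% hard).
- Per-level item allocation of the banks is near-uniform (the remainder
  goes to the lower levels) — an assumption, since only the level ordering
  matters downstream.
- Word items are abstract (latent difficulty only); concrete rendering is
  implemented for math items.
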