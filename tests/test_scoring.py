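import numpy as np
import pandas as pd
import pytest

from castsim import scoring
from castsim.engine import TrialRecord, build_design, run_session
from castsim.errors import InvalidArgumentError, UndefinedMeasureError


def make_record(**kw):
    base = dict(
        participant_id="p0",
        study="study1",
        block_index=1,
        trial_index=1,
        domain="math",
        is_practice=False,
        is_no_choice=False,
        hard_reward_offered=4,
        choice="hard",
        choice_rt=1.0,
        difficulty_level=4,
        solve_correct=True,
        solve_rt=3.0,
        solve_timeout=False,
        reward_earned=4,
    )
    base.update(kw)
    return TrialRecord(**base)


def cell(reward, choices):
    return [
        make_record(hard_reward_offered=reward, choice=c, difficulty_level=4 if c == "hard" else 1)
        for c in choices
    ]


class TestExpectedValue:
    def test_four_cent_hard_card(self):
        assert scoring.expected_value(4, 0.70) == pytest.approx(2.8)

    def test_easy_card(self):
        assert scoring.expected_value(2, 0.95) == pytest.approx(1.9)

    def test_zero_accuracy(self):
        assert scoring.expected_value(6, 0.0) == 0.0

    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            scoring.expected_value(-1, 0.5)
        with pytest.raises(InvalidArgumentError):
            scoring.expected_value(4, 1.5)


class TestComputeHcp:
    def test_always_hard(self):
        recs = cell(4, ["hard"] * 3) + cell(5, ["hard"]) + cell(6, ["hard"])
        assert scoring.compute_hcp(recs, "math") == 1.0

    def test_mean_of_three_conditions(self):
        recs = (
            cell(4, ["hard", "hard"])       # 1.0
            + cell(5, ["hard", "easy"])     # 0.5
            + cell(6, ["easy", "easy"])     # 0.0
        )
        assert scoring.compute_hcp(recs, "math") == pytest.approx(0.5)

    def test_unbalanced_mean_vs_pooled(self, fixtures):
        # hand computation on the 9-trial fixture:
        # 4c: 3/4, 5c: 1/3, 6c: 1/2 -> mean 19/36; pooled 5/9
        log = fixtures["hcp_log"]
        assert scoring.compute_hcp(log, "math") == pytest.approx(19 / 36)
        assert scoring.compute_hcp(log, "math", method="pooled") == pytest.approx(5 / 9)

    def test_balanced_mean_equals_pooled(self):
        recs = cell(4, ["hard", "easy"]) + cell(5, ["hard", "easy"]) + cell(6, ["hard", "hard"])
        mean = scoring.compute_hcp(recs, "math")
        pooled = scoring.compute_hcp(recs, "math", method="pooled")
        assert mean == pytest.approx(pooled)

    def test_empty_cell_errors_naming_cell(self):
        recs = cell(4, ["hard"]) + cell(5, ["easy"])
        with pytest.raises(UndefinedMeasureError, match="6-cent"):
            scoring.compute_hcp(recs, "math")

    def test_excludes_no_choice_timeouts_and_practice(self):
        recs = cell(4, ["hard"]) + cell(5, ["easy"]) + cell(6, ["hard"])
        noise = [
            make_record(hard_reward_offered=5, choice="hard", is_no_choice=True),
            make_record(hard_reward_offered=4, choice="timeout", difficulty_level=1),
            make_record(hard_reward_offered=6, choice="easy", is_practice=True),
        ]
        assert scoring.compute_hcp(recs + noise, "math") == scoring.compute_hcp(recs, "math")

    def test_low_reward_conditions_ignored(self):
        recs = cell(4, ["hard"]) + cell(5, ["hard"]) + cell(6, ["hard"]) + cell(2, ["easy"] * 10)
        assert scoring.compute_hcp(recs, "math") == 1.0


class TestComputeAdl:
    def test_constant_level(self):
        recs = [make_record(difficulty_level=4) for _ in range(5)]
        assert scoring.compute_adl(recs, "math") == 4.0

    def test_mean(self):
        recs = [make_record(difficulty_level=lv) for lv in (4, 5, 5, 6)]
        assert scoring.compute_adl(recs, "math") == 5.0

    def test_includes_no_choice_hard(self):
        recs = [make_record(difficulty_level=4), make_record(difficulty_level=6, is_no_choice=True)]
        assert scoring.compute_adl(recs, "math") == 5.0

    def test_no_hard_trials_errors(self):
        recs = [make_record(choice="easy", difficulty_level=1)]
        with pytest.raises(UndefinedMeasureError):
            scoring.compute_adl(recs, "math")

    def test_competence_ordering(self, study_designs):
        from castsim.agents import AgentParams

        strong = AgentParams(competence_math=5.5)
        weak = AgentParams(competence_math=2.5)
        d = study_designs["study2"]
        adl_strong = np.mean(
            [scoring.compute_adl(run_session(strong, d, seed=s), "math") for s in range(5)]
        )
        adl_weak = np.mean(
            [scoring.compute_adl(run_session(weak, d, seed=s), "math") for s in range(5)]
        )
        assert adl_strong > adl_weak


class TestTimeoutProportion:
    def test_no_timeouts(self):
        recs = [make_record() for _ in range(10)]
        assert scoring.timeout_proportion(recs, "math") == 0.0

    def test_two_of_ten(self):
        recs = [make_record() for _ in range(8)] + [
            make_record(solve_timeout=True, solve_correct=False, solve_rt=None, reward_earned=0)
            for _ in range(2)
        ]
        assert scoring.timeout_proportion(recs, "math") == pytest.approx(0.2)

    def test_slow_agent_times_out_more(self, study_designs):
        from castsim.agents import AgentParams, RTParams

        slow = AgentParams(rt_params=RTParams(solve_median=6.5, solve_sigma=0.3))
        fast = AgentParams(rt_params=RTParams(solve_median=2.0, solve_sigma=0.3))
        d = study_designs["study2"]
        slow_p = scoring.timeout_proportion(run_session(slow, d, seed=1), "math")
        fast_p = scoring.timeout_proportion(run_session(fast, d, seed=1), "math")
        assert slow_p > fast_p


class TestExclusions:
    def test_kept(self):
        df = pd.DataFrame(
            {"participant_id": ["a"], "easy_accuracy_math": [0.95], "easy_accuracy_word": [0.93]}
        )
        kept, excl = scoring.apply_exclusions(df)
        assert len(kept) == 1 and len(excl) == 0

    def test_boundary_strict_less_than(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "easy_accuracy_math": [0.69, 0.70],
                "easy_accuracy_word": [0.99, 0.99],
            }
        )
        kept, excl = scoring.apply_exclusions(df)
        assert list(kept["participant_id"]) == ["b"]
        assert list(excl["participant_id"]) == ["a"]

    def test_six_participant_fixture(self, fixtures):
        kept, excl = scoring.apply_exclusions(fixtures["exclusion_cohort"])
        assert len(kept) == 4
        assert len(excl) == 2
        assert set(excl["participant_id"]) == {"t2", "t4"}

    def test_undefined_accuracy_excluded_with_warning(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "easy_accuracy_math": [np.nan, 0.9],
                "easy_accuracy_word": [0.9, 0.9],
            }
        )
        with pytest.warns(UserWarning):
            kept, excl = scoring.apply_exclusions(df)
        assert list(kept["participant_id"]) == ["b"]

    def test_partition_exhaustive_disjoint(self, fixtures):
        df = fixtures["exclusion_cohort"]
        kept, excl = scoring.apply_exclusions(df)
        assert len(kept) + len(excl) == len(df)
        assert set(kept["participant_id"]).isdisjoint(excl["participant_id"])

    def test_summary_objects_path(self):
        summaries = [
            scoring.ParticipantSummary("a", easy_accuracy_math=0.9, easy_accuracy_word=0.9),
            scoring.ParticipantSummary("b", easy_accuracy_math=0.5, easy_accuracy_word=0.9),
        ]
        kept, excl = scoring.apply_exclusions(summaries)
        assert [s.participant_id for s in kept] == ["a"]
        assert [s.participant_id for s in excl] == ["b"]


class TestBlockSlopes:
    def _summary_with_series(self, values):
        s = scoring.ParticipantSummary("p")
        s.block_series = pd.DataFrame(
            {
                "block_index": range(1, len(values) + 1),
                "hcp_math": values,
                "hcp_word": values,
                "adl_math": values,
                "adl_word": values,
            }
        )
        return s

    def test_constant_series_slope_zero(self):
        out = scoring.block_slopes([self._summary_with_series([0.5] * 5)])
        assert np.allclose(out["mean_slope"], 0.0, atol=1e-12)

    def test_unit_slope(self):
        out = scoring.block_slopes([self._summary_with_series([1, 2, 3, 4, 5])])
        assert np.allclose(out["mean_slope"], 1.0)

    def test_single_block_errors(self):
        with pytest.raises(UndefinedMeasureError):
            scoring.block_slopes([self._summary_with_series([0.5])])

    def test_stationary_cohort_mean_slope_near_zero(self, default_agent, study_designs):
        summaries = [
            scoring.summarize_participant(
                run_session(default_agent, study_designs["study1R"], seed=100 + i), f"p{i}"
            )
            for i in range(30)
        ]
        out = scoring.block_slopes(summaries)
        hcp = out[out["measure"] == "hcp_math"].iloc[0]
        assert abs(hcp["mean_slope"]) < 0.05
        assert hcp["sign_test_p"] > 0.01


class TestSummarize:
    def test_full_session_summary(self, default_agent, study_designs):
        recs = run_session(default_agent, study_designs["study2"], seed=42)
        s = scoring.summarize_participant(recs, "p0")
        for domain in ("math", "word"):
            assert 0.0 <= getattr(s, f"hcp_{domain}") <= 1.0
            assert 2.0 <= getattr(s, f"adl_{domain}") <= 7.0
            assert 0.0 <= getattr(s, f"easy_accuracy_{domain}") <= 1.0
            assert 0.0 <= getattr(s, f"hard_timeout_prop_{domain}") <= 1.0
        assert len(s.block_series) == 5

    def test_roundtrip_via_frame(self, default_agent, study_designs):
        recs = run_session(default_agent, study_designs["study1"], seed=43)
        frame = scoring.records_to_frame(recs)
        assert scoring.compute_hcp(recs, "math") == scoring.compute_hcp(frame, "math")
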