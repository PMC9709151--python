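"""Synthetic agents: logit model evaluation, chance rates, staircase runs."""

import numpy as np
import pytest
from scipy.special import expit, logit

from repeatlab.agents import (
    AgentParams,
    generate_study,
    run_staircase_experiment,
    simulate_session,
    simulate_trial,
    success_probability,
)
from repeatlab.design import (
    BehaviorSet,
    PlannedTrial,
    StaircaseState,
    build_delayed_block,
    build_repeat_session,
)
from repeatlab.io import validate_trials


class TestSuccessProbability:
    def test_zero_logit_gives_half(self):
        agent = AgentParams("b1", alpha=0.0)
        assert success_probability(agent, "wave") == pytest.approx(0.5)

    def test_logit_inverse_identity(self):
        agent = AgentParams("b1", alpha=float(logit(0.75)))
        assert success_probability(agent, "wave") == pytest.approx(0.75)

    def test_delay_term_closed_form(self):
        # alpha=0, beta=-1, delay=e  =>  logit^-1(-1)
        agent = AgentParams("b1", alpha=0.0, beta_slope=-1.0)
        p = success_probability(agent, "wave", delay_s=float(np.e))
        assert p == pytest.approx(float(expit(-1.0)), abs=1e-12)

    def test_gamma_offset_applies(self):
        agent = AgentParams("b1", alpha=0.3, gamma_by_behavior={"head_shake": -0.8})
        assert success_probability(agent, "head_shake") == pytest.approx(float(expit(-0.5)))
        assert success_probability(agent, "wave") == pytest.approx(float(expit(0.3)))

    def test_monotone_decreasing_iff_negative_slope(self):
        delays = np.array([3.0, 6.0, 12.0, 24.0])
        falling = [success_probability(AgentParams("b", beta_slope=-0.7), "w", d) for d in delays]
        flat = [success_probability(AgentParams("b", beta_slope=0.0), "w", d) for d in delays]
        assert np.all(np.diff(falling) < 0)
        assert np.allclose(np.diff(flat), 0)

    def test_chance_agent_has_no_model_probability(self):
        with pytest.raises(ValueError):
            success_probability(AgentParams("b1", mode="chance"), "wave")


class TestSimulateTrial:
    def test_perfect_agent_always_correct(self, behaviors, rng):
        agent = AgentParams("b1", alpha=50.0)
        trial = PlannedTrial(1, "double_repeat", "wave", 2)
        recs = simulate_trial(agent, trial, behaviors, rng)
        assert [r.repeat_position for r in recs] == [1, 2]
        assert all(r.correct and r.response == "wave" for r in recs)

    def test_chance_agent_single_repeat_rate(self, behaviors, rng):
        agent = AgentParams("b1", mode="chance")
        trial = PlannedTrial(1, "single_repeat", "wave", 1)
        hits = sum(
            simulate_trial(agent, trial, behaviors, rng)[0].correct
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.25, abs=0.015)

    def test_chance_agent_double_repeat_rate(self, behaviors, rng):
        agent = AgentParams("b1", mode="chance")
        trial = PlannedTrial(1, "double_repeat", "wave", 2)
        both = sum(
            all(r.correct for r in simulate_trial(agent, trial, behaviors, rng))
            for _ in range(10_000)
        )
        assert both / 10_000 == pytest.approx(0.0625, abs=0.01)

    def test_wrong_responses_uniform_over_other_behaviors(self, behaviors, rng):
        agent = AgentParams("b1", alpha=-50.0)  # never repeats correctly
        trial = PlannedTrial(1, "single_repeat", "wave", 1)
        responses = [
            simulate_trial(agent, trial, behaviors, rng)[0].response
            for _ in range(6000)
        ]
        assert "wave" not in responses
        others = [b for b in behaviors.trained if b != "wave"]
        for b in others:
            assert responses.count(b) / 6000 == pytest.approx(1 / 3, abs=0.03)


class TestStaircaseExperiment:
    def test_always_correct_delays(self, behaviors, rng):
        agent = AgentParams("b1", alpha=50.0)
        plans = build_delayed_block(behaviors, 1, 5, seed=0)
        recs = run_staircase_experiment(agent, plans, StaircaseState(), behaviors, rng)
        assert [r.delay_s for r in recs] == [3.0, 6.0, 9.0, 12.0, 15.0]

    def test_always_wrong_pins_at_floor(self, behaviors, rng):
        agent = AgentParams("b1", alpha=-50.0)
        plans = build_delayed_block(behaviors, 1, 8, seed=0)
        recs = run_staircase_experiment(agent, plans, StaircaseState(), behaviors, rng)
        assert all(r.delay_s == 3.0 for r in recs)

    def test_trajectory_reconstructible(self, behaviors, rng):
        agent = AgentParams("b1", alpha=1.5, beta_slope=-0.8)
        plans = build_delayed_block(behaviors, 2, 16, seed=3)
        recs = run_staircase_experiment(agent, plans, StaircaseState(), behaviors, rng)
        state = StaircaseState()
        from repeatlab.design import staircase_update

        for r in recs:
            assert r.delay_s == state.current_delay_s
            state = staircase_update(state, r.correct)

    def test_stationary_mean_delay_for_decaying_agent(self, behaviors):
        # with a negative slope the staircase equilibrates around the delay
        # where p = 0.5; the long-run mean is stable across seeds
        agent = AgentParams("b1", alpha=2.0, beta_slope=-1.0)
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            plans = build_delayed_block(behaviors, 1, 2000, seed=seed)
            recs = run_staircase_experiment(
                agent, plans, StaircaseState(), behaviors, rng
            )
            means.append(np.mean([r.delay_s for r in recs[400:]]))
        assert max(means) - min(means) < 3.0
        assert np.all(np.isfinite(means))


class TestGenerateStudy:
    def test_row_counts_match_design(self, behaviors):
        agents = [AgentParams.from_success_rate(f"b{i}", 0.75) for i in range(3)]
        df = generate_study(agents, seed=11, behaviors=behaviors)
        per_ind = df.groupby("individual_id")["condition"].value_counts()
        for i in range(3):
            # 8 sessions x (4 singles + 8 doubles x 2 rows + 14 controls)
            assert per_ind[(f"b{i}", "single_repeat")] == 8 * 4
            assert per_ind[(f"b{i}", "double_repeat")] == 8 * 8 * 2
            assert per_ind[(f"b{i}", "delayed_repeat")] == 96
            assert per_ind[(f"b{i}", "criterion_repeat")] == 12

    def test_same_seed_identical_table(self):
        agents = [AgentParams.from_success_rate("b1", 0.6)]
        a = generate_study(agents, seed=5)
        b = generate_study(agents, seed=5)
        assert a.equals(b)
        assert not a.equals(generate_study(agents, seed=6))

    def test_cohort_success_rate_recovers_target(self):
        agents = [AgentParams.from_success_rate(f"b{i}", 0.75) for i in range(3)]
        df = generate_study(
            agents, seed=2, n_repeat_sessions=30,
            n_delayed_sessions=0, include_criterion=False, include_novel=False,
        )
        singles = df[(df["condition"] == "single_repeat")]
        firsts = df[(df["condition"] == "double_repeat") & (df["repeat_position"] == 1)]
        rate = np.concatenate([singles["correct"], firsts["correct"]]).mean()
        assert rate == pytest.approx(0.75, abs=0.02)

    def test_output_passes_schema_validation(self):
        agents = [AgentParams.from_success_rate("b1", 0.8, beta_slope=-0.5)]
        df = generate_study(agents, seed=9)
        validated = validate_trials(df)
        assert len(validated) == len(df)
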