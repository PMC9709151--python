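"""Scoring rules: chance levels, criterion, extraction, novel-probe rule."""

import numpy as np
import pandas as pd
import pytest

from repeatlab.agents import AgentParams, simulate_session
from repeatlab.analysis import (
    ChanceSpec,
    chance_level,
    evaluate_criterion,
    evaluate_novel,
    extract_double_repeats,
    extract_single_repeats,
    load_novel_fixture,
    performance_by,
)
from repeatlab.design import build_criterion_session, build_repeat_session

from _oracles import binomial_tail_at_least, enumerate_chance_level


class TestChanceLevel:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(4, 1, 0.25), (4, 2, 0.0625), (1, 3, 1.0), (3, 1, 1 / 3)],
    )
    def test_closed_form(self, n, k, expected):
        assert chance_level(ChanceSpec(n, k)) == pytest.approx(expected)

    @pytest.mark.parametrize("n,k", [(4, 1), (4, 2), (3, 2), (5, 1)])
    def test_agrees_with_enumeration(self, n, k):
        assert chance_level(ChanceSpec(n, k)) == pytest.approx(
            enumerate_chance_level(n, k)
        )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ChanceSpec(0, 1)


class TestExtractSingleRepeats:
    def test_session_yields_twelve_single_analysis_rows(self, behaviors, rng):
        agent = AgentParams.from_success_rate("b1", 0.75)
        plan = build_repeat_session(behaviors, 1)
        df = pd.DataFrame([vars(r) for r in simulate_session(agent, plan, behaviors, rng)])
        singles = extract_single_repeats(df)
        assert len(singles) == 12  # 4 singles + 8 double-firsts
        assert (singles["condition"] == "single_repeat").all()
        assert (singles["repeat_position"] != 2).all()

    def test_identity_without_doubles(self):
        df = pd.DataFrame(
            {
                "condition": ["single_repeat"] * 3 + ["control"],
                "repeat_position": [1, 1, 1, 0],
                "correct": [1, 0, 1, 1],
            }
        )
        out = extract_single_repeats(df)
        assert len(out) == 3

    def test_double_collapse_requires_both_positions(self, behaviors, rng):
        agent = AgentParams("b1", alpha=50.0)
        plan = build_repeat_session(behaviors, 2)
        df = pd.DataFrame([vars(r) for r in simulate_session(agent, plan, behaviors, rng)])
        doubles = extract_double_repeats(df)
        assert len(doubles) == 8
        assert doubles["correct"].all()  # perfect agent: both positions correct


class TestCriterion:
    @pytest.mark.parametrize("n_correct,passed", [(6, False), (7, True), (12, True)])
    def test_boundary(self, n_correct, passed):
        df = pd.DataFrame(
            {
                "condition": ["criterion_repeat"] * 12,
                "correct": [1] * n_correct + [0] * (12 - n_correct),
            }
        )
        res = evaluate_criterion(df)
        assert res.passed is passed
        assert res.threshold == 7
        assert res.n_correct == n_correct

    def test_generalized_threshold_warns(self):
        df = pd.DataFrame({"condition": ["criterion_repeat"] * 24, "correct": [1] * 24})
        with pytest.warns(UserWarning, match="generalized"):
            res = evaluate_criterion(df)
        assert res.threshold == 14  # ceil(7/12 * 24)

    def test_chance_agent_pass_rate_matches_binomial_tail(self, behaviors):
        """MC pass probability of a guessing agent vs the Bin(12, 1/4) tail."""
        agent = AgentParams("b1", mode="chance")
        rng = np.random.default_rng(99)
        passes = 0
        n_sessions = 4000
        for s in range(n_sessions):
            plan = build_criterion_session(behaviors, s)
            df = pd.DataFrame(
                [vars(r) for r in simulate_session(agent, plan, behaviors, rng)]
            )
            passes += evaluate_criterion(df).passed
        expected = binomial_tail_at_least(12, 7, 0.25)
        mc = passes / n_sessions
        assert mc == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n_sessions))


class TestPerformanceBy:
    def test_all_correct(self):
        df = pd.DataFrame(
            {"individual_id": ["a", "a", "b"], "correct": [1, 1, 1]}
        )
        out = performance_by(df, "individual_id")
        assert (out["proportion"] == 1.0).all()

    def test_chance_singles_pool_to_quarter(self, behaviors, rng):
        from repeatlab.agents import simulate_trial
        from repeatlab.design import PlannedTrial

        agent = AgentParams("b1", mode="chance")
        trial = PlannedTrial(1, "single_repeat", "wave", 1)
        recs = []
        for _ in range(10_000):
            recs.extend(simulate_trial(agent, trial, behaviors, rng))
        df = pd.DataFrame([vars(r) for r in recs]).assign(all="all")
        out = performance_by(df, "all")
        assert out.loc[0, "proportion"] == pytest.approx(0.25, abs=0.015)

    def test_invariant_to_row_order_and_partitioning(self, rng):
        df = pd.DataFrame(
            {
                "individual_id": rng.choice(["a", "b"], 200),
                "session_id": rng.choice(["s1", "s2"], 200),
                "correct": rng.integers(0, 2, 200),
            }
        )
        base = performance_by(df, "individual_id").set_index("individual_id")
        shuffled = performance_by(df.sample(frac=1, random_state=0), "individual_id").set_index("individual_id")
        pd.testing.assert_frame_equal(base, shuffled)
        # partition by session, pool counts, same proportions
        parts = [performance_by(g, "individual_id") for _, g in df.groupby("session_id")]
        pooled = (
            pd.concat(parts)
            .groupby("individual_id")[["n_correct", "n_trials"]]
            .sum()
        )
        assert (pooled["n_correct"] / pooled["n_trials"]).equals(base["proportion"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            performance_by(pd.DataFrame(columns=["correct"]), "correct")


class TestNovelEvaluation:
    def test_fixture_reproduces_published_outcomes(self):
        trials = load_novel_fixture()
        outcomes, per_ind = evaluate_novel(trials)
        assert len(outcomes) == 9
        assert int(outcomes["success"].sum()) == 6
        assert per_ind.to_dict() == {"Charlie": 2, "Gargamel": 2, "Mr Huang": 2}
        by_key = outcomes.set_index(["individual_id", "behavior"])["success"]
        assert bool(by_key[("Charlie", "vocalization")])
        assert bool(by_key[("Charlie", "lift_left_leg")])
        assert not bool(by_key[("Charlie", "move_ring_into_lid")])
        assert not bool(by_key[("Mr Huang", "lift_left_leg")])
        assert not bool(by_key[("Gargamel", "lift_left_leg")])

    def test_erroneous_response_recorded(self):
        trials = load_novel_fixture()
        outcomes, _ = evaluate_novel(trials)
        row = outcomes.set_index(["individual_id", "behavior"]).loc[
            ("Mr Huang", "lift_left_leg")
        ]
        assert row["observed_response"] == "lift_right_leg"
        assert not row["success"]

    def test_one_wrong_trial_fails(self):
        for erroneous_on in ("first", "critical"):
            trials = load_novel_fixture(erroneous_on=erroneous_on)
            outcomes, per_ind = evaluate_novel(trials)
            assert int(outcomes["success"].sum()) == 6
            assert (per_ind == 2).all()
            fail = outcomes.set_index(["individual_id", "behavior"]).loc[
                ("Gargamel", "lift_left_leg")
            ]
            if erroneous_on == "first":
                assert not fail["first_trial_correct"] and fail["critical_trial_correct"]
            else:
                assert fail["first_trial_correct"] and not fail["critical_trial_correct"]

    def test_incomplete_test_rejected(self):
        trials = load_novel_fixture().iloc[:-1]  # drop one critical trial
        with pytest.raises(ValueError, match="incomplete"):
            evaluate_novel(trials)
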