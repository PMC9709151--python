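"""Synthetic response agents for the repeat paradigm.

An agent's probability of repeating its own last action correctly follows
the same logit-linear structure the hierarchical analysis models assume:

    logit(p) = alpha_individual + gamma_behavior [+ beta * log(delay_s)]

where ``alpha`` is the individual's baseline ability on the log-odds scale,
``gamma`` a per-behavior offset (some actions are harder to repeat), and
``beta`` the retention slope against log delay.  A ``chance`` agent ignores
all parameters and picks uniformly among the trained behaviors, which
yields the analytic reference rates of 1/4 for a single repeat and 1/16 for
both repeats of a double-repeat trial.

When a repeat fails, the erroneous response is drawn uniformly from the
remaining trained behaviors — the minimal error model consistent with the
uniform chance level.  Control trials are simulated as compliant
(configurable), since only repeat trials enter the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import (
    BehaviorSet,
    PlannedTrial,
    SessionPlan,
    StaircaseState,
    staircase_update,
)

__all__ = [
    "AgentParams",
    "TrialRecord",
    "success_probability",
    "simulate_trial",
    "simulate_session",
    "run_staircase_experiment",
    "generate_study",
    "records_to_frame",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic subject.

    Parameters
    ----------
    individual_id
        Label used in the output trial table.
    alpha
        Logit-scale baseline repeat ability.
    gamma_by_behavior
        Per-behavior logit offsets; behaviors missing from the map get 0.
    beta_slope
        Logit change per unit log(delay in seconds); negative values give a
        decaying retention curve.  Ignored for undelayed trials.
    mode
        ``"model"`` draws correctness from the logit model; ``"chance"``
        ignores all parameters and responds uniformly over the trained set.
    control_correct_prob
        Compliance on control trials (not analyzed by the models).
    """

    individual_id: str
    alpha: float = 0.0
    gamma_by_behavior: dict[str, float] = field(default_factory=dict)
    beta_slope: float = 0.0
    mode: str = "model"
    control_correct_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("model", "chance"):
            raise ValueError(f"unknown agent mode {self.mode!r}")
        if not all(np.isfinite(v) for v in self.gamma_by_behavior.values()):
            raise ValueError("gamma offsets must be finite")

    @classmethod
    def from_success_rate(cls, individual_id: str, p: float, **kw) -> "AgentParams":
        """Agent whose undelayed repeat success probability is exactly ``p``."""
        return cls(individual_id=individual_id, alpha=float(logit(p)), **kw)


@dataclass(frozen=True)
class TrialRecord:
    """One commanded response, the unit row of the canonical trial table.

    ``repeat_position`` is 0 for control responses, 1 for the (only or
    first) repeat, 2 for the second repeat of a double-repeat trial.  Both
    repeats of a double are scored against the originally commanded action.
    """

    individual_id: str
    session_id: str
    trial_index: int
    condition: str
    action_command: str
    repeat_position: int
    response: str
    correct: bool
    delay_s: float | None = None


def success_probability(
    agent: AgentParams, behavior: str, delay_s: float | None = None
) -> float:
    """Model-mode probability of a correct repeat of ``behavior``.

    Evaluates ``logit⁻¹(alpha + gamma[behavior] + beta * log(delay_s))``,
    dropping the slope term when no delay applies.
    """
    if agent.mode == "chance":
        raise ValueError("chance agents have no model success probability")
    eta = agent.alpha + agent.gamma_by_behavior.get(behavior, 0.0)
    if delay_s is not None:
        if delay_s <= 0:
            raise ValueError("delay must be positive (log-delay model)")
        eta += agent.beta_slope * np.log(delay_s)
    return float(expit(eta))


def _wrong_response(
    correct_behavior: str, trained: tuple[str, ...], rng: np.random.Generator
) -> str:
    others = [b for b in trained if b != correct_behavior]
    return others[int(rng.integers(len(others)))]


def _repeat_response(
    agent: AgentParams,
    behavior: str,
    trained: tuple[str, ...],
    rng: np.random.Generator,
    delay_s: float | None,
) -> tuple[str, bool]:
    if agent.mode == "chance":
        response = trained[int(rng.integers(len(trained)))]
        return response, response == behavior
    p = success_probability(agent, behavior, delay_s)
    if rng.random() < p:
        return behavior, True
    return _wrong_response(behavior, trained, rng), False


def simulate_trial(
    agent: AgentParams,
    trial: PlannedTrial,
    behaviors: BehaviorSet,
    rng: np.random.Generator,
    session_id: str = "s1",
    delay_s: float | None = None,
) -> list[TrialRecord]:
    """Simulate one planned trial, returning one record per scored response.

    Repeat commands produce one record each (two for a double-repeat trial,
    both scored against the original command).  Control trials produce a
    single compliance record with ``repeat_position=0``.
    """
    if trial.condition == "delayed_repeat" and delay_s is None:
        delay_s = trial.planned_delay_s
    records: list[TrialRecord] = []
    if trial.n_repeat_commands == 0:
        ok = rng.random() < agent.control_correct_prob
        response = (
            trial.action_command
            if ok
            else _wrong_response(trial.action_command, behaviors.trained, rng)
        )
        records.append(
            TrialRecord(
                agent.individual_id, session_id, trial.trial_index,
                trial.condition, trial.action_command, 0, response, ok,
            )
        )
        return records
    for pos in range(1, trial.n_repeat_commands + 1):
        response, ok = _repeat_response(
            agent, trial.action_command, behaviors.trained, rng, delay_s
        )
        records.append(
            TrialRecord(
                agent.individual_id, session_id, trial.trial_index,
                trial.condition, trial.action_command, pos, response, ok,
                delay_s if trial.condition == "delayed_repeat" else None,
            )
        )
    return records


def simulate_session(
    agent: AgentParams,
    plan: SessionPlan,
    behaviors: BehaviorSet,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Simulate every trial of a (non-staircase) session plan in order."""
    records: list[TrialRecord] = []
    for trial in plan.trials:
        records.extend(
            simulate_trial(agent, trial, behaviors, rng, session_id=plan.session_id)
        )
    return records


def run_staircase_experiment(
    agent: AgentParams,
    plans: list[SessionPlan],
    state0: StaircaseState,
    behaviors: BehaviorSet,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Run delayed-repeat sessions under the adaptive staircase.

    Each trial is presented at the current staircase delay; the state then
    moves +3 s after a correct response and -3 s after an error (clamped at
    the floor), carrying over across sessions as in the live procedure.
    The full delay trajectory is reconstructible from the emitted records.
    """
    state = state0
    records: list[TrialRecord] = []
    for plan in plans:
        for trial in plan.trials:
            recs = simulate_trial(
                agent, trial, behaviors, rng,
                session_id=plan.session_id, delay_s=state.current_delay_s,
            )
            records.extend(recs)
            state = staircase_update(state, recs[-1].correct)
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Stack trial records into the canonical trial table."""
    df = pd.DataFrame([vars(r) for r in records])
    df["correct"] = df["correct"].astype(int)
    df["delay_s"] = df["delay_s"].astype(float)
    return df


def generate_study(
    agents: list[AgentParams],
    seed: int = 0,
    behaviors: BehaviorSet | None = None,
    n_repeat_sessions: int = 8,
    n_delayed_sessions: int = 6,
    delayed_trials_per_session: int = 16,
    include_criterion: bool = True,
    include_novel: bool = True,
    staircase0: StaircaseState | None = None,
    novel_gamma_sd: float = 0.45,
) -> pd.DataFrame:
    """Simulate a full study and return the analysis-ready trial table.

    Per agent: one criterion session, ``n_repeat_sessions`` repeat-test
    sessions (26 trials each; doubles contribute two rows), a delayed
    block run under the staircase, and one probe session per novel
    behavior.  Novel-behavior logit offsets, when not set explicitly on the
    agent, are drawn once per agent from ``normal(0, novel_gamma_sd)`` —
    the same scale family the hierarchical model places on behavior
    offsets.  Everything derives from ``seed``; identical seeds give
    byte-identical tables.
    """
    from .design import (  # local import to keep module load light
        build_criterion_session,
        build_delayed_block,
        build_novel_test_session,
        build_repeat_session,
    )

    behaviors = behaviors or BehaviorSet()
    root = np.random.SeedSequence(seed)
    agent_seeds = root.spawn(len(agents))
    records: list[TrialRecord] = []
    for agent, agent_seq in zip(agents, agent_seeds):
        streams = agent_seq.spawn(5)
        rng = np.random.default_rng(streams[0])
        plan_seeds = np.random.default_rng(streams[1]).integers(
            0, 2**31 - 1, size=n_repeat_sessions + 2 + len(behaviors.novel)
        )
        if include_criterion:
            plan = build_criterion_session(
                behaviors, int(plan_seeds[0]),
                session_id=f"{agent.individual_id}_criterion",
            )
            records.extend(simulate_session(agent, plan, behaviors, rng))
        for s in range(n_repeat_sessions):
            plan = build_repeat_session(
                behaviors, int(plan_seeds[1 + s]),
                session_id=f"{agent.individual_id}_repeat_{s + 1}",
            )
            records.extend(simulate_session(agent, plan, behaviors, rng))
        if n_delayed_sessions > 0:
            delayed_plans = build_delayed_block(
                behaviors, n_delayed_sessions, delayed_trials_per_session,
                int(plan_seeds[1 + n_repeat_sessions]),
            )
            delayed_plans = [
                SessionPlan(
                    f"{agent.individual_id}_{p.session_id}",
                    p.condition_label, p.trials, p.rng_seed,
                )
                for p in delayed_plans
            ]
            records.extend(
                run_staircase_experiment(
                    agent, delayed_plans, staircase0 or StaircaseState(),
                    behaviors, rng,
                )
            )
        if include_novel:
            novel_rng = np.random.default_rng(streams[2])
            gamma = dict(agent.gamma_by_behavior)
            for b in behaviors.novel:
                gamma.setdefault(b, float(novel_rng.normal(0.0, novel_gamma_sd)))
            novel_agent = AgentParams(
                agent.individual_id, agent.alpha, gamma, agent.beta_slope,
                agent.mode, agent.control_correct_prob,
            )
            for j, b in enumerate(behaviors.novel):
                plan = build_novel_test_session(
                    b, behaviors, int(plan_seeds[2 + n_repeat_sessions + j]),
                    session_id=f"{agent.individual_id}_novel_{b}",
                )
                records.extend(simulate_session(novel_agent, plan, behaviors, rng))
    return records_to_frame(records)
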