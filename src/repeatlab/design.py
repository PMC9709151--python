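"""Session-plan construction for the action-repeat paradigm.

A repeat experiment asks an animal to re-perform its own most recent
commanded action.  Sessions mix *repeat* trials (one or two consecutive
repeat commands) with *control* trials (a second, different action command)
so the subject cannot adopt a blanket "always repeat" strategy.  This module
builds the ordered command lists for every session type used in the study:

* repeat test sessions (26 trials: 4 single repeats, 8 double repeats,
  14 controls),
* the 20-trial testing-criterion session (12 repeat, 8 control),
* delayed-repeat blocks driven by an adaptive ±3 s staircase on the delay
  between the action and the repeat command, and
* novel-behavior probe sessions (first trial with the new behavior, a short
  run of controls, then the critical second trial).

Plans are pure functions of their inputs and an integer seed: the same seed
always yields byte-identical plans.  Behaviors are counterbalanced within a
session by balanced blocks (each behavior equally often per condition where
the counts divide evenly, any remainder assigned at random) before the trial
order is shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorSet",
    "PlannedTrial",
    "SessionPlan",
    "StaircaseState",
    "InvalidDesignError",
    "CONDITIONS",
    "build_repeat_session",
    "build_criterion_session",
    "build_delayed_block",
    "build_novel_test_session",
    "staircase_update",
]

#: Allowed trial-condition labels, shared with the simulator and the schema.
CONDITIONS = (
    "control",
    "single_repeat",
    "double_repeat",
    "criterion_repeat",
    "delayed_repeat",
    "novel_first",
    "novel_critical",
)

#: Default behavior labels.  The trained set has four entries (the main
#: experiment's size); the novel set has the three generalization-probe
#: behaviors.  'head_shake' is the trained action reported as hardest to
#: repeat, kept first so per-behavior offsets are easy to address.
DEFAULT_TRAINED = ("head_shake", "wave", "turn", "flap")
DEFAULT_NOVEL = ("vocalization", "lift_left_leg", "move_ring_into_lid")


class InvalidDesignError(ValueError):
    """Raised when a session plan cannot be built from the given inputs."""


@dataclass(frozen=True)
class BehaviorSet:
    """The trained command repertoire plus the novel probe behaviors.

    Parameters
    ----------
    trained
        Ordered labels of the behaviors the subject performs on command
        during the main experiment (four in the reference design).
    novel
        Ordered labels of the newly trained behaviors used only in the
        generalization probes; must be disjoint from ``trained``.
    """

    trained: tuple[str, ...] = DEFAULT_TRAINED
    novel: tuple[str, ...] = DEFAULT_NOVEL

    def __post_init__(self) -> None:
        object.__setattr__(self, "trained", tuple(self.trained))
        object.__setattr__(self, "novel", tuple(self.novel))
        labels = self.trained + self.novel
        if len(set(labels)) != len(labels):
            raise InvalidDesignError("behavior labels must be unique")
        if len(self.trained) < 2:
            raise InvalidDesignError("need at least two trained behaviors")

    @property
    def n_trained(self) -> int:
        return len(self.trained)


@dataclass(frozen=True)
class PlannedTrial:
    """One planned trial: an action command plus zero, one or two repeats."""

    trial_index: int  # 1-based position within the session
    condition: str
    action_command: str
    n_repeat_commands: int
    planned_delay_s: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidDesignError(f"unknown condition {self.condition!r}")
        expected = {"control": 0, "double_repeat": 2}.get(self.condition, 1)
        if self.n_repeat_commands != expected:
            raise InvalidDesignError(
                f"{self.condition} trials carry {expected} repeat command(s), "
                f"got {self.n_repeat_commands}"
            )


@dataclass(frozen=True)
class SessionPlan:
    """An ordered, seeded list of planned trials for one session."""

    session_id: str
    condition_label: str
    trials: tuple[PlannedTrial, ...]
    rng_seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the plan CSV schema (one row per trial)."""
        return pd.DataFrame(
            {
                "session_id": self.session_id,
                "trial_index": [t.trial_index for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "action_command": [t.action_command for t in self.trials],
                "n_repeat_commands": [t.n_repeat_commands for t in self.trials],
                "planned_delay_s": [t.planned_delay_s for t in self.trials],
            }
        )


@dataclass(frozen=True)
class StaircaseState:
    """Adaptive-delay state: delay climbs 3 s on success, drops 3 s on error.

    The floor keeps the delay strictly positive (log-delay must stay
    defined for the retention model) and matches the 3 s grid of the
    procedure; there is no ceiling by default.
    """

    current_delay_s: float = 3.0
    step_s: float = 3.0
    floor_s: float = 3.0
    ceiling_s: float | None = None

    def __post_init__(self) -> None:
        if self.step_s <= 0 or self.floor_s <= 0:
            raise InvalidDesignError("staircase step and floor must be positive")
        if self.current_delay_s < self.floor_s:
            raise InvalidDesignError("delay below floor")
        if self.ceiling_s is not None and self.ceiling_s < self.floor_s:
            raise InvalidDesignError("ceiling below floor")


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase one trial: +step on a correct response,
    -step on an incorrect one, clamped to ``[floor_s, ceiling_s]``."""
    delta = state.step_s if correct else -state.step_s
    new_delay = state.current_delay_s + delta
    new_delay = max(new_delay, state.floor_s)
    if state.ceiling_s is not None:
        new_delay = min(new_delay, state.ceiling_s)
    return replace(state, current_delay_s=new_delay)


def _balanced_assignment(
    labels: tuple[str, ...], n_slots: int, rng: np.random.Generator
) -> list[str]:
    """Assign labels to slots in balanced blocks: each label floor(n/k)
    times, the remainder chosen without replacement at random."""
    k = len(labels)
    out = list(labels) * (n_slots // k)
    remainder = n_slots % k
    if remainder:
        out.extend(str(x) for x in rng.choice(labels, size=remainder, replace=False))
    return out


def _assemble(
    session_id: str,
    condition_label: str,
    seed: int,
    groups: list[tuple[str, int, list[str]]],
    rng: np.random.Generator,
) -> SessionPlan:
    """Build trials from (condition, n_repeats, commands) groups and shuffle."""
    proto: list[tuple[str, int, str]] = []
    for condition, n_rep, commands in groups:
        proto.extend((condition, n_rep, c) for c in commands)
    order = rng.permutation(len(proto))
    trials = tuple(
        PlannedTrial(
            trial_index=i + 1,
            condition=proto[j][0],
            action_command=proto[j][2],
            n_repeat_commands=proto[j][1],
        )
        for i, j in enumerate(order)
    )
    return SessionPlan(session_id, condition_label, trials, seed)


def build_repeat_session(
    behaviors: BehaviorSet, seed: int, session_id: str | None = None
) -> SessionPlan:
    """Plan one 26-trial repeat-test session.

    Composition: 4 single-repeat, 8 double-repeat and 10 control trials per
    the stated design, padded with 4 extra control trials to reach the
    stated 26-trial session length (the listed counts sum to 22).  Action
    commands are counterbalanced across the four trained behaviors: each
    behavior appears exactly once as a single-repeat and twice as a
    double-repeat action per session.
    """
    if behaviors.n_trained != 4:
        raise InvalidDesignError(
            f"repeat sessions require 4 trained behaviors, got {behaviors.n_trained}"
        )
    rng = np.random.default_rng(seed)
    singles = _balanced_assignment(behaviors.trained, 4, rng)
    doubles = _balanced_assignment(behaviors.trained, 8, rng)
    controls = _balanced_assignment(behaviors.trained, 14, rng)
    return _assemble(
        session_id or f"repeat_s{seed}",
        "repeat",
        seed,
        [
            ("single_repeat", 1, singles),
            ("double_repeat", 2, doubles),
            ("control", 0, controls),
        ],
        rng,
    )


def build_criterion_session(
    behaviors: BehaviorSet, seed: int, session_id: str | None = None
) -> SessionPlan:
    """Plan the 20-trial testing-criterion session: 12 trials end in a
    repeat command (60%), 8 are controls where a second behavior command
    follows the first (40%).  Behavior command frequencies are balanced
    (12/4 and 8/4 divide evenly, so exactly 3 + 2 per behavior)."""
    if behaviors.n_trained != 4:
        raise InvalidDesignError(
            f"criterion sessions require 4 trained behaviors, got {behaviors.n_trained}"
        )
    rng = np.random.default_rng(seed)
    repeats = _balanced_assignment(behaviors.trained, 12, rng)
    controls = _balanced_assignment(behaviors.trained, 8, rng)
    return _assemble(
        session_id or f"criterion_s{seed}",
        "criterion",
        seed,
        [("criterion_repeat", 1, repeats), ("control", 0, controls)],
        rng,
    )


def build_delayed_block(
    behaviors: BehaviorSet,
    n_sessions: int = 6,
    trials_per_session: int = 16,
    seed: int = 0,
) -> list[SessionPlan]:
    """Plan the delayed-repeat block: single repeat trials only, by default
    6 sessions of 16 trials.  ``planned_delay_s`` is left unset; the actual
    delay of each trial is resolved at run time by the staircase."""
    if n_sessions <= 0 or trials_per_session <= 0:
        raise InvalidDesignError("session and trial counts must be positive")
    root = np.random.SeedSequence(seed)
    plans = []
    for s, child in enumerate(root.spawn(n_sessions), start=1):
        rng = np.random.default_rng(child)
        commands = _balanced_assignment(behaviors.trained, trials_per_session, rng)
        plans.append(
            _assemble(
                f"delayed_s{s}",
                "delayed",
                seed,
                [("delayed_repeat", 1, commands)],
                rng,
            )
        )
    return plans


def build_novel_test_session(
    novel_behavior: str,
    behaviors: BehaviorSet,
    seed: int,
    session_id: str | None = None,
) -> SessionPlan:
    """Plan one novel-behavior probe session.

    Trial 1 commands the new behavior followed by a repeat command; then
    2-4 control trials with trained behaviors (the run length drawn
    uniformly); then the critical trial commands the new behavior followed
    by a repeat command again.  The probe order is fixed by the procedure,
    so only the control commands and run length are randomized.
    """
    if novel_behavior not in behaviors.novel:
        raise InvalidDesignError(f"{novel_behavior!r} is not a novel behavior")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    controls = _balanced_assignment(behaviors.trained, k, rng)
    trials = [PlannedTrial(1, "novel_first", novel_behavior, 1)]
    trials += [
        PlannedTrial(i + 2, "control", c, 0) for i, c in enumerate(controls)
    ]
    trials.append(PlannedTrial(k + 2, "novel_critical", novel_behavior, 1))
    return SessionPlan(
        session_id or f"novel_{novel_behavior}_s{seed}",
        "novel",
        tuple(trials),
        seed,
    )
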