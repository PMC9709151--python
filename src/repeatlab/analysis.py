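"""Derived scoring rules and descriptive statistics for repeat experiments.

Covers the non-model analysis layer: analytic chance levels, the
pre-test reliability criterion (at least 7 of 12 correct repeats), the
single-repeat extraction rule (the first repeat of a double-repeat trial
counts as a single-repeat observation), grouped success proportions, and
the two-trial success rule of the novel-behavior generalization probe.

A small packaged fixture (``data/novel_behavior_table.csv``) encodes the
published outcome table of the novel-behavior test — three macaws, three
novel behaviors, six successes (two per bird) — so the scoring rules have
an executable worked example.  The fixture is a synthetic per-trial
encoding inferred from the published per-behavior outcomes: a "Success"
row implies both repeat trials were correct; a failure row names the
erroneous response that was observed, without recording which of the two
repeat trials it occurred on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from math import ceil

import numpy as np
import pandas as pd

__all__ = [
    "ChanceSpec",
    "NovelOutcome",
    "CriterionResult",
    "chance_level",
    "extract_single_repeats",
    "extract_double_repeats",
    "evaluate_criterion",
    "performance_by",
    "evaluate_novel",
    "load_novel_fixture",
]


@dataclass(frozen=True)
class ChanceSpec:
    """Chance-level specification: uniform guessing over ``n_behaviors``
    must match the commanded action ``n_matches_required`` times."""

    n_behaviors: int = 4
    n_matches_required: int = 1

    def __post_init__(self) -> None:
        if self.n_behaviors < 1 or self.n_matches_required < 1:
            raise ValueError("counts must be >= 1")


def chance_level(spec: ChanceSpec) -> float:
    """Probability that uniform guessing succeeds: (1/n)^k.

    k=1 gives the single-repeat reference of 1/4 (25%), k=2 the
    double-repeat reference of 1/16 (6.25%) for a four-behavior repertoire.
    """
    return (1.0 / spec.n_behaviors) ** spec.n_matches_required


def extract_single_repeats(trials: pd.DataFrame) -> pd.DataFrame:
    """Build the single-repeat analysis table.

    Keeps all ``single_repeat`` rows and the first-position rows of
    ``double_repeat`` trials (relabelled ``single_repeat``); the
    second-position rows are excluded — they form the double-repeat
    analysis, scored separately.
    """
    singles = trials[trials["condition"] == "single_repeat"]
    firsts = trials[
        (trials["condition"] == "double_repeat") & (trials["repeat_position"] == 1)
    ].copy()
    firsts["condition"] = "single_repeat"
    out = pd.concat([singles, firsts], ignore_index=True)
    return out


def extract_double_repeats(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse double-repeat trials to one row per trial, correct only if
    both repeat positions matched the original command."""
    dd = trials[trials["condition"] == "double_repeat"]
    if dd.empty:
        return dd.copy()
    keys = ["individual_id", "session_id", "trial_index"]
    agg = dd.groupby(keys, sort=False).agg(
        condition=("condition", "first"),
        action_command=("action_command", "first"),
        n_positions=("repeat_position", "count"),
        correct=("correct", "min"),
    )
    if (agg["n_positions"] != 2).any():
        raise ValueError("double-repeat trials must have exactly two positions")
    return agg.drop(columns="n_positions").reset_index()


@dataclass(frozen=True)
class CriterionResult:
    n_correct: int
    n_repeat_trials: int
    threshold: int
    passed: bool


def evaluate_criterion(session_trials: pd.DataFrame) -> CriterionResult:
    """Apply the testing criterion to one criterion session.

    The rule: at least 7 of the 12 repeat trials (58%) must be correct.
    If the session does not contain exactly 12 repeat trials a warning is
    raised and the rule generalizes to ``>= ceil(7/12 * n)`` — an
    extension beyond the published design, flagged as such.
    """
    reps = session_trials[session_trials["condition"] == "criterion_repeat"]
    n = len(reps)
    if n == 0:
        raise ValueError("no criterion_repeat trials in session")
    if n == 12:
        threshold = 7
    else:
        threshold = ceil(7 / 12 * n)
        warnings.warn(
            f"criterion session has {n} repeat trials (expected 12); "
            f"generalized threshold >= {threshold} applied",
            stacklevel=2,
        )
    n_correct = int(reps["correct"].sum())
    return CriterionResult(n_correct, n, threshold, n_correct >= threshold)


def performance_by(trials: pd.DataFrame, grouping: list[str] | str) -> pd.DataFrame:
    """Success proportions per group.

    ``grouping`` is any subset of {"individual_id", "action_command",
    "condition", "delay_s"} (or other table columns).  Returns one row per
    group with ``n_correct``, ``n_trials`` and ``proportion``; pooling is
    at trial level (unweighted).
    """
    if trials.empty:
        raise ValueError("empty trial table")
    if isinstance(grouping, str):
        grouping = [grouping]
    out = (
        trials.groupby(grouping, dropna=False)["correct"]
        .agg(n_correct="sum", n_trials="count")
        .reset_index()
    )
    out["proportion"] = out["n_correct"] / out["n_trials"]
    return out


@dataclass(frozen=True)
class NovelOutcome:
    individual_id: str
    behavior: str
    first_trial_correct: bool
    critical_trial_correct: bool
    observed_response: str
    success: bool


def evaluate_novel(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Score the novel-behavior probes by the two-trial rule.

    Each individual x novel behavior must contribute exactly one
    ``novel_first`` and one ``novel_critical`` record; success requires a
    correct repeat on both.  Returns the per-probe outcome table and the
    per-individual count of successful novel behaviors.
    """
    probes = trials[trials["condition"].isin(["novel_first", "novel_critical"])]
    rows = []
    for (ind, beh), grp in probes.groupby(["individual_id", "action_command"]):
        by_cond = grp.set_index("condition")
        if set(by_cond.index) != {"novel_first", "novel_critical"} or len(grp) != 2:
            raise ValueError(
                f"incomplete novel test for {ind}/{beh}: need exactly one "
                "novel_first and one novel_critical record"
            )
        first_ok = bool(by_cond.loc["novel_first", "correct"])
        crit_ok = bool(by_cond.loc["novel_critical", "correct"])
        rows.append(
            NovelOutcome(
                individual_id=ind,
                behavior=beh,
                first_trial_correct=first_ok,
                critical_trial_correct=crit_ok,
                observed_response=str(by_cond.loc["novel_critical", "response"]),
                success=first_ok and crit_ok,
            )
        )
    outcomes = pd.DataFrame([vars(r) for r in rows])
    per_individual = outcomes.groupby("individual_id")["success"].sum()
    return outcomes, per_individual


def load_novel_fixture(erroneous_on: str = "both") -> pd.DataFrame:
    """Load the packaged novel-behavior outcome table as trial records.

    Expands each per-behavior outcome row into the two probe trials.  For
    non-success rows the published table only names the erroneous response,
    not which probe trial it occurred on; ``erroneous_on`` places it on
    ``"both"`` (default), ``"first"`` or ``"critical"`` — the success flag
    is unaffected either way, since success requires both trials correct.
    """
    if erroneous_on not in ("both", "first", "critical"):
        raise ValueError("erroneous_on must be 'both', 'first' or 'critical'")
    with resources.files("repeatlab.data").joinpath(
        "novel_behavior_table.csv"
    ).open() as fh:
        table = pd.read_csv(fh)
    rows = []
    for _, r in table.iterrows():
        success = r["result"].strip().lower() == "success"
        for cond in ("novel_first", "novel_critical"):
            if success:
                response, ok = r["behavior"], True
            else:
                wrong_here = (
                    erroneous_on == "both"
                    or (erroneous_on == "first" and cond == "novel_first")
                    or (erroneous_on == "critical" and cond == "novel_critical")
                )
                response = r["observed_response"] if wrong_here else r["behavior"]
                ok = response == r["behavior"]
            rows.append(
                {
                    "individual_id": r["animal_id"],
                    "session_id": f"novel_{r['behavior']}",
                    "trial_index": 1 if cond == "novel_first" else 2,
                    "condition": cond,
                    "action_command": r["behavior"],
                    "repeat_position": 1,
                    "response": response,
                    "correct": int(ok),
                    "delay_s": np.nan,
                    "testing_date": r["testing_date"],
                }
            )
    return pd.DataFrame(rows)
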