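"""Run configuration: agents, model priors, sampler and staircase settings.

A :class:`RunConfig` fully determines a pipeline run (together with its
seed), and serializes to/from YAML so the run log alone suffices to
reproduce a run.  See ``default_config`` for a complete annotated example
of the file format.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .agents import AgentParams
from .design import DEFAULT_NOVEL, DEFAULT_TRAINED, BehaviorSet, StaircaseState
from .models import DelayModelSpec, McmcConfig, RepeatModelSpec

__all__ = ["RunConfig", "default_config"]


@dataclass
class RunConfig:
    """Everything needed to run design -> simulate -> fit -> analyze."""

    seed: int = 1
    trained_behaviors: list[str] = field(default_factory=lambda: list(DEFAULT_TRAINED))
    novel_behaviors: list[str] = field(default_factory=lambda: list(DEFAULT_NOVEL))
    # one block per synthetic subject; see AgentParams for field meanings
    agents: list[dict] = field(
        default_factory=lambda: [
            {"individual_id": "Bird1", "alpha": 1.1, "beta_slope": -0.6},
            {"individual_id": "Bird2", "alpha": 1.1, "beta_slope": -0.6},
            {"individual_id": "Bird3", "alpha": 1.1, "beta_slope": -0.6},
        ]
    )
    n_repeat_sessions: int = 8
    n_delayed_sessions: int = 6
    delayed_trials_per_session: int = 16
    staircase_start_s: float = 3.0
    staircase_step_s: float = 3.0
    staircase_floor_s: float = 3.0
    mcmc: dict = field(
        default_factory=lambda: {"n_chains": 4, "n_iterations": 8000, "n_warmup": 500}
    )
    single_prior_mean: float = -0.5
    double_prior_mean: float = -1.0
    delay_prior_mean: float = -1.0
    out_dir: str = "repeatlab_out"

    # -- constructors -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- derived objects ----------------------------------------------
    def behavior_set(self) -> BehaviorSet:
        return BehaviorSet(tuple(self.trained_behaviors), tuple(self.novel_behaviors))

    def agent_params(self) -> list[AgentParams]:
        return [AgentParams(**block) for block in self.agents]

    def staircase_state(self) -> StaircaseState:
        return StaircaseState(
            current_delay_s=self.staircase_start_s,
            step_s=self.staircase_step_s,
            floor_s=self.staircase_floor_s,
        )

    def mcmc_config(self) -> McmcConfig:
        return McmcConfig(seed=self.seed, **self.mcmc)

    def single_spec(self) -> RepeatModelSpec:
        return RepeatModelSpec(prior_alpha_bar_mean=self.single_prior_mean)

    def double_spec(self) -> RepeatModelSpec:
        return RepeatModelSpec(prior_alpha_bar_mean=self.double_prior_mean)

    def delay_spec(self) -> DelayModelSpec:
        return DelayModelSpec(prior_alpha_bar_mean=self.delay_prior_mean)


def default_config() -> RunConfig:
    """The reference-scale configuration: three subjects with ~75%
    undelayed repeat ability (logit 1.1) and a decaying retention slope."""
    return RunConfig()
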