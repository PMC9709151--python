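import numpy as np
import pandas as pd
import pytest

from repeatlab.design import BehaviorSet
from repeatlab.models import McmcConfig


@pytest.fixture(scope="session")
def behaviors() -> BehaviorSet:
    return BehaviorSet()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quick_mcmc() -> McmcConfig:
    """Reduced sampler settings for test-speed fits."""
    return McmcConfig(n_chains=4, n_iterations=1500, n_warmup=500, seed=7)


def single_cell_trials(n: int, k: int) -> pd.DataFrame:
    """n Bernoulli repeat trials, k correct, one individual and behavior."""
    return pd.DataFrame(
        {
            "individual_id": ["bird_1"] * n,
            "action_command": ["wave"] * n,
            "condition": ["single_repeat"] * n,
            "correct": [1] * k + [0] * (n - k),
        }
    )
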