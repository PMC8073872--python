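import numpy as np
import pandas as pd
import pytest

from aphasia_cea import (LifeTable, ModelSpec, TrialConfig, generate_life_table,
                         generate_trial, synthetic_5l_valueset)


@pytest.fixture(scope="session")
def valueset5l():
    return synthetic_5l_valueset()


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table(start_age=55, terminal_age=100)


@pytest.fixture(scope="session")
def model_spec():
    return ModelSpec()


@pytest.fixture(scope="session")
def small_trial():
    """A modest trial reused across read-only tests."""
    cfg = TrialConfig(n_per_arm=150, seed=11)
    return cfg, generate_trial(cfg)


@pytest.fixture(scope="session")
def big_trial():
    """A large trial for parameter-recovery checks (3-SD binomial bands)."""
    cfg = TrialConfig(n_per_arm=5000, seed=7)
    return cfg, generate_trial(cfg)


@pytest.fixture()
def toy_utility_frame():
    """Six records with hand-computable utility changes.

    Responders' mean change from baseline is 0.05, non-responders' 0.03,
    so the good-response increment is 0.02 by hand.
    """
    return pd.DataFrame({
        "u_0": [0.50, 0.60, 0.70, 0.50, 0.60, 0.70],
        "u_12": [0.54, 0.65, 0.76, 0.53, 0.63, 0.73],
        "resp_obs_12": [True, True, True, False, False, False],
    })
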