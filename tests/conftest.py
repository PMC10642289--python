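import numpy as np
import pandas as pd
import pytest

from dmcflank import DMCParams, SimOptions, simulate_condition

# Published group-level parameter sets of the mu_t-only model (the generating
# truth used throughout the recovery and direction tests).
EXP1_SHARED = dict(A=13.8, tau=249.0, b=74.5, mu_r=408.0, sigma_r=38.0)
EXP2_SHARED = dict(A=17.8, tau=254.0, b=72.8, mu_r=413.0, sigma_r=38.0)
EXP1_MU_T = {"same": 0.58, "different": 0.62}
EXP2_MU_T = {"same": 0.58, "different": 0.64}


def exp1_params(condition: str) -> DMCParams:
    return DMCParams(mu_t=EXP1_MU_T[condition], **EXP1_SHARED)


def exp2_params(condition: str) -> DMCParams:
    return DMCParams(mu_t=EXP2_MU_T[condition], **EXP2_SHARED)


@pytest.fixture(scope="session")
def exp1_same() -> DMCParams:
    return exp1_params("same")


@pytest.fixture(scope="session")
def sim_options() -> SimOptions:
    return SimOptions()


@pytest.fixture(scope="session")
def small_condition_tables(exp1_same):
    """Both congruencies of one condition, 2000 trials each, fixed seed."""
    rng = np.random.default_rng(1234)
    tabs = {
        cong: simulate_condition(exp1_same, cong, 2000, rng=rng)
        for cong in ("congruent", "incongruent")
    }
    return tabs


@pytest.fixture(scope="session")
def small_trials(small_condition_tables):
    return pd.concat(small_condition_tables.values(), ignore_index=True)
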