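import numpy as np
import pandas as pd
import pytest

from diallelkit import make_design, simulate_genetics, simulate_trial
from diallelkit.design import cross_id


@pytest.fixture(scope="session")
def design6():
    """Small half-diallel: 6 parents, 15 crosses, 2 envs x 2 reps."""
    return make_design(6, n_env=2, n_rep=2, block_size=5)


@pytest.fixture(scope="session")
def design21():
    """Study-sized half-diallel: 21 parents, 210 crosses, 2 envs x 2 reps."""
    return make_design(21, n_env=2, n_rep=2, block_size=10)


@pytest.fixture(scope="session")
def plots6(design6):
    gen = simulate_genetics(
        design6, var_gca=0.4, var_sca=0.2, var_env=1.0, var_gca_env=0.1,
        var_sca_env=0.1, seed=11, mu=10.0, var_block=0.3, var_error=0.8,
    )
    return gen, simulate_trial(design6, gen, seed=12)


def genetic_means(genetics, design, env=None):
    """True entry means (averaged over envs when env is None)."""
    eff = next(iter(genetics.traits.values()))
    envs = list(design.environments) if env is None else [env]
    vals = {}
    for a, b in design.crosses:
        vals[cross_id(a, b)] = np.mean([eff.genetic_value(a, b, e) for e in envs])
    return pd.Series(vals)
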