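import numpy as np
import pytest

from gazerl import ModelSpec, Variant, run_replicates

# Shared study conditions: 200 seeds, 2,000 trials, Table-1 defaults.
N_SEEDS = 200
SEEDS = list(range(N_SEEDS))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240213)


def _spec(variant, **kw):
    return ModelSpec(variant=variant, **kw)


@pytest.fixture(scope="session")
def cue_ensemble():
    return run_replicates(_spec(Variant.CUE), SEEDS)


@pytest.fixture(scope="session")
def independent_ensemble():
    return run_replicates(_spec(Variant.INDEPENDENT_STATE), SEEDS)


@pytest.fixture(scope="session")
def enhancement_ensemble():
    return run_replicates(_spec(Variant.ENHANCEMENT), SEEDS)


@pytest.fixture(scope="session")
def enhancement_m02_ensemble():
    return run_replicates(_spec(Variant.ENHANCEMENT, motivation=-0.2), SEEDS)


@pytest.fixture(scope="session")
def baseline_ensemble():
    # the baseline has no stochastic term in the value recursion, so a
    # handful of seeds is enough (all trajectories coincide)
    return run_replicates(_spec(Variant.BASELINE), list(range(5)))
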