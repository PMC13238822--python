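import numpy as np
import pytest

import rebuildsim as rs


@pytest.fixture(scope="session")
def lingcod():
    return rs.default_parameters()[0]


@pytest.fixture(scope="session")
def yelloweye():
    return rs.default_parameters()[1]


@pytest.fixture(scope="session")
def lingcod_sched(lingcod):
    return rs.build_schedules(lingcod)


@pytest.fixture(scope="session")
def yelloweye_sched(yelloweye):
    return rs.build_schedules(yelloweye)


@pytest.fixture(scope="session")
def system():
    """Fully calibrated default system (q-scale conditioning included)."""
    return rs.System()


@pytest.fixture(scope="session")
def scenario_runs(system):
    """Shared cache of stochastic scenario runs used across test modules.

    50 replicates per scenario keeps the suite fast while leaving Monte-Carlo
    error well inside the tolerances asserted on scenario contrasts.
    """
    cache = {}

    def get(gamma, F, b=0.05, n=50, seed=1):
        key = (round(gamma, 9), round(F, 9), round(b, 9), n, seed)
        if key not in cache:
            spec = rs.ScenarioSpec(gamma=gamma, F=F, b=b, n_replicates=n, seed=seed)
            cache[key] = rs.run_scenario(system, spec)
        return cache[key]

    return get


def summarize(result, window=150):
    from rebuildsim.io import summarize_scenario

    return summarize_scenario(result, window=window)


@pytest.fixture(scope="session")
def toy_kernel():
    """Single predator class, single prey age, hand-set rates."""

    def make(a=2.0, delta=0.3, q=0.0, gamma=0.05):
        return rs.PredationKernel(
            a=np.array([[a]]),
            pref=np.array([[1.0]]),
            delta=delta,
            q=q,
            gamma=gamma,
            pred_age=np.array([1]),
            pred_sex=np.array([0]),
            reference_prey=np.array([1.0]),
        )

    return make
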