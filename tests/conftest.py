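"""Shared fixtures: simulated runs are expensive, so the canonical
nominal and variable-legitimacy tables are session-scoped and reused by
unit, property and acceptance tests alike."""

import numpy as np
import pytest

import edmcontrol as ec

SEED = 1


@pytest.fixture(scope="session")
def nominal_table():
    """4000-step punctuated-equilibrium run (constant L=0.82, P=0.1)."""
    cfg = ec.RunConfig(seed=SEED, scenario="nominal", run_length=4000,
                       model=ec.ModelParams(run_length=4000))
    return ec.run_scenario(cfg)


@pytest.fixture(scope="session")
def benchmark_table():
    """3100-step variable-legitimacy run used by the forecast benchmark."""
    from edmcontrol.experiments import forecast_benchmark_config

    return ec.run_scenario(forecast_benchmark_config(SEED))


@pytest.fixture(scope="session")
def logistic_table():
    return ec.make_fixture(ec.FixtureSpec("logistic_map", length=600))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def random_library(rng, n_rows=None, E=None):
    """Small random state-space library for geometry tests."""
    n = n_rows or int(rng.integers(5, 200))
    E = E or int(rng.integers(1, 7))
    spec = ec.EmbeddingSpec(tuple((f"c{i}", 0) for i in range(E)),
                            target="c0", Tp=1)
    rows = rng.normal(size=(n, E))
    futures = rng.normal(size=n)
    times = np.arange(n, dtype=np.int64)
    return ec.StateSpaceLibrary(rows, times, futures, spec)
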