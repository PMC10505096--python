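import numpy as np
import pytest

from tbcperm import datasets, synth, tbc, trajio


@pytest.fixture(scope="session")
def records18():
    return datasets.load_compound_records()


@pytest.fixture(scope="session")
def langevin_dg3():
    """One moderately long Langevin run (3 kT barrier), shared read-only.

    500 ns of 64 solutes: enough crossings for rate statistics and enough
    samples for a usable free-energy profile.
    """
    spec = synth.SyntheticSpec(
        barrier_height=3.0,
        n_solutes=64,
        n_steps=100_000,
        dt=0.005,
        record_stride=2,
        seed=42,
    )
    series = trajio.recentre_and_wrap(synth.simulate_langevin(spec))
    return spec, series


@pytest.fixture(scope="session")
def langevin_events(langevin_dg3):
    spec, series = langevin_dg3
    geom = tbc.estimate_membrane_geometry(series)
    return spec, series, tbc.detect_crossings(series, geom)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
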