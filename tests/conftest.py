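import numpy as np
import pytest

import paracable as pc
from paracable.cable import Biophysics, SolverConfig
from paracable.disruption import simulate_geometry
from paracable.synthetic import gen_disruption_fixture


@pytest.fixture(scope="session")
def fibre_table():
    return pc.builtin_fibre_table()


@pytest.fixture(scope="session")
def mini_fixture():
    """Small 7-node axon for fast solver tests."""
    return gen_disruption_fixture()


@pytest.fixture(scope="session")
def mini_config():
    """Coarse but stable solver settings for the mini fixture."""
    return SolverConfig(dt_ms=0.002, t_end_ms=4.0)


@pytest.fixture(scope="session")
def mini_run(mini_fixture, mini_config):
    """One baseline simulation of the mini fixture (trace, conduction result)."""
    trace, result = simulate_geometry(
        mini_fixture.baseline_geometry,
        config=mini_config,
        nodes=(2, 6),
    )
    return trace, result
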