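import numpy as np
import pytest

from supracg import engine
from supracg.model import SystemSpec, build_system
from supracg.synthetic import scripted_scenarios


@pytest.fixture(scope="session")
def scenarios():
    return scripted_scenarios()


@pytest.fixture(scope="session")
def m10_system():
    """Minimised 10-monomer M system at the stock concentration."""
    spec = SystemSpec(counts={"M": 10}, box_edge=5.99, seed=1)
    return engine.minimise(build_system(spec))


@pytest.fixture(scope="session")
def m10_short_traj(m10_system):
    """2 ns Langevin run of the 10-monomer M system (frames every 20 ps)."""
    params = engine.IntegratorParams(seed=11)
    return engine.run(m10_system, params, n_steps=100_000,
                      sample_every_ps=20.0)


@pytest.fixture(scope="session")
def free_gas_traj():
    """1 ns run of 500 non-interacting beads (thermostat/diffusion oracle)."""
    system = engine.free_particle_system(500, 10.0, seed=4)
    params = engine.IntegratorParams(seed=9)
    return engine.run(system, params, n_steps=50_000, sample_every_ps=10.0)
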