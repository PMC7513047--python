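import numpy as np
import pytest

import activeblend as ab


@pytest.fixture(scope="session")
def ff():
    return ab.ForceField()


@pytest.fixture(scope="session")
def small_melt():
    """Equilibrated 160-monomer melt at T = 1 (4 chains of 40)."""
    return ab.initialize_melt(M=4, N=40, density=0.85, seed=3)


@pytest.fixture(scope="session")
def two_phase_traj():
    """Sharp two-phase slab ensemble with pure phases and Maxwell subsets."""
    spec = ab.TwoPhaseSpec(box=(12.0, 12.0, 30.0), interfaces=(7.5, 22.5),
                           rho_hot_phase=0.78, rho_cold_phase=0.92,
                           T_hot_species=2.6, T_cold_species=1.2)
    return ab.make_two_phase_trajectory(spec, n_snapshots=6, seed=100)


def free_particle(species=ab.HOT, box_length=10.0, v=(0.0, 0.0, 0.0)):
    """Single unbonded particle, for thermostat and ballistic checks."""
    return ab.SystemState(
        positions=np.array([[1.0, 2.0, 3.0]]),
        velocities=np.array([list(v)], dtype=float),
        species=np.array([species], dtype=np.int8),
        chain_id=np.array([0], dtype=np.int32),
        box=ab.SimulationBox(np.full(3, box_length)),
    )
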