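"""Shared fixtures: small, fast, seed-fixed systems."""

import numpy as np
import pytest

from condrheo.engine import (IntegratorConfig, PairTable, Simulation,
                             SimulationState, initialize_velocities)
from condrheo.phase_diagram import build_bulk
from condrheo.potentials import (BondSpec, PairPotentialSpec,
                                 linear_chain_topology)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def lj_spec():
    return PairPotentialSpec(kind="lj_truncated", epsilon=1.0, sigma=1.0,
                             cutoff=3.0)


@pytest.fixture
def lj_fluid_100(rng):
    """100-particle LJ fluid at rho* = 0.5, equilibrated briefly."""
    n, rho = 100, 0.5
    L = (n / rho) ** (1 / 3)
    m = int(np.ceil(n ** (1 / 3)))
    grid = np.array([(x, y, z) for x in range(m) for y in range(m)
                     for z in range(m)][:n], float) * (L / m) + 0.1
    st = SimulationState(grid, np.zeros((n, 3)), np.array([L, L, L]), seed=7)
    table = PairTable.uniform(PairPotentialSpec(cutoff=3.0))
    cfg = IntegratorConfig(dt=0.005, thermostat="langevin", target_T=1.0,
                           damping=0.5)
    sim = Simulation(st, table, config=cfg)
    initialize_velocities(st, 1.0, sim.masses, rng)
    sim.run(2000, stress_stride=0)
    return sim


@pytest.fixture
def chain_condensate_small():
    """8 chains x 10 beads, soft test bonds, bulk at rho* = 0.4."""
    top = linear_chain_topology(8, 10, BondSpec(100.0, 1.0))
    state = build_bulk(top, 0.4, seed=3)
    table = PairTable.uniform(PairPotentialSpec(cutoff=3.0))
    cfg = IntegratorConfig(dt=0.002, thermostat="langevin", target_T=2.0,
                           damping=0.5)
    sim = Simulation(state, table, top, config=cfg)
    initialize_velocities(state, 2.0, sim.masses,
                          np.random.default_rng(11))
    sim.run(1000, stress_stride=0)
    return sim
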