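"""MD engine: forces/stress correctness, integration, thermostats, shear."""

import math

import numpy as np
import pytest
from scipy import stats

from condrheo.engine import (IntegratorConfig, PairTable, Simulation,
                             SimulationState, apply_oscillatory_shear,
                             initialize_velocities)
from condrheo.potentials import (BondSpec, ChainTopology, PairPotentialSpec,
                                 linear_chain_topology)

R_MIN = 2.0 ** (1.0 / 6.0)


def _two_particle_sim(r, box=20.0, **cfg_kwargs):
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + r, 5.0, 5.0]])
    st = SimulationState(pos, np.zeros((2, 3)), np.array([box] * 3))
    table = PairTable.uniform(PairPotentialSpec(cutoff=3.0))
    cfg = IntegratorConfig(thermostat="none", **cfg_kwargs)
    return Simulation(st, table, config=cfg)


class TestForcesAndStress:
    def test_two_lj_particles_at_minimum_zero_virial(self):
        sim = _two_particle_sim(R_MIN)
        forces, stress = sim.compute_forces_and_stress()
        assert np.allclose(forces, 0, atol=1e-12)
        assert np.allclose(stress.virial, 0, atol=1e-12)

    def test_ideal_gas_pressure(self, rng):
        n, rho, T = 400, 0.3, 2.0
        L = (n / rho) ** (1 / 3)
        st = SimulationState(rng.uniform(0, L, (n, 3)), np.zeros((n, 3)),
                             np.array([L] * 3), seed=5)
        table = PairTable.uniform(
            PairPotentialSpec(epsilon=0.0, cutoff=0.5))  # no interactions
        sim = Simulation(st, table, config=IntegratorConfig(
            dt=0.005, thermostat="langevin", target_T=T, damping=0.5))
        initialize_velocities(st, T, sim.masses, rng)
        log, _ = sim.run(4000, stress_stride=5)
        p = np.mean(np.sum(log.components[:, :3], axis=1) / 3)
        assert p == pytest.approx(rho * T, rel=0.05)

    def test_stress_matches_finite_strain_energy_derivative(self, rng):
        """sigma_xy from the virial equals dU/dgamma / V on a frozen config."""
        n, L = 20, 5.0
        # sparse frozen configuration without hard overlaps
        pos = rng.uniform(0, L, (n, 3))
        ok = False
        for _ in range(200):
            d = pos[:, None, :] - pos[None, :, :]
            d -= np.rint(d / L) * L
            r = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(r, np.inf)
            if r.min() > 0.9:
                ok = True
                break
            pos = rng.uniform(0, L, (n, 3))
        assert ok
        table = PairTable.uniform(PairPotentialSpec(cutoff=2.0))

        def energy_at_strain(gamma):
            p = pos.copy()
            p[:, 0] += gamma * p[:, 1]
            st = SimulationState(p, np.zeros((n, 3)), np.array([L] * 3),
                                 tilt=gamma * L)
            sim = Simulation(st, table)
            sim.compute_forces_and_stress(all_pairs=True)
            return sim.potential_energy

        st = SimulationState(pos.copy(), np.zeros((n, 3)), np.array([L] * 3))
        sim = Simulation(st, table)
        _, stress = sim.compute_forces_and_stress(all_pairs=True)
        h = 1e-6
        dU_dgamma = (energy_at_strain(h) - energy_at_strain(-h)) / (2 * h)
        # virial sigma_xy = -(1/V) dU/dgamma_xy under affine xy strain
        assert stress.virial[3] == pytest.approx(-dU_dgamma / L**3, rel=1e-5)

    def test_neighbor_list_equals_brute_force(self, rng):
        n, L = 150, 8.0
        pos = rng.uniform(0, L, (n, 3))
        st = SimulationState(pos, np.zeros((n, 3)), np.array([L] * 3))
        table = PairTable.uniform(PairPotentialSpec(epsilon=1e-4, cutoff=3.0))
        sim = Simulation(st, table)
        f1, s1 = sim.compute_forces_and_stress(all_pairs=False)
        f1 = f1.copy()
        v1 = s1.virial.copy()
        f2, s2 = sim.compute_forces_and_stress(all_pairs=True)
        assert np.array_equal(f1, f2)
        assert np.array_equal(v1, s2.virial)

    def test_overlap_reports_pair(self):
        sim = _two_particle_sim(0.0)  # coincident particles
        with pytest.raises(FloatingPointError, match=r"pair \(0, 1\)"):
            sim.compute_forces_and_stress()


class TestIntegration:
    def test_zero_velocity_zero_force_stays_put(self):
        sim = _two_particle_sim(R_MIN, dt=0.005)
        before = sim.state.positions.copy()
        sim.step()
        assert np.allclose(sim.state.positions, before, atol=1e-14)

    def test_harmonic_dimer_period(self):
        """NVE bonded dimer oscillates with period 2 pi sqrt(m / (4K))."""
        K = 100.0
        top = ChainTopology(n_chains=1, beads_per_chain=2,
                            bond_pairs=[(0, 1)], bond_spec=BondSpec(K, 1.0))
        pos = np.array([[5.0, 5, 5], [6.05, 5, 5]])  # stretched by 0.05
        st = SimulationState(pos, np.zeros((2, 3)), np.array([20.0] * 3))
        table = PairTable.uniform(PairPotentialSpec(epsilon=0.0, cutoff=0.5))
        dt = 1e-4
        sim = Simulation(st, table, top,
                         config=IntegratorConfig(dt=dt, thermostat="none"))
        period_expected = 2 * math.pi * math.sqrt(1.0 / (4 * K))
        n_steps = int(3 * period_expected / dt)
        seps = []
        for _ in range(n_steps):
            sim.step()
            seps.append(sim.state.positions[1, 0] - sim.state.positions[0, 0])
        seps = np.array(seps)
        # measure the period from zero crossings of (r - r0)
        x = seps - 1.0
        crossings = np.nonzero(np.diff(np.sign(x)) != 0)[0]
        periods = 2 * np.diff(crossings) * dt
        assert np.mean(periods) == pytest.approx(period_expected, rel=0.01)

    def test_nve_energy_conservation(self, lj_fluid_100):
        sim = lj_fluid_100
        sim.config = IntegratorConfig(dt=0.005, thermostat="none")
        log, _ = sim.run(20000, stress_stride=10)
        E = sim.last_pe + sim.last_ke
        drift_per_tau = abs(np.polyfit(log.times, E, 1)[0])
        # secular drift of the truncated-force LJ fluid stays small
        assert drift_per_tau < 5e-3 * 100  # 5e-3 eps per tau per 100 particles

    def test_nose_hoover_temperature_and_momentum(self, lj_fluid_100):
        sim = lj_fluid_100
        sim.config = IntegratorConfig(dt=0.005, thermostat="nose_hoover",
                                      target_T=3.0, damping=0.2)
        # zero total momentum (the NH velocity scaling preserves it exactly)
        v = sim.state.velocities
        v -= np.average(v, axis=0, weights=sim.masses)
        sim.run(2000, stress_stride=0)  # re-thermalize at the new target
        log, _ = sim.run(10000, stress_stride=5)
        T_series = (np.sum(log.kinetic[:, :3], axis=1) * sim.state.volume
                    / (3 * sim.state.n - 3))
        assert np.mean(T_series) == pytest.approx(3.0, rel=0.02)
        p_total = sim.masses[:, None] * sim.state.velocities
        assert np.allclose(p_total.sum(axis=0), 0, atol=1e-8)

    def test_maxwell_boltzmann_speeds_under_thermostat(self, lj_fluid_100):
        sim = lj_fluid_100
        sim.config = IntegratorConfig(dt=0.005, thermostat="langevin",
                                      target_T=1.0, damping=0.5)
        samples = []
        for _ in range(100):
            sim.run(50, stress_stride=0)
            samples.append(np.linalg.norm(sim.state.velocities, axis=1))
        speeds = np.concatenate(samples)
        ks = stats.kstest(speeds, stats.maxwell(scale=1.0).cdf)
        assert ks.pvalue > 0.01

    def test_same_seed_bit_identical_stress(self):
        logs = []
        for _ in range(2):
            top = linear_chain_topology(4, 5, BondSpec(100.0, 1.0))
            from condrheo.phase_diagram import build_bulk
            st = build_bulk(top, 0.3, seed=9)
            table = PairTable.uniform(PairPotentialSpec(cutoff=3.0))
            sim = Simulation(st, table, top, config=IntegratorConfig(
                dt=0.002, thermostat="langevin", target_T=1.5, damping=0.3))
            initialize_velocities(st, 1.5, sim.masses,
                                  np.random.default_rng(42))
            log, _ = sim.run(500, stress_stride=5)
            logs.append(log.components)
        assert np.array_equal(logs[0], logs[1])

    def test_checkpoint_restart_continuation(self, tmp_path,
                                             chain_condensate_small):
        sim = chain_condensate_small
        ckpt = tmp_path / "state.npz"
        sim.save_checkpoint(ckpt)
        log_a, _ = sim.run(300, stress_stride=5)
        ref_pos = sim.state.positions.copy()
        sim.load_checkpoint(ckpt)
        log_b, _ = sim.run(300, stress_stride=5)
        assert np.allclose(log_a.components, log_b.components,
                           rtol=1e-10, atol=1e-12)
        assert np.allclose(sim.state.positions, ref_pos, atol=1e-10)

    def test_trajectory_stride_frame_count(self, chain_condensate_small):
        sim = chain_condensate_small
        _, traj = sim.run(200, stress_stride=0, traj_stride=100)
        assert len(traj.times) == 2


class TestOscillatoryShear:
    def test_tilt_landmarks(self):
        st = SimulationState(np.zeros((1, 3)), np.zeros((1, 3)),
                             np.array([10.0] * 3))
        apply_oscillatory_shear(st, gamma0=0.2, omega=1.0, t=0.0)
        assert st.tilt == 0.0
        apply_oscillatory_shear(st, gamma0=0.2, omega=1.0,
                                t=math.pi / 2)
        assert st.tilt == pytest.approx(0.2 * 10.0)

    def test_strain_rate_at_zero(self):
        # d(gamma)/dt at t=0 equals gamma0 * omega
        gamma0, omega, h = 0.3, 2.0, 1e-7
        st = SimulationState(np.zeros((1, 3)), np.zeros((1, 3)),
                             np.array([10.0] * 3))
        apply_oscillatory_shear(st, gamma0, omega, h)
        rate = st.gamma_xy / h
        assert rate == pytest.approx(gamma0 * omega, rel=1e-5)

    def test_excessive_amplitude_rejected(self):
        st = SimulationState(np.zeros((1, 3)), np.zeros((1, 3)),
                             np.array([10.0] * 3))
        with pytest.raises(ValueError):
            apply_oscillatory_shear(st, gamma0=50.0, omega=1.0, t=0.1)

    def test_affine_remap_moves_particles(self):
        pos = np.array([[1.0, 8.0, 1.0]])
        st = SimulationState(pos, np.zeros((1, 3)), np.array([10.0] * 3))
        apply_oscillatory_shear(st, gamma0=0.1, omega=1.0, t=math.pi / 2)
        assert st.positions[0, 0] == pytest.approx(1.0 + 0.1 * 8.0)
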