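"""Green-Kubo pipeline: correlator, G(t), Maxwell fit, viscosity, G*(w)."""

import math

import numpy as np
import pytest

from condrheo.fixtures import OUStressSpec, ou_stress_trace
from condrheo.gk import (MaxwellSpectrum, MultiTauCorrelator,
                         RelaxationModulus, choose_t0,
                         complex_modulus_from_spectrum, fit_maxwell_modes,
                         relaxation_modulus, stress_channels, viscosity_gk,
                         viscosity_from_stress_log)


def _single_channel_correlator(x, dt=1.0):
    c = MultiTauCorrelator(dt, n_channels=1)
    c.accumulate_channels(np.asarray(x, dtype=float)[:, None])
    return c


class TestMultiTauCorrelator:
    def test_constant_input_acf_is_square(self):
        c = _single_channel_correlator(np.full(500, 3.0))
        _, acf = c.lags_and_acf()
        assert np.allclose(acf, 9.0)

    def test_white_noise_acf(self, rng):
        n = 200_000
        x = rng.normal(scale=2.0, size=n)
        c = _single_channel_correlator(x)
        lags, acf = c.lags_and_acf()
        assert acf[0, 0] == pytest.approx(4.0, rel=3 / math.sqrt(n) * 4)
        assert np.all(np.abs(acf[0, 1:]) < 4.0 * 3 / math.sqrt(n / 4) * 4)

    def test_sinusoid_gives_cosine_acf(self):
        dt = 0.05
        w = 1.0
        t = np.arange(200_000) * dt
        c = _single_channel_correlator(np.sin(w * t), dt=dt)
        lags, acf = c.lags_and_acf()
        expected = 0.5 * np.cos(w * lags)
        # coarse levels block-average the signal; compare fine-level lags
        fine = lags <= 1.6
        assert np.allclose(acf[0, fine], expected[fine], atol=0.02)

    def test_nonfinite_sample_rejected(self):
        c = MultiTauCorrelator(1.0, n_channels=6)
        c.accumulate(np.full(6, np.nan))
        assert c.n_rejected == 1 and c.n_samples == 0


class TestRelaxationModulus:
    def test_degenerate_channels_make_six_equal_single(self, rng):
        """Diagonal channels with 2x the shear variance: the isotropic
        six-component estimator is exactly unbiased for the same ACF."""
        spec = OUStressSpec(variance=1.0, tau_M=2.0, dt=0.2, n=400_000,
                            seed=10, volume=5.0, temperature=1.0)
        log = ou_stress_trace(spec)
        chans = stress_channels(log.components)
        c = MultiTauCorrelator(0.2)
        c.accumulate_channels(chans)
        G6 = relaxation_modulus(c, 5.0, 1.0, "six_component")
        G1 = relaxation_modulus(c, 5.0, 1.0, "single")
        sel = G6.t < 3 * spec.tau_M
        # both estimate the same exponential ACF; agreement within sampling
        assert np.allclose(G6.G[sel], G1.G[sel], atol=0.15 * G6.G[0])

    def test_invalid_inputs(self):
        c = MultiTauCorrelator(1.0)
        with pytest.raises(ValueError):
            relaxation_modulus(c, 1.0, 1.0)  # too few samples
        c.accumulate_channels(np.zeros((40, 6)))
        with pytest.raises(ValueError):
            relaxation_modulus(c, -1.0, 1.0)


class TestChooseT0:
    def _modulus(self, t, G):
        return RelaxationModulus(np.asarray(t, float), np.asarray(G, float),
                                 1.0, 1.0)

    def test_monotone_decay_starts_at_first_lag(self):
        t = np.linspace(0.1, 50, 200)
        G = self._modulus(t, 5 * np.exp(-t / 5))
        assert choose_t0(G) == pytest.approx(0.1)

    def test_damped_oscillation_splits_after_last_zero(self):
        t = np.linspace(0.01, 60, 600)
        # oscillations up to ~ t=10 with a final sign change, then decay
        G_vals = np.exp(-t / 8) * np.where(t < 10, np.cos(2 * np.pi * t / 4),
                                           1.0)
        last_zero = 9.0  # cos zero before t=10
        t0 = choose_t0(self._modulus(t, G_vals), smooth_window=3)
        assert t0 > last_zero

    def test_all_negative_tail_raises(self):
        t = np.linspace(0.1, 20, 100)
        G = self._modulus(t, 1.0 - 0.2 * t)  # goes negative, stays
        with pytest.raises(ValueError):
            choose_t0(G)


class TestMaxwellFit:
    def test_self_fit_exact_when_tau_on_grid(self):
        # grid [t0/2, 2 t_max] with 1/decade hits tau = 5 exactly
        t = np.concatenate([[0.05], np.geomspace(0.1, 250.0, 400)])
        G0, tau = 2.0, 5.0
        G = RelaxationModulus(t, G0 * np.exp(-t / tau), 1.0, 1.0)
        sp = fit_maxwell_modes(G, t0=0.1, modes_per_decade=1)
        assert np.isclose(sp.tau_i, 5.0).any()
        k = int(np.argmin(np.abs(sp.tau_i - 5.0)))
        assert sp.G_i[k] == pytest.approx(G0, abs=1e-6)
        others = np.delete(sp.G_i, k)
        assert np.all(others < 1e-6)

    def test_two_mode_integral(self):
        t = np.concatenate([[0.005], np.geomspace(0.01, 2000.0, 600)])
        Gv = 1.0 * np.exp(-t / 1.0) + 0.5 * np.exp(-t / 100.0)
        G = RelaxationModulus(t, Gv, 1.0, 1.0)
        t0 = 0.01
        sp = fit_maxwell_modes(G, t0=t0)
        eta, _ = viscosity_gk(G, sp)
        assert eta == pytest.approx(1.0 * 1.0 + 0.5 * 100.0, rel=0.02)

    def test_noisy_single_mode_bias(self, rng):
        t = np.concatenate([[0.02], np.geomspace(0.05, 100.0, 200)])
        estimates = []
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(scale=0.05, size=len(t))
            Gv = np.clip(np.exp(-t / 5.0) * (1 + noise), 1e-9, None)
            G = RelaxationModulus(t, Gv, 1.0, 1.0)
            sp = fit_maxwell_modes(G, t0=0.05)
            estimates.append(viscosity_gk(G, sp)[0])
        assert abs(np.mean(estimates) / 5.0 - 1) < 0.05

    def test_short_span_rejected(self):
        t = np.geomspace(1.0, 2.0, 30)
        G = RelaxationModulus(t, np.exp(-t), 1.0, 1.0)
        with pytest.raises(ValueError, match="decade"):
            fit_maxwell_modes(G, t0=1.0)


class TestViscosityAndComplexModulus:
    def test_single_mode_exact(self):
        t = np.concatenate([[0.0], np.geomspace(0.01, 250.0, 500)])
        G0, tau = 2.0, 5.0
        G = RelaxationModulus(t, G0 * np.exp(-t / tau), 1.0, 1.0)
        # tau = 5 sits exactly on the 1-per-decade grid for these splits
        for t0 in (0.1, 1.0):
            sp = fit_maxwell_modes(G, t0=t0, modes_per_decade=1)
            eta, _ = viscosity_gk(G, sp)
            assert eta == pytest.approx(G0 * tau, rel=1e-4)
        # off-grid split: fit approximates the exponential, integral within 2%
        sp = fit_maxwell_modes(G, t0=5.0)
        eta, _ = viscosity_gk(G, sp)
        assert eta == pytest.approx(G0 * tau, rel=0.02)

    def test_zero_modulus_zero_viscosity(self):
        t = np.geomspace(0.01, 100.0, 100)
        G = RelaxationModulus(t, np.zeros_like(t), 1.0, 1.0)
        sp = MaxwellSpectrum(G_i=np.array([0.0]), tau_i=np.array([1.0]),
                             t0=1.0)
        eta, _ = viscosity_gk(G, sp)
        assert eta == 0.0

    def test_maxwell_crossover_and_terminal_limit(self):
        G0, tau = 2.0, 5.0
        sp = MaxwellSpectrum(G_i=np.array([G0]), tau_i=np.array([tau]),
                             t0=1e-9)
        gp, gpp = complex_modulus_from_spectrum(sp, None,
                                                np.array([1.0 / tau]))
        assert gp[0] == pytest.approx(G0 / 2)
        assert gpp[0] == pytest.approx(G0 / 2)
        w_small = np.array([1e-6])
        _, gpp_s = complex_modulus_from_spectrum(sp, None, w_small)
        assert gpp_s[0] / w_small[0] == pytest.approx(G0 * tau, rel=1e-6)

    def test_numerical_transform_matches_analytic(self):
        # densely sampled single-mode G; force the numerical remainder path
        t = np.concatenate([[0.0], np.geomspace(1e-3, 500.0, 2000)])
        G0, tau = 1.5, 3.0
        G = RelaxationModulus(t, G0 * np.exp(-t / tau), 1.0, 1.0)
        sp = fit_maxwell_modes(G, t0=2.0, modes_per_decade=2)
        omegas = np.geomspace(0.01 / tau, 100.0 / tau, 25)
        gp, gpp = complex_modulus_from_spectrum(sp, G, omegas)
        wt = omegas * tau
        assert np.allclose(gp, G0 * wt**2 / (1 + wt**2), rtol=0.01,
                           atol=1e-4 * G0)
        assert np.allclose(gpp, G0 * wt / (1 + wt**2), rtol=0.01,
                           atol=1e-4 * G0)

    def test_transform_accuracy_insensitive_to_split(self):
        t = np.concatenate([[0.0], np.geomspace(1e-3, 500.0, 2000)])
        G0, tau = 1.5, 3.0
        G = RelaxationModulus(t, G0 * np.exp(-t / tau), 1.0, 1.0)
        omegas = np.geomspace(0.01 / tau, 100.0 / tau, 15)
        wt = omegas * tau
        for t0 in (0.5, 2.0):
            sp = fit_maxwell_modes(G, t0=t0)
            gp, gpp = complex_modulus_from_spectrum(sp, G, omegas)
            assert np.allclose(gpp, G0 * wt / (1 + wt**2), rtol=0.02)


class TestEndToEnd:
    def test_ou_pipeline_converges_as_sqrt_n(self):
        """Error of the OU-fixture viscosity shrinks roughly as 1/sqrt(n)."""
        errs = {}
        for n in (50_000, 800_000):
            rels = []
            for seed in (1, 2, 3):
                spec = OUStressSpec(variance=1.5, tau_M=4.0, dt=0.4, n=n,
                                    seed=seed, volume=8.0, temperature=2.0)
                res = viscosity_from_stress_log(ou_stress_trace(spec))
                rels.append(abs(res["eta"] / spec.eta_true - 1))
            errs[n] = np.mean(rels)
        assert errs[800_000] < errs[50_000]
        assert errs[800_000] < 0.06

    def test_t0_insensitivity_for_single_mode(self):
        spec = OUStressSpec(variance=2.0, tau_M=5.0, dt=0.5, n=500_000,
                            seed=4, volume=10.0, temperature=2.5)
        log = ou_stress_trace(spec)
        etas = []
        for t0 in (1.0, 4.0, 16.0):
            res = viscosity_from_stress_log(log, t0=t0)
            etas.append((res["eta"], max(res["eta_err"], 0.05 * res["eta"])))
        for (e1, s1), (e2, s2) in zip(etas, etas[1:]):
            assert abs(e1 - e2) < 3 * math.hypot(s1, s2)
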