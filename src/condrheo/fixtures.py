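"""Synthetic inputs with known ground truth for every estimator.

These generators produce the exact data shapes the analysis pipelines
consume, with closed-form answers, so the Green-Kubo, oscillatory-shear and
bead-tracking estimators can each be validated without running any molecular
dynamics:

* :func:`ou_stress_trace` - six stress channels following independent
  Ornstein-Uhlenbeck processes with prescribed stationary variance ``s^2``
  and correlation time ``tau_M``.  The exact discretization
  ``x' = x e^(-dt/tau) + s sqrt(1 - e^(-2 dt/tau)) xi`` makes the ensemble
  ACF exponential to machine precision, so estimator tests carry no
  discretization error.  The Green-Kubo viscosity of such a trace is
  ``(V / kB T) s^2 tau_M``.
* :func:`brownian_trajectory` - an ideal Brownian probe with known diffusion
  coefficient (Gaussian increments of variance ``2 D dt`` per axis).
* :func:`maxwell_responder` - the sinusoidal stress response of a
  single-mode Maxwell material to an imposed oscillatory strain, with the
  closed-form amplitude and phase; its terminal viscosity is ``G0 tau``.

The fixtures are numerical oracles, not physical models; they never feed
scientific conclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import StressLog

__all__ = [
    "OUStressSpec",
    "BrownianSpec",
    "ou_stress_trace",
    "brownian_trajectory",
    "maxwell_responder",
    "maxwell_moduli",
    "fractional_brownian_msd_input",
    "tanh_density_profile",
]


@dataclass(frozen=True)
class OUStressSpec:
    """Ornstein-Uhlenbeck stress-trace parameters.

    ``variance`` is the stationary variance s^2 of each channel; the implied
    Green-Kubo viscosity is (volume/temperature) * variance * tau_M.
    """

    variance: float = 1.0
    tau_M: float = 1.0
    dt: float = 0.1
    n: int = 100_000
    seed: int = 0
    volume: float = 1.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.variance <= 0 or self.tau_M <= 0 or self.dt <= 0:
            raise ValueError("variance, tau_M and dt must be positive")
        if self.dt >= self.tau_M / 5.0:
            raise ValueError("dt must resolve the correlation time (dt < tau_M/5)")

    @property
    def eta_true(self) -> float:
        return self.volume / self.temperature * self.variance * self.tau_M


@dataclass(frozen=True)
class BrownianSpec:
    """Ideal Brownian probe-trajectory parameters."""

    D: float = 1.0
    dt: float = 0.01
    n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or self.dt <= 0:
            raise ValueError("D must be >= 0 and dt > 0")


def ou_stress_trace(spec: OUStressSpec) -> StressLog:
    """Six independent OU stress channels packaged as a StressLog.

    The three diagonal components are given twice the shear variance so that
    the six-component relaxation-modulus estimator (shear weights 1/5,
    normal-difference weights 1/30) is exactly unbiased for the same
    exponential ACF as the shear channels.
    """
    rng = np.random.default_rng(spec.seed)
    a = math.exp(-spec.dt / spec.tau_M)
    n = spec.n
    x = np.empty((n, 6))
    s_shear = math.sqrt(spec.variance)
    s_diag = math.sqrt(2.0 * spec.variance)
    scale = np.array([s_diag] * 3 + [s_shear] * 3)
    state = rng.normal(size=6) * scale
    b = math.sqrt(1.0 - a * a)
    noise = rng.normal(size=(n, 6))
    for i in range(n):
        state = a * state + b * scale * noise[i]
        x[i] = state
    times = spec.dt * np.arange(1, n + 1)
    return StressLog(times=times, components=x, volume=spec.volume,
                     temperature=spec.temperature)


def brownian_trajectory(spec: BrownianSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped ideal Brownian trajectory: (times, positions (n, 3))."""
    rng = np.random.default_rng(spec.seed)
    steps = rng.normal(scale=math.sqrt(2.0 * spec.D * spec.dt),
                       size=(spec.n, 3))
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    times = spec.dt * np.arange(spec.n + 1)
    return times, pos


def maxwell_moduli(G0: float, tau: float, omega: float) -> tuple[float, float]:
    """Analytic single-mode storage and loss moduli at one frequency."""
    wt = omega * tau
    return G0 * wt**2 / (1 + wt**2), G0 * wt / (1 + wt**2)


def maxwell_responder(
    G0: float, tau: float, gamma0: float, omega: float,
    noise_sd: float = 0.0, seed: int = 0,
    n_periods: int = 20, samples_per_period: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Stress response of a single-mode Maxwell material to sinusoidal strain.

    For strain gamma0 sin(w t) the linear response is
    sigma(t) = gamma0 |G*| sin(w t + delta) with |G*| = sqrt(G'^2 + G''^2)
    and tan(delta) = G''/G'; optional additive Gaussian noise.
    Returns (times, stress).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    gp, gpp = maxwell_moduli(G0, tau, omega)
    amp = gamma0 * math.hypot(gp, gpp)
    delta = math.atan2(gpp, gp)
    n = n_periods * samples_per_period
    t = np.arange(1, n + 1) * (2 * math.pi / omega / samples_per_period)
    sigma = amp * np.sin(omega * t + delta)
    if noise_sd > 0:
        sigma = sigma + np.random.default_rng(seed).normal(scale=noise_sd,
                                                           size=n)
    return t, sigma


def fractional_brownian_msd_input(
    hurst_2: float, D_eff: float, t: np.ndarray
) -> np.ndarray:
    """Power-law MSD g3(t) = 6 D_eff t^alpha (alpha = ``hurst_2`` = 2H).

    Used as a subdiffusive input for plateau-detector false-positive tests.
    """
    return 6.0 * D_eff * np.asarray(t) ** hurst_2


def tanh_density_profile(
    z: np.ndarray, rho_liquid: float, rho_vapor: float,
    center: float, half_width: float, interface_width: float,
    noise_sd: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """Symmetric two-interface slab density profile with tanh interfaces."""
    z = np.asarray(z, dtype=np.float64)
    mid = 0.5 * (rho_liquid + rho_vapor)
    amp = 0.5 * (rho_liquid - rho_vapor)
    prof = mid + amp * (np.tanh((z - (center - half_width)) / interface_width)
                        - np.tanh((z - (center + half_width)) / interface_width)
                        - 1.0)
    if noise_sd > 0:
        prof = prof + np.random.default_rng(seed).normal(scale=noise_sd,
                                                         size=len(z))
    return prof
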