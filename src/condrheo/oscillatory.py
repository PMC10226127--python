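"""Oscillatory-shear (SAOS) rheology: amplitude/frequency sweeps and moduli.

A sinusoidal strain gamma_xy(t) = gamma0 sin(w t) is imposed on the box; in
the linear viscoelastic (LVE) regime the stress response is sinusoidal,
sigma_xy(t) = sigma0 sin(w t + delta), and the storage and loss moduli follow

    G'(w)  = (sigma0 / gamma0) cos(delta)      (elastic, in phase)
    G''(w) = (sigma0 / gamma0) sin(delta)      (viscous, in quadrature).

The zero-shear viscosity is the terminal limit eta = lim_{w->0} G''(w) / w,
valid where G'' is linear in w and G' quadratic.  An amplitude sweep
certifies the LVE regime before the frequency sweep: the ratio sigma0/gamma0
must sit on the small-amplitude plateau and the third-harmonic distortion of
the response must stay small.

``frequency_sweep`` drives either a molecular-dynamics condensate (through
:class:`OscillatoryMD`) or any callable responder with the same signature,
so synthetic single-mode Maxwell materials exercise the identical pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

__all__ = [
    "OscillatoryProtocol",
    "StressResponseFit",
    "fit_stress_response",
    "moduli_from_fit",
    "amplitude_sweep",
    "frequency_sweep",
    "viscosity_os",
    "OscillatoryMD",
]


@dataclass
class OscillatoryProtocol:
    """Strain amplitude, frequency list and sampling plan for a sweep."""

    gamma0: float = 0.1
    omegas: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0)
    n_periods: int = 20
    discard_fraction: float = 0.25
    samples_per_period: int = 64
    max_thermostat_rate: float | None = None

    def __post_init__(self) -> None:
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if any(w <= 0 for w in self.omegas):
            raise ValueError("omegas must be positive")
        if self.n_periods * (1 - self.discard_fraction) < 5:
            raise ValueError("at least 5 sampled periods required after discard")
        if self.max_thermostat_rate is not None:
            bad = [w for w in self.omegas if w >= self.max_thermostat_rate]
            if bad:
                raise ValueError(
                    f"frequencies {bad} exceed the inverse thermostat "
                    "relaxation time")


@dataclass
class StressResponseFit:
    """Amplitude, phase and quality of a sinusoidal stress-response fit."""

    sigma0: float
    delta: float
    offset: float
    residual_rms: float
    sigma0_err: float = 0.0
    delta_err: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be nonnegative")


def fit_stress_response(times: np.ndarray, sigma: np.ndarray,
                        omega: float) -> StressResponseFit:
    """Least-squares fit of sigma(t) = a sin(wt) + b cos(wt) + c.

    Returns sigma0 = hypot(a, b) and delta = atan2(b, a) mapped to [0, pi);
    exact on noiseless sinusoids, with parameter standard errors from the
    residual variance.  Requires at least two whole periods of data.
    """
    times = np.asarray(times, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    span = times[-1] - times[0]
    if span < 2 * (2 * math.pi / omega):
        raise ValueError("stress series shorter than 2 periods")
    A = np.column_stack([np.sin(omega * times), np.cos(omega * times),
                         np.ones_like(times)])
    coef, res, rank, sv = np.linalg.lstsq(A, sigma, rcond=None)
    a, b, c = coef
    resid = sigma - A @ coef
    dof = max(len(sigma) - 3, 1)
    s2 = float(resid @ resid) / dof
    # correlated-noise correction: MD stress samples are autocorrelated, so
    # the effective sample count shrinks by (1+rho)/(1-rho) at lag-1
    # autocorrelation rho (AR(1) approximation); noiseless fits are exact
    # and unaffected (s2 ~ 0)
    if s2 > 0 and len(resid) > 10:
        r = resid - resid.mean()
        denom = float(r @ r)
        if denom > 0:
            rho = float(r[:-1] @ r[1:]) / denom
            rho = min(max(rho, 0.0), 0.99)
            s2 *= (1.0 + rho) / (1.0 - rho)
    cov = s2 * np.linalg.inv(A.T @ A)
    sigma0 = math.hypot(a, b)
    delta = math.atan2(b, a)
    # passive linear response has delta in [0, pi); noise can push the raw
    # phase slightly negative (clamp to 0) or past -pi/2 (sign-flipped
    # representative: shift by pi)
    if delta < -math.pi / 2:
        delta += math.pi
    elif delta < 0:
        delta = 0.0
    # errors by first-order propagation through (a, b) -> (sigma0, delta)
    if sigma0 > 0:
        g_amp = np.array([a, b]) / sigma0
        g_ph = np.array([-b, a]) / sigma0**2
        s0_err = math.sqrt(g_amp @ cov[:2, :2] @ g_amp)
        d_err = math.sqrt(g_ph @ cov[:2, :2] @ g_ph)
    else:
        s0_err = d_err = math.sqrt(cov[0, 0])
    return StressResponseFit(sigma0=sigma0, delta=delta, offset=float(c),
                             residual_rms=math.sqrt(s2), sigma0_err=s0_err,
                             delta_err=d_err, omega=omega)


def moduli_from_fit(fit: StressResponseFit, gamma0: float
                    ) -> tuple[float, float]:
    """Storage and loss moduli from a stress-response fit."""
    if gamma0 <= 0:
        raise ValueError("gamma0 must be positive")
    if not 0.0 <= fit.delta < math.pi:
        raise ValueError("delta must lie in [0, pi)")
    ratio = fit.sigma0 / gamma0
    return ratio * math.cos(fit.delta), ratio * math.sin(fit.delta)


def _third_harmonic_ratio(times: np.ndarray, sigma: np.ndarray,
                          omega: float) -> float:
    """Amplitude ratio of the 3w response harmonic to the fundamental."""
    A = np.column_stack([
        np.sin(omega * times), np.cos(omega * times),
        np.sin(3 * omega * times), np.cos(3 * omega * times),
        np.ones_like(times)])
    coef, *_ = np.linalg.lstsq(A, sigma, rcond=None)
    fund = math.hypot(coef[0], coef[1])
    third = math.hypot(coef[2], coef[3])
    return third / fund if fund > 0 else np.inf


class Responder(Protocol):
    """Anything that returns a stress response to an imposed oscillation."""

    def __call__(self, gamma0: float, omega: float, n_periods: int,
                 samples_per_period: int) -> tuple[np.ndarray, np.ndarray]:
        ...


@dataclass
class AmplitudeSweepReport:
    """sigma0/gamma0 vs gamma0, with LVE-regime flags."""

    gamma0s: np.ndarray
    ratios: np.ndarray
    deltas: np.ndarray
    distortion: np.ndarray
    linear_mask: np.ndarray
    max_linear_gamma0: float | None
    warning: str | None = None


def amplitude_sweep(system: Responder, omega_ref: float,
                    gamma0s: np.ndarray, n_periods: int = 20,
                    samples_per_period: int = 64,
                    discard_fraction: float = 0.25,
                    plateau_tol: float = 0.10,
                    distortion_tol: float = 0.10) -> AmplitudeSweepReport:
    """Certify the linear-viscoelastic strain range at a reference frequency.

    Flags the largest gamma0 whose sigma0/gamma0 deviates less than
    ``plateau_tol`` from the small-amplitude plateau and whose third-harmonic
    content stays below ``distortion_tol``.
    """
    gamma0s = np.asarray(sorted(gamma0s), dtype=np.float64)
    if len(gamma0s) < 2:
        raise ValueError("amplitude sweep needs at least two amplitudes")
    if gamma0s[-1] / gamma0s[0] < 10.0:
        raise ValueError("amplitude range must span at least one decade")
    ratios, deltas, dist = [], [], []
    for g0 in gamma0s:
        t, s = system(g0, omega_ref, n_periods, samples_per_period)
        keep = t >= t[0] + discard_fraction * (t[-1] - t[0])
        fit = fit_stress_response(t[keep], s[keep], omega_ref)
        ratios.append(fit.sigma0 / g0)
        deltas.append(fit.delta)
        dist.append(_third_harmonic_ratio(t[keep], s[keep], omega_ref))
    ratios = np.asarray(ratios)
    dist = np.asarray(dist)
    plateau = np.median(ratios[: max(2, len(ratios) // 3)])
    linear = (np.abs(ratios / plateau - 1) < plateau_tol) & (dist < distortion_tol)
    max_g0 = None
    warning = None
    if linear.any():
        max_g0 = float(gamma0s[np.nonzero(linear)[0][-1]])
    if not linear[: max(2, len(ratios) // 3)].all():
        warning = "no small-amplitude plateau identified"
    return AmplitudeSweepReport(gamma0s=gamma0s, ratios=ratios,
                                deltas=np.asarray(deltas), distortion=dist,
                                linear_mask=linear, max_linear_gamma0=max_g0,
                                warning=warning)


def frequency_sweep(system: Responder, protocol: OscillatoryProtocol
                    ) -> "SweepTable":
    """Measure (G', G'') over the protocol's frequencies.

    Each frequency is driven for ``n_periods`` periods; the leading
    ``discard_fraction`` is dropped as transient before fitting.  MD systems
    report their steady kinetic temperature through the ``temperature_excess``
    attribute of the returned samples; a frequency is aborted (flagged) when
    the system overheats by more than 5%.
    """
    rows = []
    for w in protocol.omegas:
        t, s = system(protocol.gamma0, w, protocol.n_periods,
                      protocol.samples_per_period)
        keep = t >= t[0] + protocol.discard_fraction * (t[-1] - t[0])
        overheated = False
        t_excess = getattr(system, "last_temperature_excess", 0.0)
        if t_excess > 0.05:
            overheated = True
        fit = fit_stress_response(t[keep], s[keep], w)
        gp, gpp = moduli_from_fit(fit, protocol.gamma0)
        rows.append((w, gp, gpp, fit.sigma0, fit.delta, fit.sigma0_err,
                     overheated))
    arr = np.array([r[:6] for r in rows])
    return SweepTable(omega=arr[:, 0], Gp=arr[:, 1], Gpp=arr[:, 2],
                      sigma0=arr[:, 3], delta=arr[:, 4], sigma0_err=arr[:, 5],
                      overheated=np.array([r[6] for r in rows]),
                      gamma0=protocol.gamma0)


@dataclass
class SweepTable:
    """Frequency-sweep results: per-omega moduli and fit diagnostics."""

    omega: np.ndarray
    Gp: np.ndarray
    Gpp: np.ndarray
    sigma0: np.ndarray
    delta: np.ndarray
    sigma0_err: np.ndarray
    overheated: np.ndarray
    gamma0: float = 0.1


def viscosity_os(sweep: SweepTable, terminal_tol: float = 0.15
                 ) -> tuple[float, float]:
    """Terminal-limit viscosity eta = lim_{w->0} G''(w)/w.

    Terminal-regime membership: starting from the lowest frequencies, points
    qualify while G''/w is constant within ``terminal_tol`` of its
    low-frequency value (widened by the measured 2-sigma uncertainty of the
    ratio when the sweep carries fit errors) and G' < G'' (loss-dominated).
    eta is the slope of the zero-intercept fit of G'' vs w over those
    points, with its standard error.
    """
    order = np.argsort(sweep.omega)
    w = sweep.omega[order]
    gp = sweep.Gp[order]
    gpp = sweep.Gpp[order]
    s_err = sweep.sigma0_err[order] / (sweep.gamma0 * w)  # err on G''/w
    ok = ~sweep.overheated[order]
    ratio = gpp / w
    ref = ratio[ok][0] if ok.any() else ratio[0]
    ref_err = s_err[ok][0] if ok.any() else s_err[0]
    terminal = np.zeros(len(w), dtype=bool)
    for i in range(len(w)):
        if not ok[i]:
            break
        slack = max(terminal_tol * abs(ref),
                    2.0 * math.hypot(s_err[i], ref_err))
        if abs(ratio[i] - ref) < slack and gp[i] < gpp[i] + 2.0 * w[i] * s_err[i]:
            terminal[i] = True
        else:
            break
    if terminal.sum() < 2:
        raise ValueError(
            "fewer than 2 frequencies in the terminal regime (G'' linear in "
            "omega); sample lower frequencies")
    wt, gt = w[terminal], gpp[terminal]
    et = s_err[terminal] * wt  # err on G'' itself
    if np.all(et > 0):
        wgt = 1.0 / et**2
        eta = float(np.sum(wgt * wt * gt) / np.sum(wgt * wt * wt))
        err = float(1.0 / math.sqrt(np.sum(wgt * wt * wt)))
    else:
        eta = float(np.sum(wt * gt) / np.sum(wt * wt))
        resid = gt - eta * wt
        dof = max(len(wt) - 1, 1)
        err = float(math.sqrt((resid @ resid) / dof / np.sum(wt * wt)))
    return eta, err


class OscillatoryMD:
    """Drives a Simulation through oscillatory box shear as a Responder.

    Wraps :class:`condrheo.engine.Simulation`: every call restores the
    supplied reference state, applies gamma_xy(t) = gamma0 sin(w t) and
    returns the sampled sigma_xy(t).  The steady kinetic temperature excess
    over the thermostat target is recorded for overheating checks.
    """

    def __init__(self, sim, equilibrated_state=None):
        self.sim = sim
        self.ref_state = (equilibrated_state or sim.state).copy()
        self.last_temperature_excess = 0.0

    def __call__(self, gamma0: float, omega: float, n_periods: int,
                 samples_per_period: int) -> tuple[np.ndarray, np.ndarray]:
        sim = self.sim
        st = self.ref_state.copy()
        sim.state = st
        sim._alloc_nlist()
        period_steps = max(int(round(2 * math.pi / omega / sim.config.dt)),
                           samples_per_period)
        stride = max(period_steps // samples_per_period, 1)
        n_steps = period_steps * n_periods
        log, _ = sim.run(n_steps, stress_stride=stride, gamma0=gamma0,
                         omega=omega, shear_t0=st.time)
        kin = log.kinetic[len(log.kinetic) // 2:]
        T_kin = np.mean(np.sum(kin[:, :3], axis=1)) * st.volume / (
            3 * st.n - 3)
        self.last_temperature_excess = max(
            T_kin / sim.config.target_T - 1.0, 0.0)
        times = log.times - st.time
        return times, log.channel("sxy")
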