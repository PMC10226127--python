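"""Green-Kubo rheology: stress autocorrelation -> G(t) -> viscosity and G*(w).

The zero-shear viscosity of a liquid equals the time integral of the shear
stress relaxation modulus,

    eta = int_0^inf G(t) dt,   G(t) = (V / kB T) < sigma_xy(t) sigma_xy(0) >,

with the autocorrelation taken at equilibrium over all time origins.  For an
isotropic system a lower-variance estimator combines all six independent
stress components: the three shear channels with weight 1/5 and the three
normal-stress differences N_ab = sigma_aa - sigma_bb with weight 1/30 (the
normal-difference autocorrelation is four times the shear one under isotropy,
so the combination stays unbiased: 3/5 + 4*3/30 = 1).

Because the terminal decay of G(t) is noisy in condensate simulations, the
integral is split at a time t0: below t0 it is evaluated numerically, above
t0 from a fit of G(t) to a sum of Maxwell modes G_i exp(-t/tau_i) with
relaxation times equidistant in log time, integrated analytically:

    eta = int_0^t0 G dt + sum_i G_i tau_i exp(-t0 / tau_i).

t0 is the earliest time after which the (median-smoothed) modulus is strictly
positive and decays monotonically, i.e. after all intramolecular oscillations
have died out.

The autocorrelation is accumulated on the fly by a multiple-tau correlator
(p points per level, coarsened by a factor m per level), so arbitrarily long
stress series cost O(p log n) memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import nnls

from .engine import StressLog, StressTensorSample

__all__ = [
    "MultiTauCorrelator",
    "RelaxationModulus",
    "MaxwellSpectrum",
    "relaxation_modulus",
    "choose_t0",
    "fit_maxwell_modes",
    "viscosity_gk",
    "complex_modulus_from_spectrum",
    "viscosity_from_stress_log",
    "stress_channels",
]

N_CHANNELS = 6  # 3 shear + 3 normal differences
MAX_LEVELS = 40


def stress_channels(components: np.ndarray) -> np.ndarray:
    """Map six stress components (xx,yy,zz,xy,xz,yz) onto correlator channels.

    Channels 0-2 are the shear components, channels 3-5 the normal-stress
    differences (sxx-syy, syy-szz, sxx-szz).
    """
    c = np.asarray(components, dtype=np.float64)
    out = np.empty(c.shape[:-1] + (6,))
    out[..., 0] = c[..., 3]
    out[..., 1] = c[..., 4]
    out[..., 2] = c[..., 5]
    out[..., 3] = c[..., 0] - c[..., 1]
    out[..., 4] = c[..., 1] - c[..., 2]
    out[..., 5] = c[..., 0] - c[..., 2]
    return out


@njit(cache=True, error_model="numpy")
def _mt_accumulate(samples, shift, nins, acc, nacc, corr, cnt, p, m):
    n = samples.shape[0]
    nch = samples.shape[1]
    nlev = shift.shape[1]
    vals = np.empty(nch)
    for s in range(n):
        for c in range(nch):
            vals[c] = samples[s, c]
        level = 0
        while True:
            idx = nins[level] % p
            for c in range(nch):
                shift[c, level, idx] = vals[c]
            nins[level] += 1
            kmin = 0 if level == 0 else p // m
            kmax = p if nins[level] >= p else nins[level]
            for k in range(kmin, kmax):
                jdx = (idx - k) % p
                cnt[level, k] += 1
                for c in range(nch):
                    corr[c, level, k] += shift[c, level, idx] * shift[c, level, jdx]
            for c in range(nch):
                acc[c, level] += vals[c]
            nacc[level] += 1
            if nacc[level] == m and level + 1 < nlev:
                for c in range(nch):
                    vals[c] = acc[c, level] / m
                    acc[c, level] = 0.0
                nacc[level] = 0
                level += 1
            else:
                if nacc[level] == m:
                    # deepest level: discard the coarse value
                    for c in range(nch):
                        acc[c, level] = 0.0
                    nacc[level] = 0
                break


class MultiTauCorrelator:
    """On-the-fly logarithmically blocked autocorrelation accumulator.

    Lag grid: ``p`` linear lags at the base sampling interval, then per
    level the lags ``p/m .. p-1`` at spacing coarsened by ``m``; values
    entering level ``l`` are averages of ``m**l`` raw samples.  Estimates
    are unbiased for stationary input (no mean subtraction: the ACF of a
    constant c is c^2).
    """

    def __init__(self, dt_sample: float, p: int = 16, m: int = 2,
                 n_channels: int = N_CHANNELS):
        if p % m != 0:
            raise ValueError("p must be divisible by m")
        self.dt = float(dt_sample)
        self.p = p
        self.m = m
        self.n_channels = n_channels
        self.n_samples = 0
        self.n_rejected = 0
        self._shift = np.zeros((n_channels, MAX_LEVELS, p))
        self._nins = np.zeros(MAX_LEVELS, dtype=np.int64)
        self._acc = np.zeros((n_channels, MAX_LEVELS))
        self._nacc = np.zeros(MAX_LEVELS, dtype=np.int64)
        self._corr = np.zeros((n_channels, MAX_LEVELS, p))
        self._cnt = np.zeros((MAX_LEVELS, p), dtype=np.int64)

    def accumulate(self, sample) -> "MultiTauCorrelator":
        """Add one sample: a StressTensorSample, or an array of channels."""
        if isinstance(sample, StressTensorSample):
            row = stress_channels(sample.total[None, :])
        else:
            row = np.atleast_2d(np.asarray(sample, dtype=np.float64))
        if not np.all(np.isfinite(row)):
            self.n_rejected += 1
            return self
        _mt_accumulate(row, self._shift, self._nins, self._acc, self._nacc,
                       self._corr, self._cnt, self.p, self.m)
        self.n_samples += row.shape[0]
        return self

    def accumulate_components(self, components: np.ndarray) -> "MultiTauCorrelator":
        """Add a whole (n, 6) array of stress components at the fixed stride."""
        rows = stress_channels(components)
        ok = np.all(np.isfinite(rows), axis=1)
        self.n_rejected += int((~ok).sum())
        rows = rows[ok]
        _mt_accumulate(rows, self._shift, self._nins, self._acc, self._nacc,
                       self._corr, self._cnt, self.p, self.m)
        self.n_samples += rows.shape[0]
        return self

    def accumulate_channels(self, channels: np.ndarray) -> "MultiTauCorrelator":
        """Add raw correlator channels (n, n_channels) without remapping."""
        rows = np.atleast_2d(np.asarray(channels, dtype=np.float64))
        _mt_accumulate(rows, self._shift, self._nins, self._acc, self._nacc,
                       self._corr, self._cnt, self.p, self.m)
        self.n_samples += rows.shape[0]
        return self

    def lags_and_acf(self) -> tuple[np.ndarray, np.ndarray]:
        """Lag times and the per-channel ACF estimates (n_channels, n_lags)."""
        p, m = self.p, self.m
        lags, acfs = [], []
        for level in range(MAX_LEVELS):
            if self._nins[level] == 0:
                break
            kmin = 0 if level == 0 else p // m
            scale = self.dt * m**level
            for k in range(kmin, p):
                if self._cnt[level, k] == 0:
                    continue
                lags.append(k * scale)
                acfs.append(self._corr[:, level, k] / self._cnt[level, k])
        order = np.argsort(lags)
        return np.asarray(lags)[order], np.asarray(acfs).T[:, order]


@dataclass
class RelaxationModulus:
    """Shear stress relaxation modulus G(t) on a log-spaced lag grid."""

    t: np.ndarray
    G: np.ndarray
    volume: float
    temperature: float
    channel_mode: str = "six_component"

    def __post_init__(self) -> None:
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("lag grid must be strictly increasing")


@dataclass
class MaxwellSpectrum:
    """Discrete Maxwell modes (G_i, tau_i), log-equidistant relaxation times."""

    G_i: np.ndarray
    tau_i: np.ndarray
    t0: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.G_i < 0) or np.any(self.tau_i <= 0):
            raise ValueError("modes require G_i >= 0 and tau_i > 0")
        if np.any(np.diff(self.tau_i) <= 0):
            raise ValueError("tau_i must be strictly increasing")

    def modulus(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return np.sum(self.G_i[:, None]
                      * np.exp(-t[None, :] / self.tau_i[:, None]), axis=0)

    def tail_integral(self, t0: float | None = None) -> float:
        """Analytic integral of the mode sum from t0 to infinity."""
        t0 = self.t0 if t0 is None else t0
        return float(np.sum(self.G_i * self.tau_i * np.exp(-t0 / self.tau_i)))


def relaxation_modulus(correlator: MultiTauCorrelator, volume: float,
                       temperature: float,
                       channel_mode: str = "six_component") -> RelaxationModulus:
    """G(t) from the accumulated stress autocorrelations.

    ``single`` averages the three shear-channel ACFs; ``six_component`` adds
    the normal-difference channels with the isotropic 1/5 and 1/30 weights.
    """
    if volume <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    if correlator.n_samples < correlator.p:
        raise ValueError("correlator has fewer samples than points per level")
    lags, acf = correlator.lags_and_acf()
    if channel_mode == "single":
        corr = acf[:3].mean(axis=0)
    elif channel_mode == "six_component":
        corr = acf[:3].sum(axis=0) / 5.0 + acf[3:6].sum(axis=0) / 30.0
    else:
        raise ValueError(f"unknown channel_mode {channel_mode!r}")
    G = volume / temperature * corr
    return RelaxationModulus(t=lags, G=G, volume=volume,
                             temperature=temperature, channel_mode=channel_mode)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def significant_lag_index(G: RelaxationModulus, err: np.ndarray | None = None,
                          smooth_window: int = 5, i_start: int = 0) -> int:
    """Index of the last lag where smoothed G exceeds twice its uncertainty.

    ``err`` is a per-lag standard error (e.g. from block partitions); when
    absent, the robust scatter of the terminal third of the raw-minus-
    smoothed residual is used as a flat noise floor.
    """
    Gs = _running_median(G.G, smooth_window)
    if err is None:
        tail = slice(2 * len(Gs) // 3, None)
        resid = G.G[tail] - Gs[tail]
        noise = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        err = np.full(len(Gs), max(noise, 1e-12 * np.max(np.abs(Gs))))
    # significance of |G| (sign changes of a noise-free oscillating modulus
    # are not insignificance): the window ends with the last run of at
    # least 3 consecutive 2-sigma lags BEFORE the signal first drops to its
    # own noise floor - once resolution is lost, later isolated bumps are
    # sampling artifacts (block errors at long lags are themselves noisy)
    # and must not re-open the window
    lost = np.nonzero(np.abs(Gs[i_start + 1:]) < err[i_start + 1:])[0]
    cap = (i_start + int(lost[0]) if len(lost) else len(Gs) - 1)
    sig = np.abs(Gs) > 2.0 * err
    j_sig = max(i_start, 1)
    run = 0
    for i in range(i_start, cap + 1):
        run = run + 1 if sig[i] else 0
        if run >= 3:
            j_sig = i
    return j_sig


def choose_t0(G: RelaxationModulus, smooth_window: int = 5,
              mono_tol: float = 0.05, err: np.ndarray | None = None,
              t0_min: float = 0.0) -> float:
    """Earliest time after which smoothed G is positive and decays monotonically.

    The modulus is running-median smoothed; the last statistically
    significant lag is where the smoothed value last exceeds twice its
    uncertainty (per-lag ``err`` when given, else a robust terminal noise
    floor).  The returned t0 is the smallest grid time from which the
    smoothed curve stays strictly positive and non-increasing (within
    ``mono_tol`` relative, plus the local uncertainty) through that lag.
    ``t0_min`` excludes the molecular-oscillation band when its tail cannot
    be resolved on the correlator's coarse levels (e.g. ~20 bond periods for
    stiff bead-spring chains).
    """
    if len(G.t) == 0:
        raise ValueError("empty relaxation modulus")
    Gs = _running_median(G.G, smooth_window)
    j_sig = significant_lag_index(G, err, smooth_window)
    allow = np.zeros(len(Gs)) if err is None else np.asarray(err)
    i_min = int(np.searchsorted(G.t, t0_min)) if t0_min > 0 else 0
    j_sig = max(j_sig, min(i_min + 2, len(Gs) - 1))
    # monotonic decay can only be demanded while the signal is resolved:
    # once |G| drops to its noise floor, later isolated bumps are sampling
    # artifacts and must not drag the split time outward
    if err is not None:
        resolved = np.nonzero(np.abs(Gs[i_min:j_sig + 1])
                              < allow[i_min:j_sig + 1])[0]
        if len(resolved):
            j_sig = min(j_sig, max(i_min + int(resolved[0]), i_min + 2))
    for i0 in range(i_min, j_sig + 1):
        seg = Gs[i0:j_sig + 1]
        # 2 sigma on the per-lag uncertainty: a single noisy dip must not
        # push the split far out and poison the numerical integral
        slack = mono_tol * seg[:-1] + 2.0 * allow[i0:j_sig]
        if np.all(seg > -2.0 * allow[i0:j_sig + 1]) and np.all(
                np.diff(seg) <= slack):
            # skip t = 0 (an integral split at zero leaves no short-time part)
            return float(G.t[i0]) if G.t[i0] > 0 else float(G.t[min(i0 + 1, len(G.t) - 1)])
    raise ValueError(
        "no time after which G(t) is positive and monotonically decaying; "
        "longer sampling required")


def fit_maxwell_modes(G: RelaxationModulus, t0: float,
                      modes_per_decade: float = 3.0,
                      weight_floor: float = 0.05) -> MaxwellSpectrum:
    """Nonnegative least-squares fit of G(t >= t0) to log-spaced Maxwell modes.

    Relaxation times span [t0/2, 2 t_max] with ``modes_per_decade`` modes per
    decade; amplitudes are constrained nonnegative (NNLS).  Residuals are
    weighted by 1/(|G| + weight_floor * max|G|): relative weighting where the
    modulus has decayed (so the small late-time values constrain the long
    modes that dominate the integral) blending into absolute weighting near
    the peak.  The fit is invariant to a rescaling of time units.
    """
    mask = G.t >= t0
    if mask.sum() < 2:
        raise ValueError("G(t) not defined beyond t0")
    t = G.t[mask]
    y = G.G[mask]
    t_max = t[-1]
    decades = math.log10(2.0 * t_max / (0.5 * t0))
    if decades < 1.0:
        raise ValueError(
            f"ill-conditioned fit: only {decades:.2f} decades beyond t0")
    n_modes = max(2, int(round(decades * modes_per_decade)) + 1)
    tau = np.logspace(math.log10(0.5 * t0), math.log10(2.0 * t_max), n_modes)
    A = np.exp(-t[:, None] / tau[None, :])
    y_max = float(np.max(np.abs(y)))
    w = (np.ones_like(y) if y_max == 0
         else 1.0 / (np.abs(y) + weight_floor * y_max))
    coef, rnorm = nnls(A * w[:, None], y * w)
    return MaxwellSpectrum(G_i=coef, tau_i=tau, t0=float(t0),
                           residual=float(rnorm))


def _short_time_integral(G: RelaxationModulus, t0: float) -> float:
    """Trapezoidal integral of G over [0, t0] on a spline-refined grid."""
    mask = G.t <= t0
    if mask.sum() < 2:
        return 0.0
    t = G.t[mask]
    y = G.G[mask]
    if t[-1] < t0 and np.any(G.t > t0):
        # include the bracketing point so the split is exactly at t0
        j = int(np.searchsorted(G.t, t0))
        t = np.append(t, G.t[j])
        y = np.append(y, G.G[j])
    # linear interpolation on a refined grid: exact split at t0, no spline
    # overshoot on oscillatory short-time data
    tt = np.linspace(t[0], t0, 4001)
    integral = np.trapezoid(np.interp(tt, t, y), tt)
    if t[0] > 0:  # leading sliver [0, first lag]: constant-G approximation
        integral += y[0] * t[0]
    return float(integral)


def viscosity_gk(G: RelaxationModulus, spectrum: MaxwellSpectrum,
                 block_moduli: list[RelaxationModulus] | None = None
                 ) -> tuple[float, float]:
    """Viscosity from the split Green-Kubo integral, with uncertainty.

    eta = int_0^t0 G dt (numerical) + sum_i G_i tau_i exp(-t0/tau_i)
    (analytic Maxwell tail).  If ``block_moduli`` are supplied (moduli from
    disjoint partitions of the stress series), the uncertainty is the
    standard error over blocks, else 0.
    """
    t0 = spectrum.t0
    if len(G.t) and not (G.t[0] <= t0 <= G.t[-1]):
        raise ValueError("spectrum t0 outside the modulus grid")
    eta = _short_time_integral(G, t0) + spectrum.tail_integral()
    err = 0.0
    if block_moduli:
        vals = []
        for Gb in block_moduli:
            try:
                sb = fit_maxwell_modes(Gb, t0)
                vals.append(_short_time_integral(Gb, t0) + sb.tail_integral())
            except ValueError:
                continue
        if len(vals) >= 2:
            err = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
    return float(eta), err


def complex_modulus_from_spectrum(
    spectrum: MaxwellSpectrum, G: RelaxationModulus | None,
    omegas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Storage and loss moduli G'(w), G''(w).

    The Maxwell modes transform analytically,
    G' = sum G_i (w tau)^2 / (1 + (w tau)^2),
    G'' = sum G_i (w tau) / (1 + (w tau)^2);
    the remainder (measured G minus the mode sum) is Fourier-transformed
    numerically on a per-frequency grid resolving the oscillations.  Pass the
    modulus trimmed to its statistically significant window (the pipeline's
    ``modulus_fit``): the remainder below t0 carries the short-time physics,
    the part up to the significance cut keeps fit residuals from leaking into
    the moduli, and anything beyond would integrate pure ACF noise.
    Terminal limits: G''/w -> eta and G'/w^2 finite as w -> 0.
    """
    omegas = np.asarray(omegas, dtype=np.float64)
    if np.any(omegas <= 0):
        raise ValueError("omegas must be positive")
    wt = omegas[:, None] * spectrum.tau_i[None, :]
    gp = np.sum(spectrum.G_i * wt**2 / (1 + wt**2), axis=1)
    gpp = np.sum(spectrum.G_i * wt / (1 + wt**2), axis=1)
    if G is not None and len(G.t) >= 4:
        t = G.t
        rem = G.G - spectrum.modulus(t)
        t_max = t[-1]
        # linear interpolation: never overshoots, which matters when the
        # short-time remainder carries (possibly under-resolved) molecular
        # oscillations
        for i, w in enumerate(omegas):
            n_pts = int(min(max(8000, 25 * w * t_max), 400_000))
            tt = np.linspace(t[0], t_max, n_pts)
            rr = np.interp(tt, t, rem)
            gp[i] += w * np.trapezoid(rr * np.sin(w * tt), tt)
            gpp[i] += w * np.trapezoid(rr * np.cos(w * tt), tt)
    return gp, gpp


def viscosity_from_stress_log(
    log: StressLog,
    channel_mode: str = "six_component",
    p: int = 16,
    m: int = 2,
    n_blocks: int = 5,
    modes_per_decade: float = 3.0,
    t0: float | None = None,
    t0_min: float = 0.0,
) -> dict:
    """End-to-end Green-Kubo pipeline on a sampled stress log.

    Builds the multiple-tau correlator (full series plus ``n_blocks``
    disjoint partitions for the uncertainty), extracts G(t), picks t0, fits
    the Maxwell tail and integrates.  Returns a dict with eta, eta_err, the
    modulus, the spectrum and t0.
    """
    dt_s = float(log.times[1] - log.times[0])
    chans = stress_channels(log.components)
    corr = MultiTauCorrelator(dt_s, p=p, m=m)
    corr.accumulate_channels(chans)
    G = relaxation_modulus(corr, log.volume, log.temperature, channel_mode)
    blocks = []
    nb = len(chans) // n_blocks
    for b in range(n_blocks):
        cb = MultiTauCorrelator(dt_s, p=p, m=m)
        cb.accumulate_channels(chans[b * nb:(b + 1) * nb])
        try:
            blocks.append(relaxation_modulus(cb, log.volume, log.temperature,
                                             channel_mode))
        except ValueError:
            pass
    G_err = None
    if len(blocks) >= 2:
        nl = min(len(b.G) for b in blocks)
        stack = np.vstack([b.G[:nl] for b in blocks])
        G_err = np.full(len(G.G), np.inf)
        G_err[:nl] = np.std(stack, axis=0, ddof=1) / math.sqrt(len(blocks))
    t0_val = (choose_t0(G, err=G_err, t0_min=t0_min) if t0 is None
              else float(t0))
    # fit the Maxwell tail over the lags beyond t0 that remain statistically
    # significant, keeping at least one decade so the fit stays conditioned
    i_t0 = int(np.searchsorted(G.t, t0_val))
    j_sig = significant_lag_index(G, G_err, i_start=i_t0)
    j_sig = max(j_sig, i_t0 + 2, int(np.searchsorted(G.t, 3.0 * t0_val)))
    j_sig = min(j_sig, len(G.t) - 1)
    G_fit = RelaxationModulus(G.t[:j_sig + 1], G.G[:j_sig + 1], G.volume,
                              G.temperature, G.channel_mode)
    spectrum = fit_maxwell_modes(G_fit, t0_val, modes_per_decade)
    block_fits = [RelaxationModulus(b.t[:j_sig + 1], b.G[:j_sig + 1],
                                    b.volume, b.temperature, b.channel_mode)
                  for b in blocks if len(b.t) > j_sig]
    eta, err = viscosity_gk(G_fit, spectrum, block_moduli=block_fits)
    return {"eta": eta, "eta_err": err, "modulus": G, "modulus_fit": G_fit,
            "spectrum": spectrum, "t0": t0_val, "G_err": G_err}
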