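"""Direct-coexistence phase diagrams and critical-point estimation.

In a direct-coexistence (DC) simulation both phases share one elongated box:
a dense slab of chains surrounded by vapor.  Averaged density profiles along
the slab axis show two plateaus; fitting a symmetric hyperbolic-tangent
interface form,

    rho(z) = (rho_l + rho_v)/2 - (rho_l - rho_v)/2 * tanh((|z - z0| - w)/d),

yields the coexisting densities at each temperature.  The critical point is
then located by fitting the law of rectilinear diameters together with the
order-parameter scaling law (3D-Ising exponent beta = 0.325 by default):

    rho_l - rho_v       = A (1 - T/Tc)^beta
    (rho_l + rho_v) / 2 = rho_c + B (Tc - T).

Builders for the initial configurations (a centred slab in an elongated box,
or a homogeneous bulk cube) place chains on a self-avoiding "snake" lattice
path with unit spacing, so bonds start at their rest length and no pair sits
below 0.8 sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .engine import SimulationState, Trajectory
from .potentials import ChainTopology

__all__ = [
    "DensityProfile",
    "CoexistencePoint",
    "CriticalPointFit",
    "build_slab",
    "build_bulk",
    "density_profile",
    "coexisting_densities",
    "fit_critical_point",
]

ISING_BETA = 0.325


@dataclass
class DensityProfile:
    """Mean reduced density per bin along the slab axis."""

    bin_centers: np.ndarray
    density: np.ndarray
    n_frames: int
    axis: int = 2

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bin width must be uniform")
        if np.any(self.density < -1e-12):
            raise ValueError("densities must be nonnegative")


@dataclass
class CoexistencePoint:
    """Coexisting reduced densities at one reduced temperature."""

    T: float
    rho_liquid: float
    rho_vapor: float
    rho_liquid_err: float = 0.0
    rho_vapor_err: float = 0.0
    interface_width: float = 0.0

    def __post_init__(self) -> None:
        if not self.rho_liquid > self.rho_vapor >= 0:
            raise ValueError("require rho_liquid > rho_vapor >= 0")


@dataclass
class CriticalPointFit:
    """Critical temperature and density from the rectilinear-diameters fit."""

    Tc: float
    rhoc: float
    A: float
    B: float
    beta: float
    Tc_err: float = 0.0
    rhoc_err: float = 0.0
    residual: float = 0.0

    def rho_branches(self, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        T = np.asarray(T, dtype=np.float64)
        diff = self.A * np.clip(1 - T / self.Tc, 0, None) ** self.beta
        mean = self.rhoc + self.B * (self.Tc - T)
        return mean + diff / 2, mean - diff / 2


# ---------------------------------------------------------------------------
# Configuration builders
# ---------------------------------------------------------------------------

def _snake_sites(n: int, nx: int, ny: int, nz: int) -> np.ndarray:
    """First n sites of a boustrophedon path through an nx*ny*nz unit lattice.

    Consecutive sites are lattice neighbors (distance exactly 1), so chains
    threaded along the path have all bonds at rest length and every pair of
    beads at distance >= 1.
    """
    if nx * ny * nz < n:
        raise ValueError("lattice too small for the requested bead count")
    sites = np.empty((n, 3))
    k = 0
    for z in range(nz):
        if k >= n:
            break
        ys = range(ny) if z % 2 == 0 else range(ny - 1, -1, -1)
        for y in ys:
            if k >= n:
                break
            xs = range(nx) if (y + z) % 2 == 0 else range(nx - 1, -1, -1)
            for x in xs:
                if k >= n:
                    break
                sites[k] = (x, y, z)
                k += 1
    return sites


def build_bulk(topology: ChainTopology, rho: float,
               jitter: float = 0.0, seed: int = 0) -> SimulationState:
    """Homogeneous cubic configuration at reduced density ``rho``.

    Chains are threaded along a snake-lattice path (spacing 1 sigma) filling
    the cube from one corner; with ``rho < 1`` the remainder is vacuum that
    fills in during equilibration.
    """
    n = topology.n_beads
    L = (n / rho) ** (1.0 / 3.0)
    m = int(math.floor(L))
    sites = _snake_sites(n, m, m, m) + 0.5
    if jitter > 0:
        rng = np.random.default_rng(seed)
        sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
    vel = np.zeros_like(sites)
    return SimulationState(sites, vel, np.array([L, L, L]), seed=seed)


def build_slab(topology: ChainTopology, rho_init: float,
               elongation: float = 3.0, seed: int = 0) -> SimulationState:
    """Dense slab centred in an elongated box with vacuum on both sides.

    The slab is built at density ``rho_init`` spanning the full x/y cross
    section; the box's z edge is ``elongation`` times the transverse edges.
    No pair of beads sits closer than 0.8 sigma by construction.
    """
    if elongation < 3.0:
        raise ValueError("elongated axis must be >= 3x the transverse edges")
    n = topology.n_beads
    # slab volume n/rho_init with square cross section Lt^2 and height h
    # chosen so the box (Lt, Lt, elongation*Lt) leaves vacuum above and below
    Lt = (n / rho_init / (0.6 * elongation)) ** (1.0 / 3.0)
    h = n / rho_init / Lt**2
    if h > 0.9 * elongation * Lt:
        raise ValueError(
            f"density {rho_init} unachievable without overlap in a "
            f"{elongation}x elongated box")
    nx = max(int(math.floor(Lt)), 1)
    ny = nx
    nz = int(math.ceil(n / (nx * ny))) + 1
    sites = _snake_sites(n, nx, ny, nz) + 0.5
    Lz = elongation * Lt
    # centre the slab in z
    z_extent = sites[:, 2].max() - sites[:, 2].min()
    if z_extent > 0.9 * Lz:
        raise ValueError("slab too tall for the requested box")
    sites[:, 2] += 0.5 * Lz - 0.5 * (sites[:, 2].min() + sites[:, 2].max())
    # centre transversally too (cosmetic)
    for a in range(2):
        sites[:, a] += 0.5 * (Lt - nx)
    vel = np.zeros_like(sites)
    return SimulationState(sites, vel, np.array([Lt, Lt, Lz]), seed=seed)


# ---------------------------------------------------------------------------
# Profile analysis
# ---------------------------------------------------------------------------

def density_profile(trajectory: Trajectory | list[np.ndarray],
                    box: np.ndarray | None = None, axis: int = 2,
                    n_bins: int = 60, recenter: bool = True) -> DensityProfile:
    """Frame-averaged reduced density profile along one axis.

    Each frame is recentred by the densest half-window (cyclic convolution
    with a box kernel) before averaging, so slab drift does not smear the
    interfaces; pass ``recenter=False`` to skip (profiles then differ only
    by a cyclic shift).
    """
    if isinstance(trajectory, Trajectory):
        frames = [trajectory.positions[i] for i in range(len(trajectory.times))]
        box = trajectory.box
    else:
        frames = list(trajectory)
        if box is None:
            raise ValueError("box required with raw frame lists")
    if len(frames) < 10:
        raise ValueError("need >= 10 frames for a density profile")
    L = float(box[axis])
    area = float(np.prod(box)) / L
    edges = np.linspace(0, L, n_bins + 1)
    width = L / n_bins
    total = np.zeros(n_bins)
    for pos in frames:
        z = np.mod(pos[:, axis], L)
        hist, _ = np.histogram(z, bins=edges)
        if recenter:
            kernel = np.zeros(n_bins)
            half = n_bins // 2
            kernel[:half] = 1.0
            # cyclic correlation: window starting at each bin
            dens_win = np.real(np.fft.ifft(np.fft.fft(hist)
                                           * np.conj(np.fft.fft(kernel))))
            start = int(np.argmax(dens_win))
            # roll so the densest window is centred
            hist = np.roll(hist, n_bins // 2 - (start + half // 2) % n_bins)
        total += hist
    rho = total / len(frames) / (area * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(bin_centers=centers, density=rho,
                          n_frames=len(frames), axis=axis)


def _tanh_profile(z, rho_l, rho_v, z0, half_width, d):
    return (0.5 * (rho_l + rho_v)
            - 0.5 * (rho_l - rho_v) * np.tanh((np.abs(z - z0) - half_width) / d))


def coexisting_densities(profile: DensityProfile, T: float = 0.0,
                         n_block: int = 1) -> CoexistencePoint:
    """Fit the symmetric tanh interface form and return plateau densities.

    Raises when the profile shows no coexistence (flat within scatter or
    inverted plateaus).  Uncertainties, when the profile carries block
    sub-profiles, come from block averaging; otherwise from the fit
    covariance.
    """
    z = profile.bin_centers
    rho = profile.density
    lo, hi = float(np.min(rho)), float(np.max(rho))
    if hi - lo < 0.05 * max(hi, 1e-12) or hi - lo < 1e-6:
        raise ValueError("no coexistence: density profile is flat")
    z0_guess = float(z[np.argmax(rho)])
    span = z[-1] - z[0]
    p0 = [hi, lo, z0_guess, span / 6, span / 30]
    bounds = ([0, 0, z[0], 0, 1e-6], [10 * hi, hi, z[-1], span, span])
    try:
        popt, pcov = curve_fit(_tanh_profile, z, rho, p0=p0, bounds=bounds,
                               maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(
            f"interface fit did not converge (initial guesses {p0})") from exc
    rho_l, rho_v, z0, half_width, d = popt
    errs = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if rho_l <= rho_v:
        raise ValueError("no coexistence: fitted liquid density below vapor")
    return CoexistencePoint(T=T, rho_liquid=float(rho_l),
                            rho_vapor=float(rho_v),
                            rho_liquid_err=float(errs[0]),
                            rho_vapor_err=float(errs[1]),
                            interface_width=float(d))


def fit_critical_point(points: list[CoexistencePoint],
                       beta: float = ISING_BETA) -> CriticalPointFit:
    """Simultaneous scaling-law + rectilinear-diameters fit.

    Fits rho_l - rho_v = A (1 - T/Tc)^beta and
    (rho_l + rho_v)/2 = rho_c + B (Tc - T) with beta fixed, by least squares
    over (Tc, rho_c, A, B).  Exact on noise-free synthetic data.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 coexistence points")
    T = np.array([p.T for p in points])
    diff = np.array([p.rho_liquid - p.rho_vapor for p in points])
    mean = np.array([(p.rho_liquid + p.rho_vapor) / 2 for p in points])

    T_max = T.max()

    def residuals(theta):
        Tc, rhoc, A, B = theta
        red = np.clip(1 - T / Tc, 1e-12, None)
        return np.concatenate([
            A * red**beta - diff,
            rhoc + B * (Tc - T) - mean,
        ])

    # initial guess by linearizing the scaling law: diff^(1/beta) = a + b T
    # is exact for noise-free data, giving Tc0 = -a/b and A0 = a^beta Tc0...
    u = diff ** (1.0 / beta)
    b_lin, a_lin = np.polyfit(T, u, 1)
    if b_lin < 0 and a_lin > 0:
        Tc0 = -a_lin / b_lin
        A0 = a_lin**beta if a_lin > 0 else diff.max()
    else:
        Tc0, A0 = T_max * 1.1, diff.max()
    Tc0 = max(Tc0, T_max * 1.005)
    b_mean, a_mean = np.polyfit(Tc0 - T, mean, 1)
    x0 = [Tc0, float(a_mean), float(A0), float(b_mean)]
    sol = least_squares(residuals, x0,
                        bounds=([T_max * 1.0001, 0, 0, -np.inf],
                                [np.inf, np.inf, np.inf, np.inf]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    Tc, rhoc, A, B = sol.x
    if not sol.success:
        raise ValueError(f"critical-point fit failed: {sol.message}")
    # covariance from the Jacobian at the solution
    try:
        J = sol.jac
        dof = max(len(sol.fun) - 4, 1)
        s2 = float(sol.fun @ sol.fun) / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        Tc_err, rhoc_err = math.sqrt(abs(cov[0, 0])), math.sqrt(abs(cov[1, 1]))
    except np.linalg.LinAlgError:
        Tc_err = rhoc_err = float("nan")
    return CriticalPointFit(Tc=float(Tc), rhoc=float(rhoc), A=float(A),
                            B=float(B), beta=beta, Tc_err=Tc_err,
                            rhoc_err=rhoc_err,
                            residual=float(np.sqrt(np.mean(sol.fun**2))))
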