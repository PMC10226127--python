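"""Passive probe-bead microrheology (bead tracking).

A single inert probe bead of radius R is inserted into a bulk condensate;
its mean-squared displacement g3(t) = <(r(t) - r(0))^2> yields the
diffusion coefficient in the Fickian (diffusive) regime,

    D = lim_{t->inf} g3(t) / (6 t),

and the medium viscosity follows from the Stokes-Einstein relation with the
no-slip boundary condition,

    eta = kB T / (6 pi R D).

The probe interacts with the medium through a purely repulsive
Ashbaugh-Hatch potential (epsilon = 4 for no-slip, lambda = 0, i.e. a WCA
pseudo-hard sphere), with a cutoff of three probe diameters and unit mass.
The estimate is only meaningful when the probe is larger than the
condensate mesh size and when a genuine diffusive window (log-log slope 1)
exists; the plateau detector reports the documented "no diffusive regime"
failure mode otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import PairTable, SimulationState, Simulation, Trajectory
from .potentials import PairPotentialSpec

__all__ = [
    "ProbeBead",
    "MSDCurve",
    "insert_probe",
    "msd",
    "plateau_RD",
    "viscosity_stokes_einstein",
    "NoDiffusiveRegime",
]


class NoDiffusiveRegime(Exception):
    """Raised when no Fickian window exists (documented BT failure mode)."""


@dataclass
class ProbeBead:
    """Geometry and interaction of the single inert probe."""

    radius: float = 3.0
    epsilon: float = 4.0
    lambda_scale: float = 0.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def cutoff(self) -> float:
        # three probe molecular diameters
        return 3.0 * self.diameter

    def cross_spec(self, medium_sigma: float = 1.0) -> PairPotentialSpec:
        """Probe-medium interaction: arithmetic-mean cross diameter."""
        return PairPotentialSpec(
            kind="ashbaugh_hatch", epsilon=self.epsilon,
            sigma=0.5 * (self.diameter + medium_sigma),
            lambda_scale=self.lambda_scale, cutoff=self.cutoff)


@dataclass
class MSDCurve:
    """Probe mean-squared displacement g3(t) on a log-spaced lag grid."""

    t: np.ndarray
    g3: np.ndarray
    n_origins: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.g3 < 0):
            raise ValueError("g3 must be nonnegative")


def insert_probe(sim: Simulation, probe: ProbeBead,
                 rng: np.random.Generator | None = None,
                 n_candidates: int = 512, growth_steps: int = 40,
                 relax_per_stage: int = 400,
                 max_pair_energy: float = 10.0) -> Simulation:
    """Insert a probe into a bulk configuration by growth from 0.1 R.

    The insertion point is the candidate position with the largest clearance
    to any medium bead; the probe's interaction diameter is then grown in
    stages from 10% to 100% of its final value, each stage followed by a
    short burst of Langevin dynamics (soft push: the medium flows around the
    growing cavity).  Fails when any single probe-medium pair ends above
    ``max_pair_energy`` (in units of the pair epsilon).

    Returns a new Simulation containing the probe as the last particle (its
    own type ``probe``), excluded from Langevin noise so its dynamics
    reflect medium friction only.
    """
    rng = rng or np.random.default_rng(sim.state.seed)
    st = sim.state
    st.wrap()
    box = st.box
    # pick the candidate point with maximal distance to the nearest bead
    cands = rng.uniform(0, 1, size=(n_candidates, 3)) * box
    best, best_d = None, -1.0
    pos = st.positions
    for c in cands:
        d = pos - c
        d -= np.rint(d / box) * box
        dmin = float(np.min(np.sqrt((d**2).sum(axis=1))))
        if dmin > best_d:
            best_d, best = dmin, c
    n = st.n
    new_pos = np.vstack([pos, best])
    new_vel = np.vstack([st.velocities,
                         rng.normal(scale=math.sqrt(
                             sim.config.target_T / probe.mass), size=3)])
    table = PairTable(sim.pair_table.type_names + ["probe"])
    nt = sim.pair_table.n_types
    table.eps[:nt, :nt] = sim.pair_table.eps
    table.sigma[:nt, :nt] = sim.pair_table.sigma
    table.lam[:nt, :nt] = sim.pair_table.lam
    table.kind[:nt, :nt] = sim.pair_table.kind
    table.rcut[:nt, :nt] = sim.pair_table.rcut
    table.dh_pref[:nt, :nt] = sim.pair_table.dh_pref
    table.dh_rcut[:nt, :nt] = sim.pair_table.dh_rcut
    table.dh_kappa = sim.pair_table.dh_kappa

    new_state = SimulationState(new_pos, new_vel, box.copy(), tilt=st.tilt,
                                time=st.time, seed=st.seed)
    type_ids = np.append(sim.type_ids, nt)
    masses = np.append(sim.masses, probe.mass)
    medium_sigma = float(np.max(sim.pair_table.sigma))

    def set_cross(scale: float) -> None:
        d_eff = scale * probe.diameter
        for k, name in enumerate(sim.pair_table.type_names):
            sig_cross = 0.5 * (d_eff + medium_sigma)
            cut = max(3.0 * d_eff, 1.5 * medium_sigma)
            if probe.lambda_scale == 0.0:
                # WCA limit: the potential is identically zero beyond its
                # minimum, so the formal 3-diameter cutoff can be truncated
                # there (bit-identical forces, box-size friendly)
                cut = min(cut, 2.0 ** (1.0 / 6.0) * sig_cross * 1.0001)
            spec = PairPotentialSpec(
                kind="ashbaugh_hatch", epsilon=probe.epsilon,
                sigma=sig_cross, lambda_scale=probe.lambda_scale, cutoff=cut)
            table.set_pair(name, "probe", spec)

    set_cross(0.1)
    from .engine import IntegratorConfig
    grow_cfg = IntegratorConfig(dt=sim.config.dt,
                                thermostat="langevin",
                                target_T=sim.config.target_T,
                                damping=max(0.1, 20 * sim.config.dt),
                                stress_stride=0)
    grown = Simulation(new_state, table, sim.topology, type_ids=type_ids,
                       masses=masses, config=grow_cfg, skin=sim.skin)
    grown.noise_mask = np.append(np.ones(n, dtype=np.int64), 0)
    # stage-wise growth: enlarge the probe, let the medium flow around it
    for scale in np.linspace(0.1, 1.0, growth_steps):
        set_cross(scale)
        try:
            grown.run(relax_per_stage, stress_stride=0)
        except FloatingPointError:
            raise RuntimeError("probe insertion failed: hard overlap")
    grown.run(4 * relax_per_stage, stress_stride=0)
    e_pair = _probe_max_pair_energy(grown, probe)
    if e_pair > max_pair_energy * probe.epsilon:
        raise RuntimeError(
            f"probe insertion failed: max probe-medium pair energy "
            f"{e_pair:.2f} exceeds {max_pair_energy} eps")
    grown.config = sim.config
    grown.state.images[:] = 0
    grown.state.time = sim.state.time
    return grown


def _probe_max_pair_energy(sim: Simulation, probe: ProbeBead) -> float:
    """Largest single probe-medium pair energy (last particle = probe)."""
    st = sim.state
    p = st.positions[-1]
    d = st.positions[:-1] - p
    d -= np.rint(d / st.box) * st.box
    r = np.sqrt((d**2).sum(axis=1))
    nt = sim.pair_table.n_types - 1
    e_max = 0.0
    for i, ri in enumerate(r):
        ti = sim.type_ids[i]
        spec = PairPotentialSpec(
            kind="ashbaugh_hatch", epsilon=probe.epsilon,
            sigma=sim.pair_table.sigma[ti, nt],
            lambda_scale=probe.lambda_scale,
            cutoff=sim.pair_table.rcut[ti, nt])
        if ri < spec.cutoff:
            e_max = max(e_max, spec.energy_force(ri)[0])
    return e_max


def msd(trajectory: Trajectory | tuple[np.ndarray, np.ndarray],
        n_lags: int = 40, particle: int = 0,
        max_lag_fraction: float = 0.125) -> MSDCurve:
    """Multiple-time-origin MSD of one tracked particle on a log lag grid.

    Coordinates must be unwrapped; a jump larger than half the box (when the
    box is known) triggers an error.  Origins are spaced ``lag/2`` apart so
    successive displacement samples overlap at most 50%.
    """
    if isinstance(trajectory, Trajectory):
        times = trajectory.times
        pos = trajectory.positions[:, particle, :]
        box = trajectory.box
        jumps = np.abs(np.diff(pos, axis=0))
        if np.any(jumps > 0.5 * box[None, :]):
            raise ValueError(
                "wrapped coordinates detected (jump > box/2); msd requires "
                "unwrapped input")
    else:
        times, pos = trajectory
        pos = np.asarray(pos, dtype=np.float64)
    n = len(times)
    if n < 8:
        raise ValueError("trajectory too short for MSD analysis")
    dt = float(times[1] - times[0])
    # lags beyond ~n/8 average too few origins to carry statistical weight
    max_lag = max(int(n * max_lag_fraction), 4)
    lags = np.unique(np.geomspace(1, max_lag, n_lags).astype(np.int64))
    g3 = np.empty(len(lags))
    n_origins = np.empty(len(lags), dtype=np.int64)
    for i, lag in enumerate(lags):
        stride = max(int(lag) // 2, 1)
        origins = np.arange(0, n - lag, stride)
        disp = pos[origins + lag] - pos[origins]
        g3[i] = float(np.mean((disp**2).sum(axis=1)))
        n_origins[i] = len(origins)
    return MSDCurve(t=lags * dt, g3=g3, n_origins=n_origins)


def plateau_RD(curve: MSDCurve, radius: float, slope_tol: float = 0.05,
               min_window_decades: float = 0.5) -> tuple[float, dict]:
    """Terminal plateau of R * g3 / (6 t): the product R*D.

    Identifies the longest terminal window over which the log-log slope of
    g3 is within ``slope_tol`` of 1 and averages R g3/(6t) there.  Raises
    :class:`NoDiffusiveRegime` when the window spans less than
    ``min_window_decades`` decades (e.g. subdiffusive dynamics).
    """
    t, g3 = curve.t, curve.g3
    pos_mask = (t > 0) & (g3 > 0)
    t, g3 = t[pos_mask], g3[pos_mask]
    if len(t) < 4 or t[-1] / t[0] < 100.0:
        raise ValueError("MSD must span at least 2 decades")
    lt, lg = np.log(t), np.log(g3)

    def window_slope(i: int, j: int) -> float:
        x, y = lt[i:j + 1], lg[i:j + 1]
        xm, ym = x.mean(), y.mean()
        return float(((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm)))

    # longest terminal window whose overall regression slope is 1 +- tol and
    # whose two halves are individually diffusive (rejects crossover
    # curvature that a full-window slope alone would average away); the
    # window must end within the final decade of the data
    n = len(t)
    min_span = 10.0**min_window_decades
    best = None
    for j in range(n - 1, -1, -1):
        if t[j] < t[-1] / 10.0:
            break
        for i in range(j - 2, -1, -1):
            if t[j] / t[i] < min_span:
                continue
            mid = (i + j) // 2
            if (abs(window_slope(i, j) - 1.0) <= slope_tol
                    and abs(window_slope(i, mid) - 1.0) <= 1.5 * slope_tol
                    and abs(window_slope(mid, j) - 1.0) <= 1.5 * slope_tol):
                if best is None or (lt[j] - lt[i]) > (lt[best[1]] - lt[best[0]]):
                    best = (i, j)
    if best is None:
        raise NoDiffusiveRegime(
            "no diffusive regime: no terminal window with log-log slope "
            f"1 +- {slope_tol} spanning {min_window_decades} decades")
    start, end = best
    diagnostics = {"window": (start, end + 1),
                   "slope": window_slope(start, end),
                   "t_window": (float(t[start]), float(t[end]))}
    rd = radius * g3[start:end + 1] / (6.0 * t[start:end + 1])
    # weight by origin count: short lags carry many more independent samples
    w = curve.n_origins[pos_mask][start:end + 1].astype(np.float64)
    diagnostics["rd_values"] = rd
    return float(np.sum(w * rd) / np.sum(w)), diagnostics


def viscosity_stokes_einstein(D: float, radius: float,
                              temperature: float) -> float:
    """Stokes-Einstein viscosity eta = kB T / (6 pi R D), no-slip."""
    if D <= 0 or radius <= 0:
        raise ValueError("D and radius must be positive")
    return temperature / (6.0 * math.pi * radius * D)


def finite_size_correct_D(D_box: float, radius: float,
                          box_length: float) -> float:
    """Infinite-box diffusion coefficient from a periodic-box measurement.

    Periodic hydrodynamic self-images slow a probe down; to leading order
    (cubic-lattice Ewald term, the standard Yeh-Hummer correction combined
    self-consistently with Stokes-Einstein),

        D_inf = D_box / (1 - 2.837297 R / L).

    For a probe that is not small relative to the box the correction is
    large and approximate; the packaged condensate boxes (R/L ~ 0.2) lean
    on it heavily, which is part of the documented price of the scaled-down
    study systems.
    """
    factor = 1.0 - 2.837297 * radius / box_length
    if factor <= 0:
        raise ValueError(
            f"box too small for the finite-size correction (R/L = "
            f"{radius / box_length:.2f} >= 0.352)")
    return D_box / factor
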