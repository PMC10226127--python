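"""Molecular dynamics engine for coarse-grained condensate rheology.

NVT/NVE velocity-Verlet dynamics of bead-spring chains in a periodic,
optionally xy-tilted (sheared) box, with:

* Verlet neighbor lists (skin 0.4 sigma, rebuilt on half-skin displacement),
* Lennard-Jones / Ashbaugh-Hatch short-range pair potentials plus an optional
  additive Debye-Hueckel term, per type pair,
* stiff harmonic bonds with bonded-pair nonbonded exclusions,
* instantaneous virial + kinetic stress-tensor sampling (the input of the
  Green-Kubo pipeline),
* Langevin (equilibration) and single Nose-Hoover (production; momentum
  conserving, so it does not contaminate stress fluctuations) thermostats,
* sinusoidal box shear gamma_xy(t) = gamma0 sin(omega t) with affine
  coordinate remapping (a Lees-Edwards-equivalent tilting cell),
* an optional pairwise interaction-strengthening table used by the aging
  algorithm (LARKS-LARKS beta-sheet bonds).

The hot loops are numba-jitted; a trajectory of millions of steps for a
thousand beads runs in minutes on one core.  All quantities are in reduced
LJ units (kB = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .potentials import BondSpec, ChainTopology, PairPotentialSpec

__all__ = [
    "SimulationState",
    "StressTensorSample",
    "IntegratorConfig",
    "PairTable",
    "Simulation",
    "StressLog",
    "Trajectory",
    "apply_oscillatory_shear",
    "initialize_velocities",
]

DEFAULT_SKIN = 0.4

THERMO_NONE = 0
THERMO_LANGEVIN = 1
THERMO_NOSE_HOOVER = 2
_THERMO_CODES = {"none": THERMO_NONE, "langevin": THERMO_LANGEVIN,
                 "nose_hoover": THERMO_NOSE_HOOVER}

STRESS_COLUMNS = ("sxx", "syy", "szz", "sxy", "sxz", "syz")


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Positions, velocities, periodic box and clock of a running system.

    Positions are stored wrapped into the primary cell together with integer
    image counters, so unwrapped displacements (needed for MSD analysis) are
    exact.  ``tilt`` is the xy tilt factor: gamma_xy = tilt / box[1].
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    tilt: float = 0.0
    time: float = 0.0
    seed: int = 0
    images: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.images is None:
            self.images = np.zeros_like(self.positions, dtype=np.int64)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities shapes differ")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def gamma_xy(self) -> float:
        return self.tilt / self.box[1]

    def unwrapped_positions(self) -> np.ndarray:
        """Unwrapped coordinates (exact via image counters)."""
        out = self.positions + self.images * self.box
        out[:, 0] += self.images[:, 1] * self.tilt
        return out

    def wrap(self) -> None:
        _wrap_positions(self.positions, self.images, self.box[0], self.box[1],
                        self.box[2], self.tilt)

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(), velocities=self.velocities.copy(),
            box=self.box.copy(), tilt=self.tilt, time=self.time,
            seed=self.seed, images=self.images.copy(),
        )


@dataclass(frozen=True)
class StressTensorSample:
    """Instantaneous six-component stress with separable kinetic/virial parts.

    Components are ordered (xx, yy, zz, xy, xz, yz) in energy/volume units;
    the tensor is symmetric by construction and trace/3 is the instantaneous
    pressure.
    """

    time: float
    virial: np.ndarray
    kinetic: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.virial + self.kinetic

    @property
    def pressure(self) -> float:
        return float(np.sum(self.total[:3]) / 3.0)


@dataclass
class IntegratorConfig:
    """Timestep, thermostat and sampling strides."""

    dt: float = 0.005
    thermostat: str = "nose_hoover"
    target_T: float = 1.0
    damping: float = 0.5
    stress_stride: int = 5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat not in _THERMO_CODES:
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and self.damping <= self.dt:
            raise ValueError("thermostat relaxation time must exceed dt")


@dataclass
class StressLog:
    """Time series of stress-tensor samples (total = kinetic + virial)."""

    times: np.ndarray
    components: np.ndarray  # (n_samples, 6)
    volume: float
    temperature: float

    def channel(self, name: str) -> np.ndarray:
        return self.components[:, STRESS_COLUMNS.index(name)]


@dataclass
class Trajectory:
    """Stored frames of (a subset of) unwrapped particle coordinates."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_tracked, 3), unwrapped
    box: np.ndarray
    tilts: np.ndarray
    indices: np.ndarray


# ---------------------------------------------------------------------------
# Pair interaction tables (per bead type)
# ---------------------------------------------------------------------------

class PairTable:
    """Symmetric per-type-pair interaction matrices fed to the kernels.

    ``kind`` selects LJ or Ashbaugh-Hatch for the short-range part; an
    additive Debye-Hueckel term is active wherever its prefactor is nonzero.
    """

    def __init__(self, type_names: Sequence[str]):
        self.type_names = list(type_names)
        nt = len(self.type_names)
        self.eps = np.zeros((nt, nt))
        self.sigma = np.ones((nt, nt))
        self.lam = np.ones((nt, nt))
        self.kind = np.zeros((nt, nt), dtype=np.int64)
        self.rcut = np.zeros((nt, nt))
        self.dh_pref = np.zeros((nt, nt))
        self.dh_rcut = np.zeros((nt, nt))
        self.dh_kappa = 0.0  # inverse screening length

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def index(self, name: str) -> int:
        return self.type_names.index(name)

    def set_pair(self, a: str, b: str, spec: PairPotentialSpec) -> None:
        i, j = self.index(a), self.index(b)
        if spec.kind == "debye_huckel":
            self.dh_pref[i, j] = self.dh_pref[j, i] = (
                spec.coulomb_prefactor * spec.charge_product)
            self.dh_rcut[i, j] = self.dh_rcut[j, i] = spec.cutoff
            self.dh_kappa = 1.0 / spec.screening_length
            return
        self.eps[i, j] = self.eps[j, i] = spec.epsilon
        self.sigma[i, j] = self.sigma[j, i] = spec.sigma
        self.lam[i, j] = self.lam[j, i] = spec.lambda_scale
        self.kind[i, j] = self.kind[j, i] = spec.kind_code
        self.rcut[i, j] = self.rcut[j, i] = spec.cutoff

    @classmethod
    def uniform(cls, spec: PairPotentialSpec, name: str = "A") -> "PairTable":
        t = cls([name])
        t.set_pair(name, name, spec)
        return t

    def max_cutoff(self) -> float:
        return float(max(self.rcut.max(), self.dh_rcut.max()))


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _wrap_positions(pos, img, Lx, Ly, Lz, tilt):
    n = pos.shape[0]
    for i in range(n):
        nz = math.floor(pos[i, 2] / Lz)
        pos[i, 2] -= nz * Lz
        img[i, 2] += nz
        ny = math.floor(pos[i, 1] / Ly)
        pos[i, 1] -= ny * Ly
        pos[i, 0] -= ny * tilt
        img[i, 1] += ny
        nx = math.floor(pos[i, 0] / Lx)
        pos[i, 0] -= nx * Lx
        img[i, 0] += nx


@njit(cache=True, inline="always")
def _mi(dx, dy, dz, Lx, Ly, Lz, tilt):
    """Minimum image displacement in an xy-tilted periodic cell."""
    nz = np.rint(dz / Lz)
    dz -= nz * Lz
    ny = np.rint(dy / Ly)
    dy -= ny * Ly
    dx -= ny * tilt
    nx = np.rint(dx / Lx)
    dx -= nx * Lx
    return dx, dy, dz


@njit(cache=True, fastmath=True, error_model="numpy")
def _build_nlist(pos, Lx, Ly, Lz, tilt, rlist2, excl, nlist, nshift, ncount):
    """Half Verlet list with per-pair periodic shift vectors.

    Positions must be wrapped on entry.  The stored integer shifts fix the
    minimum-image choice for each pair, valid until any particle moves more
    than half the skin (the rebuild criterion), provided every box edge
    exceeds twice the list radius.
    """
    n = pos.shape[0]
    cap = nlist.shape[1]
    for i in range(n):
        ncount[i] = 0
    for i in range(n):
        for j in range(i + 1, n):
            if j == excl[i, 0] or j == excl[i, 1]:
                continue
            dx0 = pos[i, 0] - pos[j, 0]
            dy0 = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            sz = int(np.rint(dz / Lz))
            dz -= sz * Lz
            # in a tilted cell the minimal image is not always the one with
            # minimal |dy|: scan the neighboring y-images too
            sy0 = int(np.rint(dy0 / Ly))
            best = 1e300
            bsx = 0
            bsy = 0
            bdx = 0.0
            bdy = 0.0
            for dsy in range(-1, 2):
                sy = sy0 + dsy
                dy = dy0 - sy * Ly
                dx = dx0 - sy * tilt
                sx = int(np.rint(dx / Lx))
                dx -= sx * Lx
                r2 = dx * dx + dy * dy
                if r2 < best:
                    best = r2
                    bsx = sx
                    bsy = sy
                    bdx = dx
                    bdy = dy
            if bdx * bdx + bdy * bdy + dz * dz <= rlist2:
                k = ncount[i]
                if k >= cap:
                    return 1
                nlist[i, k] = j
                nshift[i, k, 0] = -bsx
                nshift[i, k, 1] = -bsy
                nshift[i, k, 2] = -sz
                ncount[i] += 1
    return 0


@njit(cache=True, fastmath=True, error_model="numpy")
def _forces(pos, type_id, eps_t, sig2_t, lam_t, kind_t, rcut2_t,
            dh_pref_t, dh_kappa, dh_rcut2_t,
            larks_id, strong, strong_factor,
            bonds, bond_k, bond_r0,
            Lx, Ly, Lz, tilt, nlist, nshift, ncount, forces, w):
    """Pair + bond forces, potential energy and virial tensor.

    ``w`` receives the six components of sum_pairs r_a f_b (symmetric).
    Returns the potential energy (non-finite when particles overlap).
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for a in range(6):
        w[a] = 0.0
    pe = 0.0
    for i in range(n):
        ti = type_id[i]
        li = larks_id[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        fix = 0.0
        fiy = 0.0
        fiz = 0.0
        for k in range(ncount[i]):
            j = nlist[i, k]
            tj = type_id[j]
            dx = (xi - pos[j, 0] + nshift[i, k, 0] * Lx
                  + nshift[i, k, 1] * tilt)
            dy = yi - pos[j, 1] + nshift[i, k, 1] * Ly
            dz = zi - pos[j, 2] + nshift[i, k, 2] * Lz
            r2 = dx * dx + dy * dy + dz * dz
            fsc = 0.0
            if r2 < rcut2_t[ti, tj]:
                eps = eps_t[ti, tj]
                lj = larks_id[j]
                if li >= 0 and lj >= 0 and li != lj and strong[li, lj] != 0:
                    eps *= strong_factor
                s2 = sig2_t[ti, tj] / r2
                sr6 = s2 * s2 * s2
                sr12 = sr6 * sr6
                u = 4.0 * eps * (sr12 - sr6)
                f = 24.0 * eps * (2.0 * sr12 - sr6) / r2
                if kind_t[ti, tj] == 1:  # Ashbaugh-Hatch
                    lam = lam_t[ti, tj]
                    if r2 <= 1.2599210498948732 * sig2_t[ti, tj]:  # (2^(1/6) s)^2
                        u = u + (1.0 - lam) * eps
                    else:
                        u = lam * u
                        f = lam * f
                pe += u
                fsc += f
            if dh_pref_t[ti, tj] != 0.0 and r2 < dh_rcut2_t[ti, tj]:
                r = math.sqrt(r2)
                pref = dh_pref_t[ti, tj]
                e = math.exp(-r * dh_kappa)
                pe += pref * e / r
                fsc += pref * e * (1.0 / (r2 * r) + dh_kappa / r2)
            if fsc != 0.0:
                fx = fsc * dx
                fy = fsc * dy
                fz = fsc * dz
                fix += fx
                fiy += fy
                fiz += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
                w[0] += dx * fx
                w[1] += dy * fy
                w[2] += dz * fz
                w[3] += dx * fy
                w[4] += dx * fz
                w[5] += dy * fz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx, dy, dz = _mi(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1],
                         pos[i, 2] - pos[j, 2], Lx, Ly, Lz, tilt)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        pe += bond_k[b] * dr * dr
        fsc = -2.0 * bond_k[b] * dr / r
        fx = fsc * dx
        fy = fsc * dy
        fz = fsc * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        w[0] += dx * fx
        w[1] += dy * fy
        w[2] += dz * fz
        w[3] += dx * fy
        w[4] += dx * fz
        w[5] += dy * fz
    return pe


@njit(cache=True, error_model="numpy")
def _kinetic_tensor(vel, mass, kin):
    n = vel.shape[0]
    for a in range(6):
        kin[a] = 0.0
    for i in range(n):
        m = mass[i]
        kin[0] += m * vel[i, 0] * vel[i, 0]
        kin[1] += m * vel[i, 1] * vel[i, 1]
        kin[2] += m * vel[i, 2] * vel[i, 2]
        kin[3] += m * vel[i, 0] * vel[i, 1]
        kin[4] += m * vel[i, 0] * vel[i, 2]
        kin[5] += m * vel[i, 1] * vel[i, 2]


@njit(cache=True, error_model="numpy")
def _run_md(pos, img, vel, mass, type_id,
            eps_t, sig2_t, lam_t, kind_t, rcut2_t,
            dh_pref_t, dh_kappa, dh_rcut2_t,
            larks_id, strong, strong_factor,
            bonds, bond_k, bond_r0, excl,
            Lx, Ly, Lz, tilt_in, time_in,
            dt, n_steps, thermo, T_target, damping, xi_in, dof,
            noise_mask, seed,
            gamma0, omega, shear_t0,
            stress_stride, stress_out, stress_kin_out, stress_t_out,
            pe_out, ke_out,
            traj_stride, traj_idx, traj_pos, traj_t, traj_tilt,
            rlist, nlist, nshift, ncount, ref_pos):
    """Advance ``n_steps`` of velocity-Verlet dynamics entirely in machine code.

    Returns (status, tilt, time, xi, n_sampled, n_frames); status is 0 on
    success, 1 on neighbor-list overflow, 2 on non-finite forces.
    """
    n = pos.shape[0]
    tilt = tilt_in
    t = time_in
    xi = xi_in
    np.random.seed(seed)
    forces = np.zeros((n, 3))
    w = np.zeros(6)
    kin = np.zeros(6)
    half_skin2 = ((rlist - math.sqrt(rcut2_t.max() if rcut2_t.max() >
                                     dh_rcut2_t.max() else dh_rcut2_t.max()))
                  * 0.5) ** 2
    vol = Lx * Ly * Lz
    gfric = 1.0 / damping
    q_nh = dof * T_target * damping * damping
    # exact Ornstein-Uhlenbeck velocity update constants (Langevin O-step)
    lang_c1 = math.exp(-gfric * dt)
    lang_c2 = math.sqrt(T_target * (1.0 - lang_c1 * lang_c1))

    _wrap_positions(pos, img, Lx, Ly, Lz, tilt)
    if _build_nlist(pos, Lx, Ly, Lz, tilt, rlist * rlist, excl, nlist,
                    nshift, ncount) != 0:
        return 1, tilt, t, xi, 0, 0
    for i in range(n):
        for a in range(3):
            ref_pos[i, a] = pos[i, a]
    pe = _forces(pos, type_id, eps_t, sig2_t, lam_t, kind_t, rcut2_t,
                 dh_pref_t, dh_kappa, dh_rcut2_t, larks_id, strong,
                 strong_factor, bonds, bond_k, bond_r0,
                 Lx, Ly, Lz, tilt, nlist, nshift, ncount, forces, w)
    if not math.isfinite(pe):
        return 2, tilt, t, xi, 0, 0

    n_sampled = 0
    n_frames = 0
    for step in range(n_steps):
        # --- thermostat half (Nose-Hoover single chain) ---
        if thermo == 2:
            ke2 = 0.0
            for i in range(n):
                ke2 += mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                  + vel[i, 2] ** 2)
            xi += 0.5 * dt * (ke2 - dof * T_target) / q_nh
            s = math.exp(-0.5 * dt * xi)
            for i in range(n):
                vel[i, 0] *= s
                vel[i, 1] *= s
                vel[i, 2] *= s
        # --- half kick + drift ---
        for i in range(n):
            im = 0.5 * dt / mass[i]
            vel[i, 0] += im * forces[i, 0]
            vel[i, 1] += im * forces[i, 1]
            vel[i, 2] += im * forces[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        t += dt
        # --- oscillatory box shear: affine remap of coordinates ---
        if gamma0 != 0.0:
            new_tilt = gamma0 * Ly * math.sin(omega * (t - shear_t0))
            dgam = (new_tilt - tilt) / Ly
            for i in range(n):
                pos[i, 0] += dgam * pos[i, 1]
            tilt = new_tilt
        # --- neighbor list maintenance ---
        maxdisp2 = 0.0
        for i in range(n):
            d2 = ((pos[i, 0] - ref_pos[i, 0]) ** 2
                  + (pos[i, 1] - ref_pos[i, 1]) ** 2
                  + (pos[i, 2] - ref_pos[i, 2]) ** 2)
            if d2 > maxdisp2:
                maxdisp2 = d2
        if maxdisp2 > half_skin2:
            _wrap_positions(pos, img, Lx, Ly, Lz, tilt)
            if _build_nlist(pos, Lx, Ly, Lz, tilt, rlist * rlist, excl,
                            nlist, nshift, ncount) != 0:
                return 1, tilt, t, xi, n_sampled, n_frames
            for i in range(n):
                for a in range(3):
                    ref_pos[i, a] = pos[i, a]
        # --- new forces + second half kick ---
        pe = _forces(pos, type_id, eps_t, sig2_t, lam_t, kind_t, rcut2_t,
                     dh_pref_t, dh_kappa, dh_rcut2_t, larks_id, strong,
                     strong_factor, bonds, bond_k, bond_r0,
                     Lx, Ly, Lz, tilt, nlist, nshift, ncount, forces, w)
        if not math.isfinite(pe):
            return 2, tilt, t, xi, n_sampled, n_frames
        for i in range(n):
            im = 0.5 * dt / mass[i]
            vel[i, 0] += im * forces[i, 0]
            vel[i, 1] += im * forces[i, 1]
            vel[i, 2] += im * forces[i, 2]
        if thermo == 2:
            ke2 = 0.0
            for i in range(n):
                ke2 += mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                  + vel[i, 2] ** 2)
            xi += 0.5 * dt * (ke2 - dof * T_target) / q_nh
            s = math.exp(-0.5 * dt * xi)
            for i in range(n):
                vel[i, 0] *= s
                vel[i, 1] *= s
                vel[i, 2] *= s
        elif thermo == 1:
            # exact OU velocity refresh; masked-out particles (e.g. a probe
            # bead) feel only the conservative medium forces
            for i in range(n):
                if noise_mask[i] != 0:
                    cs = lang_c2 / math.sqrt(mass[i])
                    vel[i, 0] = lang_c1 * vel[i, 0] + cs * np.random.normal()
                    vel[i, 1] = lang_c1 * vel[i, 1] + cs * np.random.normal()
                    vel[i, 2] = lang_c1 * vel[i, 2] + cs * np.random.normal()
        # --- sampling ---
        if stress_stride > 0 and (step + 1) % stress_stride == 0:
            _kinetic_tensor(vel, mass, kin)
            ke = 0.0
            for a in range(3):
                ke += 0.5 * kin[a]
            for a in range(6):
                stress_out[n_sampled, a] = w[a] / vol
                stress_kin_out[n_sampled, a] = kin[a] / vol
            stress_t_out[n_sampled] = t
            pe_out[n_sampled] = pe
            ke_out[n_sampled] = ke
            n_sampled += 1
        if traj_stride > 0 and (step + 1) % traj_stride == 0:
            for k in range(traj_idx.shape[0]):
                i = traj_idx[k]
                traj_pos[n_frames, k, 0] = (pos[i, 0] + img[i, 0] * Lx
                                            + img[i, 1] * tilt)
                traj_pos[n_frames, k, 1] = pos[i, 1] + img[i, 1] * Ly
                traj_pos[n_frames, k, 2] = pos[i, 2] + img[i, 2] * Lz
            traj_t[n_frames] = t
            traj_tilt[n_frames] = tilt
            n_frames += 1
    return 0, tilt, t, xi, n_sampled, n_frames


# ---------------------------------------------------------------------------
# Public driver
# ---------------------------------------------------------------------------

def initialize_velocities(state: SimulationState, target_T: float,
                          masses: np.ndarray, rng: np.random.Generator) -> None:
    """Maxwell-Boltzmann velocities at ``target_T`` with zero total momentum."""
    v = rng.normal(size=state.positions.shape)
    v *= np.sqrt(target_T / masses)[:, None]
    v -= np.average(v, axis=0, weights=masses)
    ke2 = float(np.sum(masses[:, None] * v * v))
    dof = 3 * state.n - 3
    v *= math.sqrt(dof * target_T / ke2)
    state.velocities[:] = v


def apply_oscillatory_shear(state: SimulationState, gamma0: float,
                            omega: float, t: float) -> SimulationState:
    """Set the box tilt to ``gamma0 * Ly * sin(omega t)`` with affine remap.

    The strain gamma_xy(t) = Delta Lx / Ly follows a sinusoid; particle x
    coordinates are remapped affinely by the tilt increment so that the
    periodic images stay consistent (tilting-cell equivalent of Lees-Edwards
    boundaries).
    """
    if abs(gamma0) > 5.0:
        raise ValueError("strain amplitude beyond tilt re-wrapping support")
    new_tilt = gamma0 * state.box[1] * math.sin(omega * t)
    dgam = (new_tilt - state.tilt) / state.box[1]
    state.positions[:, 0] += dgam * state.positions[:, 1]
    state.tilt = new_tilt
    # keep |tilt| <= Lx/2 by re-wrapping whole box periods
    Lx = state.box[0]
    while state.tilt > 0.5 * Lx:
        state.tilt -= Lx
    while state.tilt < -0.5 * Lx:
        state.tilt += Lx
    return state


class Simulation:
    """Binds a state, a topology and interaction tables into a runnable system.

    Parameters
    ----------
    state
        Initial :class:`SimulationState`.
    pair_table
        Per-type nonbonded interactions.
    topology
        Optional bead-spring topology (bonds + exclusions).  ``type_ids``
        maps each bead onto a row of the pair table; by default all beads are
        type 0.
    """

    def __init__(
        self,
        state: SimulationState,
        pair_table: PairTable,
        topology: ChainTopology | None = None,
        type_ids: np.ndarray | None = None,
        masses: np.ndarray | None = None,
        config: IntegratorConfig | None = None,
        skin: float = DEFAULT_SKIN,
    ) -> None:
        self.state = state
        self.pair_table = pair_table
        self.topology = topology
        self.config = config or IntegratorConfig()
        n = state.n
        self.type_ids = (np.zeros(n, dtype=np.int64) if type_ids is None
                         else np.asarray(type_ids, dtype=np.int64))
        self.masses = (np.ones(n) if masses is None
                       else np.asarray(masses, dtype=np.float64))
        self.skin = skin
        self._rng = np.random.default_rng(state.seed)
        self.nh_xi = 0.0

        if topology is not None:
            self.bonds = np.asarray(topology.bond_pairs, dtype=np.int64
                                    ).reshape(-1, 2)
            k = topology.bond_spec.k_bond
            r0 = topology.bond_spec.r0
            self.bond_k = np.full(len(self.bonds), float(k))
            self.bond_r0 = np.full(len(self.bonds), float(r0))
            w_bond = math.sqrt(2.0 * k / self.masses.min())
            if self.config.dt * w_bond > 0.1:
                import warnings
                warnings.warn(
                    f"dt*sqrt(2K/m) = {self.config.dt * w_bond:.3f} > 0.1: "
                    "timestep too large for the bond stiffness", stacklevel=2)
        else:
            self.bonds = np.zeros((0, 2), dtype=np.int64)
            self.bond_k = np.zeros(0)
            self.bond_r0 = np.zeros(0)
        self.excl = _exclusion_array(n, self.bonds)

        # aging hooks (identity defaults: no strengthening)
        self.larks_id = np.full(n, -1, dtype=np.int64)
        self.strong = np.zeros((1, 1), dtype=np.uint8)
        self.strong_factor = 1.0

        self._nlist_cap = 160
        self._alloc_nlist()

    # -- plumbing -----------------------------------------------------------

    def _alloc_nlist(self) -> None:
        n = self.state.n
        self.nlist = np.zeros((n, self._nlist_cap), dtype=np.int32)
        self.nshift = np.zeros((n, self._nlist_cap, 3), dtype=np.int8)
        self.ncount = np.zeros(n, dtype=np.int64)
        self.ref_pos = np.zeros((n, 3))

    @property
    def rlist(self) -> float:
        return self.pair_table.max_cutoff() + self.skin

    def _table_args(self):
        t = self.pair_table
        return (t.eps, t.sigma**2, t.lam, t.kind, t.rcut**2,
                t.dh_pref, t.dh_kappa, t.dh_rcut**2)

    def set_aging_tables(self, larks_id: np.ndarray, strong: np.ndarray,
                         factor: float) -> None:
        """Install per-bead LARKS ids and the strengthened-pair matrix."""
        self.larks_id = np.asarray(larks_id, dtype=np.int64)
        self.strong = np.asarray(strong, dtype=np.uint8)
        self.strong_factor = float(factor)

    # -- observables --------------------------------------------------------

    def compute_forces_and_stress(
        self, all_pairs: bool = False
    ) -> tuple[np.ndarray, StressTensorSample]:
        """Current forces and the instantaneous virial+kinetic stress tensor.

        ``all_pairs=True`` bypasses the neighbor list (brute-force reference,
        exact for validation on small systems).
        """
        st = self.state
        n = st.n
        st.wrap()
        rlist = 2.0 * float(np.max(st.box)) if all_pairs else self.rlist
        if _build_nlist(st.positions, st.box[0], st.box[1], st.box[2],
                        st.tilt, rlist * rlist, self.excl, self.nlist,
                        self.nshift, self.ncount) != 0:
            if all_pairs:
                self._nlist_cap = n + 1
                self._alloc_nlist()
                _build_nlist(st.positions, st.box[0], st.box[1], st.box[2],
                             st.tilt, rlist * rlist, self.excl, self.nlist,
                             self.nshift, self.ncount)
            else:
                raise RuntimeError("neighbor list overflow")
        forces = np.zeros((n, 3))
        w = np.zeros(6)
        pe = _forces(st.positions, self.type_ids, *self._table_args(),
                     self.larks_id, self.strong, self.strong_factor,
                     self.bonds, self.bond_k, self.bond_r0,
                     st.box[0], st.box[1], st.box[2], st.tilt,
                     self.nlist, self.nshift, self.ncount, forces, w)
        if not math.isfinite(pe):
            pair = self._find_overlap()
            raise FloatingPointError(
                f"non-finite forces (overlapping pair {pair})")
        kin = np.zeros(6)
        _kinetic_tensor(st.velocities, self.masses, kin)
        vol = st.volume
        self.potential_energy = pe
        return forces, StressTensorSample(time=st.time, virial=w / vol,
                                          kinetic=kin / vol)

    def _find_overlap(self) -> tuple[int, int]:
        st = self.state
        d = st.positions[:, None, :] - st.positions[None, :, :]
        for a, L in enumerate(st.box):
            d[..., a] -= np.rint(d[..., a] / L) * L
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        i, j = np.unravel_index(np.argmin(r), r.shape)
        return int(i), int(j)

    def kinetic_temperature(self) -> float:
        ke2 = float(np.sum(self.masses[:, None] * self.state.velocities**2))
        return ke2 / (3 * self.state.n - 3)

    # -- dynamics -----------------------------------------------------------

    def step(self) -> SimulationState:
        """Advance a single velocity-Verlet step (convenience wrapper)."""
        self.run(1, stress_stride=0)
        return self.state

    def run(
        self,
        n_steps: int,
        stress_stride: int | None = None,
        traj_stride: int = 0,
        track_indices: np.ndarray | None = None,
        gamma0: float = 0.0,
        omega: float = 0.0,
        shear_t0: float | None = None,
    ) -> tuple[StressLog, Trajectory | None]:
        """Run ``n_steps`` of dynamics, streaming stress samples and frames.

        Reproducible given the state seed: every call draws its kernel seed
        from the state's generator, so identical initial states produce
        bit-identical logs.
        """
        cfg = self.config
        st = self.state
        stride = cfg.stress_stride if stress_stride is None else stress_stride
        n_samp = n_steps // stride if stride > 0 else 0
        n_frames = n_steps // traj_stride if traj_stride > 0 else 0
        stress = np.zeros((n_samp, 6))
        stress_kin = np.zeros((n_samp, 6))
        stress_t = np.zeros(n_samp)
        pe_out = np.zeros(n_samp)
        ke_out = np.zeros(n_samp)
        if track_indices is None:
            track_indices = np.arange(st.n, dtype=np.int64)
        else:
            track_indices = np.asarray(track_indices, dtype=np.int64)
        traj_pos = np.zeros((n_frames, len(track_indices), 3))
        traj_t = np.zeros(n_frames)
        traj_tilt = np.zeros(n_frames)
        dof = 3 * st.n - 3
        noise_mask = getattr(self, "noise_mask", None)
        if noise_mask is None:
            noise_mask = np.ones(st.n, dtype=np.int64)
        kseed = int(self._rng.integers(2**31 - 1))
        if shear_t0 is None:
            shear_t0 = st.time if gamma0 != 0.0 else 0.0

        for attempt in range(3):
            status, tilt, t, xi, ns, nf = _run_md(
                st.positions, st.images, st.velocities, self.masses,
                self.type_ids, *self._table_args(),
                self.larks_id, self.strong, self.strong_factor,
                self.bonds, self.bond_k, self.bond_r0, self.excl,
                st.box[0], st.box[1], st.box[2], st.tilt, st.time,
                cfg.dt, n_steps, _THERMO_CODES[cfg.thermostat], cfg.target_T,
                cfg.damping, self.nh_xi, dof, noise_mask, kseed,
                gamma0, omega, shear_t0,
                stride, stress, stress_kin, stress_t, pe_out, ke_out,
                traj_stride, track_indices, traj_pos, traj_t, traj_tilt,
                self.rlist, self.nlist, self.nshift, self.ncount, self.ref_pos)
            if status != 1:
                break
            self._nlist_cap *= 2
            self._alloc_nlist()
        if status == 1:
            raise RuntimeError("neighbor list overflow (cap exhausted)")
        if status == 2:
            raise FloatingPointError(
                f"non-finite forces at step {ns * stride if stride else 0} "
                f"(t = {t:.4g})")
        st.tilt = tilt
        st.time = t
        self.nh_xi = xi
        self.last_pe = pe_out
        self.last_ke = ke_out
        log = StressLog(times=stress_t, components=stress + stress_kin,
                        volume=st.volume, temperature=cfg.target_T)
        log.virial = stress
        log.kinetic = stress_kin
        traj = None
        if traj_stride > 0:
            traj = Trajectory(times=traj_t, positions=traj_pos,
                              box=st.box.copy(), tilts=traj_tilt,
                              indices=track_indices)
        return log, traj

    # -- checkpointing ------------------------------------------------------

    def save_checkpoint(self, path) -> None:
        st = self.state
        bg = self._rng.bit_generator.state
        np.savez(path, schema=np.int64(1),
                 positions=st.positions, velocities=st.velocities,
                 images=st.images, box=st.box, tilt=st.tilt, time=st.time,
                 seed=st.seed, nh_xi=self.nh_xi,
                 rng_state=np.array([bg["state"]["state"],
                                     bg["state"]["inc"],
                                     int(bg["has_uint32"]),
                                     int(bg["uinteger"])], dtype=object))

    def load_checkpoint(self, path) -> None:
        d = np.load(path, allow_pickle=True)
        if int(d["schema"]) != 1:
            raise ValueError("unknown checkpoint schema version")
        st = self.state
        st.positions[:] = d["positions"]
        st.velocities[:] = d["velocities"]
        st.images[:] = d["images"]
        st.box[:] = d["box"]
        st.tilt = float(d["tilt"])
        st.time = float(d["time"])
        self.nh_xi = float(d["nh_xi"])
        bg = self._rng.bit_generator.state
        bg["state"]["state"] = int(d["rng_state"][0])
        bg["state"]["inc"] = int(d["rng_state"][1])
        bg["has_uint32"] = int(d["rng_state"][2])
        bg["uinteger"] = int(d["rng_state"][3])
        self._rng.bit_generator.state = bg


def _exclusion_array(n: int, bonds: np.ndarray) -> np.ndarray:
    excl = np.full((n, 2), -1, dtype=np.int64)
    slot = np.zeros(n, dtype=np.int64)
    for i, j in bonds:
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        if slot[a] >= 2:
            raise ValueError("more than two bonds per bead unsupported")
        excl[a, slot[a]] = b
        slot[a] += 1
    return excl
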