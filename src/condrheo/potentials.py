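"""Interaction potentials for coarse-grained condensate models.

All functional forms used by the simulation engine live here, together with
their analytic radial forces (``f = -dU/dr``).  Three nonbonded families are
supported:

* a truncated Lennard-Jones potential (the generic one-bead-per-residue-group
  IDP model),
* the Ashbaugh-Hatch potential, an LJ variant whose attractive tail is scaled
  by ``lambda in [0, 1]`` (``lambda = 0`` is a purely repulsive WCA sphere,
  ``lambda = 1`` the full LJ), used for probe beads and for hydropathy-scaled
  residue-residue interactions,
* a Yukawa/Debye-Hueckel screened electrostatic potential.

Bonded beads interact through a stiff harmonic spring ``U = K (r - r0)^2``
(no 1/2 prefactor; the stiff spring makes observables insensitive to the
convention, which is exposed as the single constant :data:`BOND_HALF_PREFACTOR`).

Everything is expressed in reduced Lennard-Jones units unless a
:class:`ResidueParameterTable` supplies physical per-residue values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReducedUnits",
    "PairPotentialSpec",
    "BondSpec",
    "ChainTopology",
    "ResidueParameterTable",
    "lj_energy_force",
    "bond_energy_force",
    "ashbaugh_hatch_energy_force",
    "debye_huckel_energy_force",
    "sticker_count",
    "linear_chain_topology",
]

# Bond convention switch: False -> U = K (r-r0)^2 ; True -> U = (K/2)(r-r0)^2.
BOND_HALF_PREFACTOR = False

# Kind codes shared with the numba engine kernels.
KIND_LJ = 0
KIND_ASHBAUGH_HATCH = 1
KIND_DEBYE_HUCKEL = 2

_KIND_NAMES = {
    "lj_truncated": KIND_LJ,
    "ashbaugh_hatch": KIND_ASHBAUGH_HATCH,
    "debye_huckel": KIND_DEBYE_HUCKEL,
}

STICKERS = frozenset("YFR")
AROMATIC_STICKERS = frozenset("YF")
_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ReducedUnits:
    """Reduced Lennard-Jones unit system.

    Temperature is ``T* = kB T / epsilon``, density ``rho* = (N/V) sigma^3``,
    pressure ``p* = p sigma^3 / epsilon`` and time ``tau = sigma sqrt(m/epsilon)``.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0 or self.mass <= 0:
            raise ValueError("all base units must be strictly positive")

    @property
    def tau(self) -> float:
        return self.sigma * math.sqrt(self.mass / self.epsilon)


@dataclass
class PairPotentialSpec:
    """Parameters of one nonbonded pair interaction."""

    kind: str = "lj_truncated"
    epsilon: float = 1.0
    sigma: float = 1.0
    lambda_scale: float = 1.0
    cutoff: float = 3.0
    screening_length: float = 1.0
    charge_product: float = 0.0
    #: Coulomb prefactor 1/(4 pi eps0 eps_r) in the working unit system.
    coulomb_prefactor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_NAMES:
            raise ValueError(f"unknown pair potential kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0.0 <= self.lambda_scale <= 1.0:
            raise ValueError("lambda_scale must lie in [0, 1]")
        if self.kind == "debye_huckel" and self.screening_length <= 0:
            raise ValueError("screening_length must be positive for debye_huckel")

    @property
    def kind_code(self) -> int:
        return _KIND_NAMES[self.kind]

    def energy_force(self, r: float) -> tuple[float, float]:
        """Dispatch to the matching energy/force function."""
        if self.kind == "lj_truncated":
            return lj_energy_force(r, self)
        if self.kind == "ashbaugh_hatch":
            return ashbaugh_hatch_energy_force(r, self)
        return debye_huckel_energy_force(r, self)


@dataclass(frozen=True)
class BondSpec:
    """Stiff harmonic bond ``U = K (r - r0)^2`` joining consecutive beads."""

    k_bond: float = 7.5e4
    r0: float = 1.0

    def __post_init__(self) -> None:
        if self.k_bond <= 0:
            raise ValueError("k_bond must be positive")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


def _check_r(r: float) -> None:
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")


def _lj_uf(r: float, epsilon: float, sigma: float) -> tuple[float, float]:
    sr6 = (sigma / r) ** 6
    sr12 = sr6 * sr6
    u = 4.0 * epsilon * (sr12 - sr6)
    f = 24.0 * epsilon * (2.0 * sr12 - sr6) / r
    return u, f


def lj_energy_force(r: float, spec: PairPotentialSpec) -> tuple[float, float]:
    """Truncated Lennard-Jones ``U = 4 eps [(s/r)^12 - (s/r)^6]``.

    Both energy and force are truncated to exactly zero at ``r >= cutoff``
    (no energy shift: the force is what drives the dynamics, the energy is a
    diagnostic).  The returned force is the radial force ``-dU/dr``.
    """
    _check_r(r)
    if r >= spec.cutoff:
        return 0.0, 0.0
    return _lj_uf(r, spec.epsilon, spec.sigma)


def bond_energy_force(r: float, spec: BondSpec) -> tuple[float, float]:
    """Harmonic bond energy and radial force under the adopted convention."""
    _check_r(r)
    pref = 0.5 * spec.k_bond if BOND_HALF_PREFACTOR else spec.k_bond
    dr = r - spec.r0
    return pref * dr * dr, -2.0 * pref * dr


def ashbaugh_hatch_energy_force(
    r: float, spec: PairPotentialSpec
) -> tuple[float, float]:
    """Ashbaugh-Hatch potential: LJ with a lambda-scaled attractive tail.

    ``U = U_LJ + (1 - lambda) eps`` for ``r <= 2^(1/6) sigma`` and
    ``U = lambda U_LJ`` beyond, continuous at the split, zero past the cutoff.
    """
    _check_r(r)
    lam = spec.lambda_scale
    if r >= spec.cutoff:
        return 0.0, 0.0
    u_lj, f_lj = _lj_uf(r, spec.epsilon, spec.sigma)
    r_min = 2.0 ** (1.0 / 6.0) * spec.sigma
    if r <= r_min:
        return u_lj + (1.0 - lam) * spec.epsilon, f_lj
    return lam * u_lj, lam * f_lj


def debye_huckel_energy_force(
    r: float, spec: PairPotentialSpec
) -> tuple[float, float]:
    """Yukawa/Debye-Hueckel screened Coulomb interaction.

    ``U = C q1 q2 exp(-r/lambda_D) / r`` with ``C`` the Coulomb prefactor in
    the working unit system, truncated at the cutoff.
    """
    _check_r(r)
    if spec.screening_length <= 0:
        raise ValueError("screening_length must be positive")
    if r >= spec.cutoff:
        return 0.0, 0.0
    pref = spec.coulomb_prefactor * spec.charge_product
    e = math.exp(-r / spec.screening_length)
    u = pref * e / r
    # -dU/dr = pref * e * (1/r^2 + 1/(lambda r))
    f = pref * e * (1.0 / r**2 + 1.0 / (spec.screening_length * r))
    return u, f


def sticker_count(sequence: str, aromatics_only: bool = False) -> int:
    """Count sticker residues in a one-letter amino-acid sequence.

    Tyrosine (Y) and phenylalanine (F) are main stickers and arginine (R) a
    context-dependent sticker; ``aromatics_only`` restricts the count to Y+F.
    Unknown residue codes trigger a warning and count as spacers.
    """
    stickers = AROMATIC_STICKERS if aromatics_only else STICKERS
    n = 0
    unknown: set[str] = set()
    for aa in sequence.upper():
        if aa in stickers:
            n += 1
        elif aa not in _AMINO_ACIDS:
            unknown.add(aa)
    if unknown:
        warnings.warn(
            f"unknown residue codes {sorted(unknown)} counted as spacers",
            stacklevel=2,
        )
    return n


@dataclass
class ChainTopology:
    """Bead-spring topology of a multichain system.

    Bonds join consecutive beads within one chain; every bonded pair is also
    a nonbonded exclusion (directly connected beads do not interact through
    the pair potential).
    """

    n_chains: int
    beads_per_chain: int
    bond_pairs: list[tuple[int, int]] = field(default_factory=list)
    type_labels: list[str] = field(default_factory=list)
    bond_spec: BondSpec = field(default_factory=BondSpec)

    def __post_init__(self) -> None:
        n = self.n_beads
        if not self.type_labels:
            self.type_labels = ["A"] * n
        if len(self.type_labels) != n:
            raise ValueError("type_labels length must equal bead count")
        for i, j in self.bond_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range")
            if i // self.beads_per_chain != j // self.beads_per_chain:
                raise ValueError(f"bond ({i},{j}) crosses chains")
            if abs(i - j) != 1:
                raise ValueError(f"bond ({i},{j}) is not between consecutive beads")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    @property
    def nonbonded_exclusions(self) -> set[frozenset[int]]:
        return {frozenset(p) for p in self.bond_pairs}

    def chain_of(self, bead: int) -> int:
        return bead // self.beads_per_chain


def linear_chain_topology(
    n_chains: int,
    beads_per_chain: int,
    bond_spec: BondSpec | None = None,
    type_labels_per_chain: Sequence[str] | None = None,
) -> ChainTopology:
    """Build the standard linear homopolymer topology (consecutive-bead bonds)."""
    bonds = []
    for c in range(n_chains):
        off = c * beads_per_chain
        bonds.extend((off + i, off + i + 1) for i in range(beads_per_chain - 1))
    labels: list[str] = []
    if type_labels_per_chain is not None:
        if len(type_labels_per_chain) != beads_per_chain:
            raise ValueError("type_labels_per_chain length must equal beads_per_chain")
        labels = list(type_labels_per_chain) * n_chains
    return ChainTopology(
        n_chains=n_chains,
        beads_per_chain=beads_per_chain,
        bond_pairs=bonds,
        type_labels=labels,
        bond_spec=bond_spec or BondSpec(),
    )


class ResidueParameterTable:
    """Per-residue parameters of a sequence-dependent coarse-grained model.

    Holds one row per residue/nucleotide code with its molecular diameter,
    hydropathy scale ``lambda``, charge and mass, plus the global combination
    rule, Debye screening length and dielectric constant.  The packaged
    defaults are a documented toy table for tests; real work reads a
    user-supplied CSV/TSV (columns ``code, diameter, lambda, charge, mass``).
    """

    COLUMNS = ("code", "diameter", "lambda", "charge", "mass")

    def __init__(
        self,
        table: pd.DataFrame,
        combination_rule: str = "lorentz_berthelot",
        screening_length: float = 1.0,
        dielectric_constant: float = 80.0,
        epsilon: float = 0.2,
    ) -> None:
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"parameter table missing columns {missing}")
        if combination_rule not in ("lorentz_berthelot", "geometric"):
            raise ValueError(f"unknown combination rule {combination_rule!r}")
        self.table = table.set_index("code") if table.index.name != "code" else table
        self.combination_rule = combination_rule
        self.screening_length = screening_length
        self.dielectric_constant = dielectric_constant
        self.epsilon = epsilon

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ResidueParameterTable":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df, **kwargs)

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    def validate_sequence(self, sequence: Iterable[str]) -> None:
        missing = sorted({c for c in sequence if c not in self.table.index})
        if missing:
            raise KeyError(f"residue codes {missing} absent from parameter table")

    def pair_parameters(self, code_a: str, code_b: str) -> PairPotentialSpec:
        """Cross-interaction spec for two residue codes (symmetric)."""
        a, b = self.table.loc[code_a], self.table.loc[code_b]
        sigma = 0.5 * (a["diameter"] + b["diameter"])
        if self.combination_rule == "geometric":
            lam = math.sqrt(a["lambda"] * b["lambda"])
        else:
            lam = 0.5 * (a["lambda"] + b["lambda"])
        return PairPotentialSpec(
            kind="ashbaugh_hatch",
            epsilon=self.epsilon,
            sigma=sigma,
            lambda_scale=float(lam),
            cutoff=3.0 * sigma,
        )

    def electrostatic_parameters(self, code_a: str, code_b: str) -> PairPotentialSpec:
        a, b = self.table.loc[code_a], self.table.loc[code_b]
        return PairPotentialSpec(
            kind="debye_huckel",
            charge_product=float(a["charge"] * b["charge"]),
            screening_length=self.screening_length,
            coulomb_prefactor=1.0 / self.dielectric_constant,
            cutoff=4.0 * self.screening_length,
        )


def toy_residue_table() -> ResidueParameterTable:
    """Small synthetic parameter table for tests (non-physical values)."""
    rows = []
    for code in sorted(_AMINO_ACIDS) + ["U"]:
        lam = 0.9 if code in STICKERS else 0.4
        charge = {"R": 1.0, "K": 1.0, "D": -1.0, "E": -1.0, "U": -1.0}.get(code, 0.0)
        rows.append({"code": code, "diameter": 1.0, "lambda": lam,
                     "charge": charge, "mass": 1.0})
    return ResidueParameterTable(pd.DataFrame(rows))
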