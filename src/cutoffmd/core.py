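"""Domain types, units and periodic geometry.

Everything downstream (force evaluation, integration, analysis) works on the
:class:`ParticleSystem` container defined here: a set of point particles with
charges, Lennard-Jones parameters and masses inside a cubic periodic box.

Unit system
-----------
Lengths in angstrom (A), time in femtoseconds (fs), masses in atomic mass
units (amu), energies in kcal/mol, charges in units of the elementary charge.
In these units 1 amu*A^2/fs^2 = 2390.0574 kcal/mol; the constant
:data:`KCAL_PER_AMU_A2_FS2` converts kinetic energy and forces between the
mechanical and thermochemical scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

#: Boltzmann constant, kcal mol^-1 K^-1.
K_B = 0.0019872041

#: Coulomb constant k_e, kcal A mol^-1 e^-2 (standard MD convention).
K_E = 332.0636

#: kcal/mol per amu A^2 fs^-2 (kinetic-energy / force unit conversion).
KCAL_PER_AMU_A2_FS2 = 2390.0574


class Electrostatics(str, Enum):
    """Electrostatics treatment: hard truncation, force shifting, or Ewald."""

    TRUNC = "trunc"
    SHIFT = "shift"
    EWALD = "ewald"


@dataclass(frozen=True)
class Bond:
    """Harmonic bond i-j with equilibrium length (A) and spring constant
    k (kcal mol^-1 A^-2); energy is k/2 (r - r0)^2."""

    i: int
    j: int
    length: float
    k: float = 300.0

    def pair(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


def _as_bond(b) -> Bond:
    if isinstance(b, Bond):
        return b
    return Bond(*b)


def _per_particle(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass
class ParticleSystem:
    """Point particles in a cubic periodic box.

    Positions live in Cartesian A with the box spanning [0, box_edge) from the
    origin corner; coordinates may drift outside the box during dynamics and
    are wrapped only inside distance computations, never destructively, so
    trajectories stay continuous for analysis.

    Parameters
    ----------
    positions : (n, 3) array
    box_edge : float
        Edge length of the cubic periodic box (A).
    charges, lj_sigma, lj_epsilon, masses : (n,) arrays or scalars
        Per-particle charge (e), LJ sigma (A), LJ epsilon (kcal/mol), mass
        (amu). Scalars broadcast.
    velocities : (n, 3) array, optional
        A/fs; defaults to zero.
    bonds : sequence of Bond or (i, j, length[, k]) tuples
    constrained_bonds : subset of bonds held rigid by SHAKE
    exclusions : iterable of (i, j) pairs excluded from nonbonded interactions
    labels : per-particle names
    residue_index : per-particle residue assignment for chain systems
    """

    positions: np.ndarray
    box_edge: float
    charges: np.ndarray = 0.0
    lj_sigma: np.ndarray = 0.0
    lj_epsilon: np.ndarray = 0.0
    masses: np.ndarray = 1.0
    velocities: np.ndarray | None = None
    bonds: list[Bond] = field(default_factory=list)
    constrained_bonds: list[Bond] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    labels: list[str] | None = None
    residue_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = self.positions.shape[0]
        if n < 1 or self.positions.shape != (n, 3):
            raise ValueError("positions must be an (n, 3) array with n >= 1")
        if not self.box_edge > 0:
            raise ValueError("box_edge must be positive")
        self.charges = _per_particle(self.charges, n, "charges")
        self.lj_sigma = _per_particle(self.lj_sigma, n, "lj_sigma")
        self.lj_epsilon = _per_particle(self.lj_epsilon, n, "lj_epsilon")
        self.masses = _per_particle(self.masses, n, "masses")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if np.any(self.lj_sigma < 0) or np.any(self.lj_epsilon < 0):
            raise ValueError("LJ parameters must be non-negative")
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (n, 3):
                raise ValueError("velocities must match positions shape")
        self.bonds = [_as_bond(b) for b in self.bonds]
        self.constrained_bonds = [_as_bond(b) for b in self.constrained_bonds]
        for b in self.bonds + self.constrained_bonds:
            if not (0 <= b.i < n and 0 <= b.j < n and b.i != b.j):
                raise ValueError(f"bond {b} references invalid particles")
        excl = set()
        for i, j in self.exclusions:
            if i == j:
                raise ValueError(f"exclusion ({i},{i}) is a self-pair")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"exclusion ({i},{j}) out of range")
            excl.add((min(i, j), max(i, j)))
        self.exclusions = excl
        if self.residue_index is not None:
            self.residue_index = np.asarray(self.residue_index, dtype=int)
        self._excl_mask: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def exclusion_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix, True where the pair is excluded."""
        if self._excl_mask is None:
            n = self.n_particles
            m = np.zeros((n, n), dtype=bool)
            for i, j in self.exclusions:
                m[i, j] = m[j, i] = True
            self._excl_mask = m
        return self._excl_mask

    def copy(self) -> "ParticleSystem":
        new = ParticleSystem(
            positions=self.positions.copy(),
            box_edge=self.box_edge,
            charges=self.charges.copy(),
            lj_sigma=self.lj_sigma.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            masses=self.masses.copy(),
            velocities=self.velocities.copy(),
            bonds=list(self.bonds),
            constrained_bonds=list(self.constrained_bonds),
            exclusions=set(self.exclusions),
            labels=list(self.labels) if self.labels is not None else None,
            residue_index=(
                self.residue_index.copy() if self.residue_index is not None else None
            ),
        )
        return new


@dataclass(frozen=True)
class NonbondedScheme:
    """Which electrostatics treatment to use, and its parameters.

    cutoff applies to both the electrostatics (TRUNC/SHIFT, and the Ewald
    real-space sum) and the truncated Lennard-Jones term. ewald_alpha (A^-1)
    and ewald_kmax (reciprocal-space integer cutoff: all wave-vectors
    k = 2*pi*n/L with each |n_i| <= kmax) are used only by EWALD.
    """

    electrostatics: Electrostatics
    cutoff: float
    ewald_alpha: float | None = None
    ewald_kmax: int | None = None
    coulomb_constant: float = K_E

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "electrostatics", Electrostatics(self.electrostatics)
        )
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.electrostatics is Electrostatics.EWALD:
            if self.ewald_alpha is None or self.ewald_kmax is None:
                raise ValueError("EWALD requires ewald_alpha and ewald_kmax")
            if not self.ewald_alpha > 0 or self.ewald_kmax < 1:
                raise ValueError("need ewald_alpha > 0 and ewald_kmax >= 1")


@dataclass
class ForceReport:
    """Forces (kcal mol^-1 A^-1), total potential energy (kcal/mol) and a
    per-term energy breakdown. The total must equal the component sum."""

    forces: np.ndarray
    potential_energy: float
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.components:
            total = sum(self.components.values())
            scale = max(1.0, abs(self.potential_energy))
            if abs(total - self.potential_energy) > 1e-8 * scale:
                raise ValueError(
                    "potential_energy does not equal the component sum: "
                    f"{self.potential_energy} vs {total}"
                )

    def __add__(self, other: "ForceReport") -> "ForceReport":
        comps = dict(self.components)
        for k, v in other.components.items():
            comps[k] = comps.get(k, 0.0) + v
        return ForceReport(
            forces=self.forces + other.forces,
            potential_energy=self.potential_energy + other.potential_energy,
            components=comps,
        )


def minimum_image(displacement: np.ndarray, box_edge: float) -> np.ndarray:
    """Map a displacement (or array of displacements) to the nearest periodic
    image; each component of the result lies in [-box_edge/2, box_edge/2)."""
    if not box_edge > 0:
        raise ValueError("box_edge must be positive")
    d = np.asarray(displacement, dtype=float)
    return d - box_edge * np.floor(d / box_edge + 0.5)


def pair_table(
    system: ParticleSystem, cutoff: float, include_excluded: bool = False
):
    """Vectorized i<j pair enumeration within the cutoff.

    Returns (i, j, dvec, r): index arrays, minimum-image displacement vectors
    positions[i]-positions[j], and distances. Internal workhorse behind
    :func:`neighbor_pairs` and the force kernels.
    """
    if cutoff >= system.box_edge / 2:
        raise ValueError(
            f"cutoff {cutoff} violates minimum image (box {system.box_edge})"
        )
    n = system.n_particles
    iu, ju = np.triu_indices(n, k=1)
    d = minimum_image(system.positions[iu] - system.positions[ju], system.box_edge)
    r = np.linalg.norm(d, axis=1)
    keep = r <= cutoff
    if not include_excluded and system.exclusions:
        keep &= ~system.exclusion_mask()[iu, ju]
    return iu[keep], ju[keep], d[keep], r[keep]


def excluded_pair_table(system: ParticleSystem):
    """(i, j, dvec, r) over the excluded pairs (any distance, minimum image)."""
    if not system.exclusions:
        e = np.empty(0, dtype=int)
        return e, e, np.empty((0, 3)), np.empty(0)
    ij = np.array(sorted(system.exclusions), dtype=int)
    d = minimum_image(
        system.positions[ij[:, 0]] - system.positions[ij[:, 1]], system.box_edge
    )
    return ij[:, 0], ij[:, 1], d, np.linalg.norm(d, axis=1)


def neighbor_pairs(
    system: ParticleSystem, cutoff: float
) -> list[tuple[int, int, float]]:
    """All non-excluded pairs with minimum-image distance <= cutoff, each once
    with i < j. Raises if cutoff >= box_edge/2 (minimum-image violation)."""
    i, j, _, r = pair_table(system, cutoff)
    return [(int(a), int(b), float(d)) for a, b, d in zip(i, j, r)]


def kinetic_energy(system: ParticleSystem) -> float:
    """Kinetic energy in kcal/mol."""
    v2 = np.einsum("ij,ij->i", system.velocities, system.velocities)
    return 0.5 * float(np.dot(system.masses, v2)) * KCAL_PER_AMU_A2_FS2


def degrees_of_freedom(system: ParticleSystem) -> int:
    """3N minus the number of rigid bond constraints minus 3 (COM momentum)."""
    return 3 * system.n_particles - len(system.constrained_bonds) - 3


def instantaneous_temperature(system: ParticleSystem) -> float:
    """Kinetic temperature 2*KE / (N_df * k_B), in K."""
    ndf = degrees_of_freedom(system)
    if ndf <= 0:
        return 0.0
    return 2.0 * kinetic_energy(system) / (ndf * K_B)
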