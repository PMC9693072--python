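"""Interaction energies: discrete atom-atom sums and continuum plane integrals.

Two evaluation routes coexist.  Between two molecules the energy is the
exact discrete double sum

    E = sum_i sum_j ( -A_ij/rho_ij^6 + B_ij/rho_ij^12 ),

with no cutoff (69 x 69 = 4761 terms for two default drugs).  Between a
molecule and the graphene sheet the sheet is smeared into an infinite plane
of areal density ``eta`` and the potential is integrated analytically:

    I_n = integral over the plane of rho^(-2n) dS = pi / ((n-1) delta^(2n-2))

for an atom a height ``delta`` above the plane, giving the point-plane energy

    Ep(delta) = eta * pi * ( -A/(2 delta^4) + B/(5 delta^10) )

and a molecule-plane energy that is the sum of Ep over the molecule's atoms
(69 terms for the default drug).  The composite two-drugs-on-graphene system
adds the discrete drug-drug sum to the two continuum drug-plane terms.

Every evaluator accepts ``mode="strict"`` (raise on sub-guard distances) or
``mode="penalized"`` (return a large finite penalty), the latter keeping the
GA objective finite near overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    DISTANCE_GUARD,
    PENALTY_ENERGY,
    ForceFieldTable,
    GuardError,
    InvalidParameterError,
    PairParams,
    default_forcefield,
)
from .structures import Pose, RigidMolecule, apply_pose, center_of_mass, rotation_matrix

__all__ = [
    "GRAPHENE_SURFACE_DENSITY",
    "InfinitePlane",
    "SystemSpec",
    "point_plane_integral",
    "point_plane_energy",
    "molecule_plane_energy",
    "molecule_pair_energy",
    "system_energy",
    "system_energy_from_molecules",
    "EnergyModel",
]

#: Mean areal density of carbon atoms on graphene (atoms/Angstrom^2).
GRAPHENE_SURFACE_DENSITY = 0.3812


@dataclass(frozen=True)
class InfinitePlane:
    """Infinite flat graphene sheet on the xy-plane at ``z_offset``."""

    z_offset: float = 0.0
    eta: float = GRAPHENE_SURFACE_DENSITY
    element: str = "C"

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise InvalidParameterError(f"surface density must be positive: {self.eta}")


@dataclass(frozen=True)
class SystemSpec:
    """One or two rigid molecules plus an optional continuum plane.

    The three study systems: (i) two molecules, no plane; (ii) one molecule
    + plane; (iii) two molecules + plane.  At least one interaction must be
    present.
    """

    molecules: tuple[RigidMolecule, ...]
    plane: InfinitePlane | None = None
    forcefield: ForceFieldTable = field(default_factory=default_forcefield)

    def __post_init__(self) -> None:
        mols = tuple(self.molecules)
        object.__setattr__(self, "molecules", mols)
        if not 1 <= len(mols) <= 2:
            raise InvalidParameterError("a system holds 1 or 2 molecules")
        if len(mols) == 1 and self.plane is None:
            raise InvalidParameterError(
                "a single molecule without a plane has no interaction"
            )

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


def point_plane_integral(delta: float, n: int) -> float:
    """Surface integral I_n of rho^(-2n) over an infinite plane.

    ``delta`` is the perpendicular distance of the point to the plane.
    Closed form: pi / ((n-1) * delta^(2n-2)); units Angstrom^(2-2n).
    """
    if not delta > 0:
        raise InvalidParameterError(f"delta must be positive, got {delta!r}")
    if n < 2:
        raise InvalidParameterError("integral diverges for n < 2")
    return math.pi / ((n - 1) * delta ** (2 * n - 2))


def point_plane_energy(
    delta: float,
    pair: PairParams,
    eta: float = GRAPHENE_SURFACE_DENSITY,
    mode: str = "strict",
    guard: float = DISTANCE_GUARD,
) -> float:
    """Continuum energy of one atom a height ``delta`` above the plane.

    Ep = eta * pi * (-A/(2 delta^4) + B/(5 delta^10)); its minimum sits at
    delta* = (B/A)^(1/6).
    """
    if delta <= guard:
        if mode == "penalized":
            return PENALTY_ENERGY
        raise GuardError(f"plane distance {delta!r} <= guard {guard!r}")
    d4 = delta**4
    return eta * math.pi * (-pair.A / (2.0 * d4) + pair.B / (5.0 * d4 * d4 * delta**2))


def _plane_constants(
    ff: ForceFieldTable, elements: tuple[str, ...], plane_element: str
) -> tuple[np.ndarray, np.ndarray]:
    pairs = [ff.pair(el, plane_element) for el in elements]
    return np.array([p.A for p in pairs]), np.array([p.B for p in pairs])


def _pair_constant_matrices(
    ff: ForceFieldTable, els_a: tuple[str, ...], els_b: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    uniq = sorted(set(els_a) | set(els_b))
    idx = {el: k for k, el in enumerate(uniq)}
    At = np.empty((len(uniq), len(uniq)))
    Bt = np.empty_like(At)
    for ei in uniq:
        for ej in uniq:
            p = ff.pair(ei, ej)
            At[idx[ei], idx[ej]] = p.A
            Bt[idx[ei], idx[ej]] = p.B
    ia = np.array([idx[e] for e in els_a])
    ib = np.array([idx[e] for e in els_b])
    return At[np.ix_(ia, ib)], Bt[np.ix_(ia, ib)]


def _plane_energy_from_z(
    z: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    eta: float,
    z_offset: float,
    mode: str,
    guard: float,
) -> float:
    dz = np.abs(z - z_offset)
    if dz.min() <= guard:
        if mode == "penalized":
            return PENALTY_ENERGY
        raise GuardError(
            f"atom at height {dz.min():.4g} on/through the plane (guard {guard})"
        )
    inv2 = dz**-2.0
    inv4 = inv2 * inv2
    return float(eta * math.pi * ((B / 5.0) * inv4 * inv4 * inv2 - (A / 2.0)
                                  * inv4).sum())


def _pair_energy_from_coords(
    ca: np.ndarray,
    cb: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    mode: str,
    guard: float,
) -> float:
    diff = ca[:, None, :] - cb[None, :, :]
    r2 = (diff * diff).sum(axis=-1)
    if r2.min() <= guard * guard:
        if mode == "penalized":
            return PENALTY_ENERGY
        raise GuardError(
            f"pair distance {math.sqrt(r2.min()):.4g} <= guard {guard}"
        )
    inv6 = r2**-3.0
    return float(((B * inv6 - A) * inv6).sum())


def molecule_plane_energy(
    mol: RigidMolecule,
    plane: InfinitePlane,
    ff: ForceFieldTable,
    mode: str = "strict",
    guard: float = DISTANCE_GUARD,
) -> float:
    """Continuum energy between a molecule and the plane: sum of per-atom
    point-plane terms (one per atom; 69 for the default drug)."""
    A, B = _plane_constants(ff, mol.elements, plane.element)
    return _plane_energy_from_z(
        mol.coords[:, 2], A, B, plane.eta, plane.z_offset, mode, guard
    )


def molecule_pair_energy(
    molA: RigidMolecule,
    molB: RigidMolecule,
    ff: ForceFieldTable,
    mode: str = "strict",
    guard: float = DISTANCE_GUARD,
) -> float:
    """Exact discrete double sum between two molecules; symmetric in its
    arguments, no cutoff."""
    A, B = _pair_constant_matrices(ff, molA.elements, molB.elements)
    return _pair_energy_from_coords(molA.coords, molB.coords, A, B, mode, guard)


def system_energy_from_molecules(
    molecules,
    plane: InfinitePlane | None,
    ff: ForceFieldTable,
    mode: str = "strict",
    guard: float = DISTANCE_GUARD,
) -> float:
    """Total energy of already-placed molecules (+ optional plane)."""
    molecules = list(molecules)
    total = 0.0
    for i in range(len(molecules)):
        for j in range(i + 1, len(molecules)):
            total += molecule_pair_energy(molecules[i], molecules[j], ff, mode, guard)
        if plane is not None:
            total += molecule_plane_energy(molecules[i], plane, ff, mode, guard)
    return total


def system_energy(
    spec: SystemSpec,
    poses,
    mode: str = "strict",
    guard: float = DISTANCE_GUARD,
) -> float:
    """Objective value: total energy of the system with one pose per molecule.

    Sum of every molecule-molecule discrete term plus each molecule-plane
    continuum term present.  This is exactly what the search minimizes.
    """
    poses = list(poses)
    if len(poses) != spec.n_molecules:
        raise InvalidParameterError(
            f"need {spec.n_molecules} poses, got {len(poses)}"
        )
    placed = [apply_pose(m, p) for m, p in zip(spec.molecules, poses)]
    return system_energy_from_molecules(placed, spec.plane, spec.forcefield, mode, guard)


class EnergyModel:
    """Pre-compiled evaluator of the system objective for the optimizer.

    Caches COM-centered coordinates, element arrays and Lennard-Jones
    constant matrices once, then maps flat decision vectors
    ``(x, y, z, theta_x, theta_y) * n_molecules`` to penalized energies.
    """

    def __init__(self, spec: SystemSpec, guard: float = DISTANCE_GUARD):
        self.spec = spec
        self.guard = guard
        self._rel = [
            m.coords - center_of_mass(m) for m in spec.molecules
        ]
        ff = spec.forcefield
        self._pairAB = {}
        for i in range(spec.n_molecules):
            for j in range(i + 1, spec.n_molecules):
                self._pairAB[(i, j)] = _pair_constant_matrices(
                    ff, spec.molecules[i].elements, spec.molecules[j].elements
                )
        self._planeAB = None
        if spec.plane is not None:
            self._planeAB = [
                _plane_constants(ff, m.elements, spec.plane.element)
                for m in spec.molecules
            ]

    @property
    def n_var(self) -> int:
        return 5 * self.spec.n_molecules

    def placed_coords(self, vector: np.ndarray) -> list[np.ndarray]:
        vector = np.asarray(vector, dtype=float)
        coords = []
        for i, rel in enumerate(self._rel):
            x, y, z, tx, ty = vector[5 * i : 5 * i + 5]
            R = rotation_matrix(Pose(x, y, z, tx, ty))
            coords.append(rel @ R.T + np.array([x, y, z]))
        return coords

    def energy(self, vector: np.ndarray, mode: str = "penalized") -> float:
        coords = self.placed_coords(vector)
        total = 0.0
        plane = self.spec.plane
        for i, ci in enumerate(coords):
            for j in range(i + 1, len(coords)):
                A, B = self._pairAB[(i, j)]
                total += _pair_energy_from_coords(ci, coords[j], A, B, mode, self.guard)
            if plane is not None:
                A, B = self._planeAB[i]
                total += _plane_energy_from_z(
                    ci[:, 2], A, B, plane.eta, plane.z_offset, mode, self.guard
                )
        return total

    def batch(self, X: np.ndarray, mode: str = "penalized") -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.energy(row, mode) for row in X])
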