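"""Geometric characterization and type classification of optimized poses.

Two-molecule descriptors: center-of-mass separation ``d_doxh``; incline
angle ``alpha_doxh`` between the two oriented ring normals (0-180 deg, so an
anti-parallel pair reads ~180 deg); rotational angle ``beta`` between the
two in-plane C20->C3 reference directions, the second projected onto the
first molecule's ring plane (0-180 deg).

Molecule-plane descriptors: COM height ``d_gra``; ring tilt ``alpha_gra``
versus the sheet, folded to 0-90 deg; the closest atom's height and label
``delta_closest``; and the mean ring-carbon height ``d_star`` (a separation-
distance proxy comparable across studies).

Configuration classes: for two free molecules, A1 (oppositely parallel), A2
(overlapping) and A3 (perpendicular); on graphene, B1 (rings anti-aligned)
and B2 (aligned), both parallel to the sheet.  Threshold values separate the
empirically observed clusters and are configuration-exposed, since the
boundaries between classes are a convention rather than physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import InfinitePlane, SystemSpec, system_energy_from_molecules
from .forcefield import PENALTY_ENERGY
from .structures import (
    RigidMolecule,
    StructureError,
    apply_pose,
    center_of_mass,
    ring_plane,
)

__all__ = [
    "PairDescriptors",
    "PlaneDescriptors",
    "TYPE_LABELS",
    "ClassifierThresholds",
    "pair_descriptors",
    "plane_descriptors",
    "classify_two_doxh",
    "classify_two_doxh_on_graphene",
    "type_frequencies",
    "ScanProfile",
    "scan_profile",
    "SCAN_AXES",
]

TYPE_LABELS = ("A1", "A2", "A3", "B1", "B2", "failure")

SCAN_AXES = ("translate-x", "translate-z", "rotate-z", "rotate-x", "rotate-y")


@dataclass(frozen=True)
class PairDescriptors:
    """Relative geometry of two ring-bearing molecules."""

    d_doxh: float
    alpha_doxh: float  # deg, [0, 180]
    beta: float  # deg, [0, 180]

    def __post_init__(self) -> None:
        if self.d_doxh < 0:
            raise ValueError("d_doxh must be non-negative")
        for ang in (self.alpha_doxh, self.beta):
            if not 0.0 <= ang <= 180.0:
                raise ValueError(f"angle {ang} outside [0, 180] degrees")


@dataclass(frozen=True)
class PlaneDescriptors:
    """Geometry of one molecule relative to the graphene plane."""

    d_gra: float
    alpha_gra: float  # deg, [0, 90]
    delta_closest: float
    closest_label: str
    d_star: float


@dataclass(frozen=True)
class ClassifierThresholds:
    """Angular bands separating the configuration classes (degrees)."""

    anti: float = 135.0  # "oppositely aligned" lower bound on alpha or beta
    aligned: float = 45.0  # "aligned" upper bound on alpha_doxh
    perp_low: float = 60.0
    perp_high: float = 120.0
    overlap_low: float = 35.0
    overlap_high: float = 60.0
    b2_beta: float = 35.0


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise StructureError("zero-length vector in angle computation")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def pair_descriptors(molA: RigidMolecule, molB: RigidMolecule) -> PairDescriptors:
    """Distance and ring-plane angles between two placed molecules."""
    d = float(np.linalg.norm(center_of_mass(molA) - center_of_mass(molB)))
    v1a, _, n1 = ring_plane(molA)
    v1b, _, n2 = ring_plane(molB)
    alpha = _angle_deg(n1, n2)
    v1b_proj = v1b - np.dot(v1b, n1) * n1
    if np.linalg.norm(v1b_proj) < 1e-9 * np.linalg.norm(v1b):
        # reference direction perpendicular to the other ring: undefined spin
        beta = 90.0
    else:
        beta = _angle_deg(v1a, v1b_proj)
    return PairDescriptors(d, alpha, beta)


def plane_descriptors(
    mol: RigidMolecule,
    plane: InfinitePlane = InfinitePlane(),
    ring_labels: tuple[str, ...] | None = None,
) -> PlaneDescriptors:
    """Height, tilt and closest-atom bookkeeping versus the sheet.

    ``d_star`` averages |z| over the ring carbons (labels C1..C20 by
    default, or any explicit ``ring_labels``).
    """
    z0 = plane.z_offset
    d_gra = abs(float(center_of_mass(mol)[2]) - z0)
    _, _, n = ring_plane(mol)
    alpha = math.degrees(math.acos(min(1.0, abs(float(n[2])))))
    heights = np.abs(mol.coords[:, 2] - z0)
    k = int(np.argmin(heights))
    if ring_labels is None:
        ring_labels = tuple(
            l for l in (f"C{i}" for i in range(1, 21)) if l in mol.labels
        )
        if not ring_labels:
            raise StructureError("no ring carbons C1..C20 found for d_star")
    ring_idx = [mol.index_of(l) for l in ring_labels]
    d_star = float(heights[ring_idx].mean())
    return PlaneDescriptors(
        d_gra=d_gra,
        alpha_gra=alpha,
        delta_closest=float(heights[k]),
        closest_label=mol.labels[k],
        d_star=d_star,
    )


def classify_two_doxh(
    desc: PairDescriptors, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> str:
    """Assign A1/A2/A3 (or 'failure') to a free two-molecule configuration."""
    t = thresholds
    a, b = desc.alpha_doxh, desc.beta
    if a > t.anti and b > t.anti:
        return "A1"
    if a > t.anti and t.perp_low < b < t.perp_high:
        return "A3"
    if a < t.aligned and t.overlap_low < b < t.overlap_high:
        return "A2"
    return "failure"


def classify_two_doxh_on_graphene(
    desc: PairDescriptors,
    alpha_gra: tuple[float, float] | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    max_tilt: float = 20.0,
) -> str:
    """Assign B1/B2 (or 'failure') to a two-molecules-on-graphene result.

    Both rings must lie near-parallel to the sheet; if per-molecule
    ``alpha_gra`` tilts are supplied, a tilt above ``max_tilt`` degrees is a
    failure outright.
    """
    if alpha_gra is not None and any(a >= max_tilt for a in alpha_gra):
        return "failure"
    if desc.beta > thresholds.anti:
        return "B1"
    if desc.beta < thresholds.b2_beta:
        return "B2"
    return "failure"


def type_frequencies(labels) -> dict[str, float]:
    """Fraction of each configuration label; fractions sum to 1."""
    labels = [getattr(r, "type_label", r) for r in labels]
    if not labels:
        raise ValueError("need at least one labeled record")
    for l in labels:
        if l not in TYPE_LABELS:
            raise ValueError(f"unknown type label {l!r}")
    n = len(labels)
    return {l: labels.count(l) / n for l in TYPE_LABELS if l in labels}


@dataclass(frozen=True)
class ScanProfile:
    """1-D energy profile around a configuration."""

    axis: str
    offsets: tuple[float, ...]  # Angstrom (translate-*) or degrees (rotate-*)
    energies: tuple[float, ...]
    valid: tuple[bool, ...]
    argmin_offset: float


def _perturb(mol: RigidMolecule, axis: str, offset: float) -> RigidMolecule:
    coords = mol.coords.copy()
    if axis.startswith("translate-"):
        k = "xyz".index(axis[-1])
        coords[:, k] += offset
        return mol.with_coords(coords)
    k = "xyz".index(axis[-1])
    t = math.radians(offset)
    c, s = math.cos(t), math.sin(t)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][k]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s if k != 1 else s
    R[j, i] = s if k != 1 else -s
    com = center_of_mass(mol)
    return mol.with_coords((coords - com) @ R.T + com)


def scan_profile(
    spec: SystemSpec,
    poses,
    axis: str,
    grid,
    mol_index: int = 0,
) -> ScanProfile:
    """Energy along a translation (Angstrom) or rotation (degree) offset.

    One molecule is re-posed along ``axis`` while everything else stays
    fixed; the rotation pivot is the moving molecule's own center of mass.
    The grid must contain offset 0 so the unperturbed energy is on the
    profile; guard-violating grid points are flagged invalid and excluded
    from the arg-min.
    """
    if axis not in SCAN_AXES:
        raise ValueError(f"axis must be one of {SCAN_AXES}, got {axis!r}")
    grid = [float(g) for g in grid]
    if not any(abs(g) < 1e-12 for g in grid):
        raise ValueError("scan grid must contain offset 0")
    placed = [apply_pose(m, p) for m, p in zip(spec.molecules, poses)]
    energies, valid = [], []
    for g in grid:
        mols = list(placed)
        mols[mol_index] = _perturb(placed[mol_index], axis, g)
        e = system_energy_from_molecules(
            mols, spec.plane, spec.forcefield, mode="penalized"
        )
        energies.append(e)
        valid.append(e < PENALTY_ENERGY / 2.0)
    finite = [(e, g) for e, g, ok in zip(energies, grid, valid) if ok]
    if not finite:
        raise ValueError("every grid point violated the distance guard")
    argmin_offset = min(finite)[1]
    return ScanProfile(
        axis=axis,
        offsets=tuple(grid),
        energies=tuple(energies),
        valid=tuple(valid),
        argmin_offset=float(argmin_offset),
    )
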