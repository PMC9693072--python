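"""Rigid molecules, poses, ring-plane geometry and coordinate conversions.

A molecule is a labeled list of atoms treated as a solid body: the only
degrees of freedom are a rigid translation and two rotations.  A pose is the
5-tuple ``(x, y, z, theta_x, theta_y)``: the body is rotated about its center
of mass by ``Rx(theta_x)`` then ``Ry(theta_y)`` and the center of mass is
moved to ``(x, y, z)``.  There is no z-rotation variable by default; for a
body above an isotropic continuum plane a z-rotation does not change the
energy, and the two-body encoding deliberately mirrors the same 5-DOF choice.

The fused carbon-ring plane of the drug is spanned by the two anchor vectors
C20->C3 and C20->C19; their cross product is the ring normal used by all
angular descriptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .forcefield import ATOMIC_WEIGHTS, ELEMENTS

__all__ = [
    "Atom",
    "RigidMolecule",
    "Pose",
    "UnitCell",
    "StructureError",
    "center_of_mass",
    "apply_pose",
    "rotation_matrix",
    "ring_plane",
    "fractional_to_cartesian",
    "cell_matrix",
]

DEFAULT_ANCHORS = ("C20", "C3", "C19")
DEFAULT_PROBES = ("H21B", "H8A")


class StructureError(ValueError):
    """Invalid molecular structure or degenerate geometry."""


@dataclass(frozen=True)
class Atom:
    """One labeled atom: e.g. ``Atom("C20", "C", (1.2, 0.0, -0.3))``."""

    label: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise StructureError(f"unsupported element {self.element!r}")
        object.__setattr__(self, "position", tuple(float(v) for v in self.position))
        if len(self.position) != 3:
            raise StructureError("position must be a 3-vector")


@dataclass(frozen=True)
class Pose:
    """Rigid-body placement: COM target (x, y, z) in Angstrom, angles in rad."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    theta_x: float = 0.0
    theta_y: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.theta_x, self.theta_y])

    @classmethod
    def from_array(cls, v) -> "Pose":
        v = np.asarray(v, dtype=float)
        if v.shape != (5,):
            raise StructureError(f"pose vector must have 5 entries, got {v.shape}")
        return cls(*v.tolist())


class RigidMolecule:
    """Labeled atoms with coordinates, treated as one solid body.

    Parameters
    ----------
    atoms:
        Ordered atoms; labels must be unique.
    plane_anchors:
        Labels ``(origin, terminal1, terminal2)`` spanning the carbon ring
        plane, or ``None`` for structures (e.g. single-atom probes) that have
        no ring.  Operations needing the ring plane raise if absent.
    probe_labels:
        Labels reported specially by descriptors (closest-atom bookkeeping).
    """

    def __init__(
        self,
        atoms,
        plane_anchors: tuple[str, str, str] | None = DEFAULT_ANCHORS,
        probe_labels: tuple[str, ...] = DEFAULT_PROBES,
    ):
        atoms = list(atoms)
        if not atoms:
            raise StructureError("molecule needs at least one atom")
        labels = [a.label for a in atoms]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise StructureError(f"duplicate atom labels: {dup}")
        if plane_anchors is not None:
            missing = [l for l in plane_anchors if l not in set(labels)]
            if missing and tuple(plane_anchors) == DEFAULT_ANCHORS:
                # default anchors absent (e.g. probe "molecules"): no ring
                plane_anchors = None
            elif missing:
                raise StructureError(f"anchor labels not in molecule: {missing}")
        self.atoms = tuple(atoms)
        self.plane_anchors = tuple(plane_anchors) if plane_anchors else None
        self.probe_labels = tuple(probe_labels)
        self._index = {a.label: i for i, a in enumerate(self.atoms)}
        self._coords = np.array([a.position for a in self.atoms], dtype=float)
        self._coords.flags.writeable = False

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) read-only coordinate array in Angstrom."""
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_WEIGHTS[a.element] for a in self.atoms])

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise StructureError(f"no atom labeled {label!r}") from None

    def position_of(self, label: str) -> np.ndarray:
        return self._coords[self.index_of(label)]

    def composition(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts

    def with_coords(self, coords: np.ndarray) -> "RigidMolecule":
        """Copy of this molecule with replaced coordinates (same labels)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise StructureError(
                f"coordinate shape {coords.shape} != {self._coords.shape}"
            )
        atoms = [
            replace(a, position=tuple(p)) for a, p in zip(self.atoms, coords)
        ]
        return RigidMolecule(atoms, self.plane_anchors, self.probe_labels)

    def validate_ring_contract(self) -> None:
        """Enforce the ring-plane contract: >=3 atoms, anchors present and
        non-collinear."""
        if len(self.atoms) < 3:
            raise StructureError("ring contract needs at least 3 atoms")
        if self.plane_anchors is None:
            raise StructureError("molecule has no ring-plane anchors")
        ring_plane(self)  # raises on missing/collinear anchors


def center_of_mass(mol: RigidMolecule) -> np.ndarray:
    """Mass-weighted mean position, with IUPAC standard atomic weights."""
    m = mol.masses
    return (m[:, None] * mol.coords).sum(axis=0) / m.sum()


def _rot_x(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(pose: Pose) -> np.ndarray:
    """Combined rotation Ry(theta_y) @ Rx(theta_x) of a pose."""
    return _rot_y(pose.theta_y) @ _rot_x(pose.theta_x)


def apply_pose(mol: RigidMolecule, pose: Pose) -> RigidMolecule:
    """Rigidly transform ``mol``: rotate about its COM, move COM to (x,y,z).

    The input molecule is unmodified.  Internal distances are exactly
    preserved up to floating-point rounding.
    """
    com = center_of_mass(mol)
    R = rotation_matrix(pose)
    coords = (mol.coords - com) @ R.T + np.array([pose.x, pose.y, pose.z])
    return mol.with_coords(coords)


def ring_plane(mol: RigidMolecule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ring-plane spanning vectors and unit normal.

    Returns ``(v1, v2, n_hat)`` with ``v1 = terminal1 - origin``,
    ``v2 = terminal2 - origin`` and ``n_hat = (v1 x v2)/|v1 x v2|`` for the
    molecule's anchor labels (default C20, C3, C19).
    """
    if mol.plane_anchors is None:
        raise StructureError("molecule has no ring-plane anchors")
    o, t1, t2 = (mol.position_of(l) for l in mol.plane_anchors)
    v1 = t1 - o
    v2 = t2 - o
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    if norm < 1e-10 * max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-30):
        raise StructureError("anchor atoms are collinear; ring plane degenerate")
    return v1, v2, n / norm


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise StructureError("cell angles must lie in (0, 180) degrees")


def cell_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional->Cartesian matrix, ``a`` along x, ``b`` in the xy-plane.

    Columns are the Cartesian cell vectors.  Raises for degenerate cells
    (angle combinations with no 3-D realization).
    """
    al, be, ga = (math.radians(v) for v in (cell.alpha, cell.beta, cell.gamma))
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sg = math.sin(ga)
    vol_term = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if vol_term <= 0 or sg == 0:
        raise StructureError("degenerate unit cell")
    return np.array(
        [
            [cell.a, cell.b * cg, cell.c * cb],
            [0.0, cell.b * sg, cell.c * (ca - cb * cg) / sg],
            [0.0, 0.0, cell.c * math.sqrt(vol_term) / sg],
        ]
    )


def fractional_to_cartesian(frac, cell: UnitCell) -> np.ndarray:
    """Map fractional coordinates (single triplet or (N,3)) to Cartesian."""
    frac = np.asarray(frac, dtype=float)
    return frac @ cell_matrix(cell).T
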