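"""Deterministic synthetic structures for testing and demonstration.

The real drug coordinates come from an external crystal structure that is
not bundled here, so every pipeline stage is exercised against a *mock*
molecule instead: a 69-atom rigid body with the doxorubicin cation's
composition (27 C, 30 H, 1 N, 11 O), an exactly planar fused-ring block of
20 carbons labeled C1..C20 (anchors C20, C3, C19), and peripheral atoms
grown at chemically plausible bond lengths (0.9-1.6 Angstrom) including the
probe hydrogens H21B and H8A.  The mock geometry is not doxorubicin — it
only honors the structural contracts the pipeline consumes (labels,
planarity, composition, minimum interatomic separation).

A honeycomb graphene patch generator provides the discrete counterpart of
the continuum plane (0.3812 carbon atoms per square Angstrom at the
1.421 Angstrom bond length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structures import Atom, RigidMolecule

__all__ = [
    "MockSpec",
    "InvalidSpecError",
    "make_mock_doxh",
    "make_graphene_patch",
    "GRAPHENE_BOND_LENGTH",
    "graphene_surface_density",
]

#: Carbon-carbon bond length of graphene (Angstrom).
GRAPHENE_BOND_LENGTH = 1.421

_RING_BOND = 1.42
_MIN_SEPARATION = 0.9
_BOND = {"C": 1.52, "N": 1.47, "O": 1.40}  # heavy-atom bond to parent
_H_BOND = {"C": 1.09, "N": 1.02, "O": 1.00}


class InvalidSpecError(ValueError):
    """Mock-molecule specification cannot be realized."""


@dataclass(frozen=True)
class MockSpec:
    """Recipe for a mock drug molecule.

    ``composition`` maps element to atom count (default: the drug's
    27 C / 30 H / 1 N / 11 O); ``ring_size`` carbons form the planar
    fused-ring block.
    """

    seed: int = 0
    composition: dict = field(
        default_factory=lambda: {"C": 27, "H": 30, "N": 1, "O": 11}
    )
    ring_size: int = 20

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.composition.values()):
            raise InvalidSpecError("element counts must be non-negative")
        if self.ring_size > self.composition.get("C", 0):
            raise InvalidSpecError(
                f"ring_size {self.ring_size} exceeds carbon count "
                f"{self.composition.get('C', 0)}"
            )
        if self.ring_size < 4:
            raise InvalidSpecError("ring needs at least 4 carbons")


def _honeycomb_sites(radius: float, bond: float) -> np.ndarray:
    """All honeycomb lattice points within ``radius`` of the origin (2-D)."""
    a1 = np.array([1.5 * bond, math.sqrt(3.0) / 2.0 * bond])
    a2 = np.array([1.5 * bond, -math.sqrt(3.0) / 2.0 * bond])
    m = int(radius / bond) + 3
    ij = np.mgrid[-m : m + 1, -m : m + 1].reshape(2, -1).T
    cells = ij @ np.vstack([a1, a2])
    pts = np.concatenate([cells, cells + np.array([bond, 0.0])])
    return pts[(pts**2).sum(axis=1) <= radius**2]


def make_graphene_patch(
    radius: float, bond_length: float = GRAPHENE_BOND_LENGTH
) -> list[Atom]:
    """Finite honeycomb carbon lattice in the z=0 plane, within ``radius``.

    The discrete stand-in for the continuum plane; its areal density
    converges to 4/(3*sqrt(3)*bond^2) = 0.3812 atoms/Angstrom^2.
    """
    if radius <= bond_length:
        raise InvalidSpecError("patch radius must exceed the bond length")
    pts = _honeycomb_sites(radius, bond_length)
    order = np.lexsort((pts[:, 1], pts[:, 0], (pts**2).sum(axis=1).round(9)))
    return [
        Atom(f"C{k + 1}", "C", (p[0], p[1], 0.0)) for k, p in enumerate(pts[order])
    ]


def graphene_surface_density(bond_length: float = GRAPHENE_BOND_LENGTH) -> float:
    """Exact areal density of the honeycomb lattice (atoms/Angstrom^2)."""
    return 4.0 / (3.0 * math.sqrt(3.0) * bond_length**2)


def _fibonacci_sphere(n: int = 48) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _place_bonded(
    parent: np.ndarray,
    bond: float,
    placed: np.ndarray,
    outward: np.ndarray,
    rng: np.random.Generator,
    min_sep: float = _MIN_SEPARATION,
) -> np.ndarray | None:
    """First sterically feasible position at ``bond`` from ``parent``.

    Candidate directions are ranked outward-first with a seeded perturbation
    so different seeds grow visibly different peripheries.
    """
    dirs = _fibonacci_sphere()
    score = dirs @ outward + rng.normal(0.0, 0.35, len(dirs))
    for d in dirs[np.argsort(-score)]:
        pos = parent + bond * d
        dmin = np.sqrt(((placed - pos) ** 2).sum(axis=1).min())
        if dmin >= min_sep:
            return pos
    return None


def _ring_block(n_ring: int) -> tuple[np.ndarray, np.ndarray]:
    """Compact planar honeycomb patch of ``n_ring`` sites, centered."""
    pts = _honeycomb_sites(_RING_BOND * (1.5 + math.sqrt(n_ring)), _RING_BOND)
    order = np.lexsort((pts[:, 1], pts[:, 0], (pts**2).sum(axis=1).round(9)))
    ring = pts[order][:n_ring]
    centroid = ring.mean(axis=0)
    ring = ring - centroid
    return np.column_stack([ring, np.zeros(len(ring))]), np.zeros(3)


def _label_ring(ring: np.ndarray) -> list[int]:
    """Order ring sites so the last is the most central and the rest sweep
    by angle (labels C1..C{n-1} then C{n} at the center)."""
    r2 = (ring[:, :2] ** 2).sum(axis=1)
    center_idx = int(np.argmin(r2))
    rest = [i for i in range(len(ring)) if i != center_idx]
    rest.sort(key=lambda i: (math.atan2(ring[i, 1], ring[i, 0]), r2[i]))
    return rest + [center_idx]


def make_mock_doxh(spec: MockSpec = MockSpec()) -> RigidMolecule:
    """Generate the deterministic mock drug molecule for ``spec``.

    Guarantees: exact composition; ring carbons coplanar (z identically 0
    before any pose is applied); all bonds 0.9-1.6 Angstrom; minimum
    interatomic separation >= 0.9 Angstrom; bitwise-identical output for a
    given seed.
    """
    comp = dict(spec.composition)
    n_ring = spec.ring_size
    for attempt in range(20):
        rng = np.random.default_rng((spec.seed, attempt))
        try:
            return _build(comp, n_ring, rng)
        except _CrowdingError:
            continue
    raise InvalidSpecError("could not realize spec without steric clashes")


class _CrowdingError(Exception):
    pass


def _build(comp: dict, n_ring: int, rng: np.random.Generator) -> RigidMolecule:
    ring, centroid = _ring_block(n_ring)
    order = _label_ring(ring)
    ring = ring[order]
    ring_labels = [f"C{i + 1}" for i in range(n_ring)]  # C{n_ring} is central

    positions = [ring[i] for i in range(n_ring)]
    labels = list(ring_labels)
    elements = ["C"] * n_ring

    # ring connectivity: perimeter atoms have < 3 ring neighbors
    d = np.sqrt(((ring[:, None, :] - ring[None, :, :]) ** 2).sum(-1))
    n_nb = ((d > 0.1) & (d < _RING_BOND * 1.15)).sum(axis=1)
    perimeter = [i for i in range(n_ring) if n_nb[i] < 3]
    perimeter.sort(key=lambda i: -np.linalg.norm(ring[i, :2]))

    def outward(p: np.ndarray) -> np.ndarray:
        v = p - centroid
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

    def grow(parent_idx: int, element: str, bond: float, label: str) -> int:
        placed = np.array(positions)
        pos = _place_bonded(
            positions[parent_idx], bond, placed, outward(positions[parent_idx]), rng
        )
        if pos is None:
            raise _CrowdingError
        positions.append(pos)
        labels.append(label)
        elements.append(element)
        return len(positions) - 1

    # side chain: remaining carbons then the nitrogen, grown tip-to-tip
    chain = []
    tip = perimeter[0]
    for k in range(comp.get("C", 0) - n_ring):
        tip = grow(tip, "C", _BOND["C"], f"C{n_ring + k + 1}")
        chain.append(tip)
    for k in range(comp.get("N", 0)):
        tip = grow(tip, "N", _BOND["N"], f"N{k + 1}")
        chain.append(tip)

    # oxygens decorate the ring perimeter first, then the chain
    o_parents = [i for i in perimeter[1:]] + chain
    for k in range(comp.get("O", 0)):
        parent = o_parents[k % len(o_parents)]
        chain_idx = grow(parent, "O", _BOND["O"], f"O{k + 1}")

    # hydrogens: capacity-weighted queue over heavy atoms
    h_queue: list[int] = []
    cap = {"O": 1, "N": 3, "C": 2}
    heavy = list(range(len(positions)))
    for rounds in range(6):
        for i in heavy:
            if elements[i] == "C" and i < n_ring and i not in perimeter:
                continue  # interior ring carbons stay bare
            h_queue.extend([i] * (cap[elements[i]] if rounds == 0 else 1))
        if len(h_queue) >= comp.get("H", 0):
            break
    n_h = comp.get("H", 0)
    for k in range(n_h):
        label = f"H{k + 1}"
        if k + 1 == 8:
            label = "H8A"
        elif k + 1 == 21:
            label = "H21B"
        parent = h_queue[k % len(h_queue)]
        grow(parent, "H", _H_BOND[elements[parent]], label)

    coords = np.array(positions)
    dmat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < _MIN_SEPARATION - 1e-12:
        raise _CrowdingError

    anchors = (f"C{n_ring}", "C3", f"C{n_ring - 1}")
    probes = tuple(p for p in ("H21B", "H8A") if p in labels)
    atoms = [
        Atom(l, e, tuple(p)) for l, e, p in zip(labels, elements, positions)
    ]
    mol = RigidMolecule(atoms, plane_anchors=anchors, probe_labels=probes)
    mol.validate_ring_contract()
    return mol
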