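"""Energy evaluators: continuum integrals, plane energies, discrete sums."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize as sopt

from nanopose.energy import (
    EnergyModel,
    InfinitePlane,
    SystemSpec,
    molecule_pair_energy,
    molecule_plane_energy,
    point_plane_energy,
    point_plane_integral,
    system_energy,
    system_energy_from_molecules,
)
from nanopose.fixtures import graphene_surface_density, make_graphene_patch
from nanopose.forcefield import GuardError, InvalidParameterError, PENALTY_ENERGY
from nanopose.structures import Atom, Pose, RigidMolecule, apply_pose


def carbon_at(z, label="C1"):
    return RigidMolecule([Atom(label, "C", (0.0, 0.0, z))], plane_anchors=None)


# -- continuum integral ----------------------------------------------------

def test_point_plane_integral_closed_forms():
    assert point_plane_integral(1.0, 3) == pytest.approx(math.pi / 2)
    assert point_plane_integral(2.0, 6) == pytest.approx(math.pi / 5120)
    with pytest.raises(InvalidParameterError):
        point_plane_integral(0.0, 3)
    with pytest.raises(InvalidParameterError):
        point_plane_integral(1.0, 1)


def test_point_plane_integral_matches_quadrature():
    d, n = 2.5, 3
    oracle, _ = integrate.dblquad(
        lambda y, z: (d * d + y * y + z * z) ** -n,
        -400, 400, -400, 400, epsabs=1e-14, epsrel=1e-10,
    )
    assert point_plane_integral(d, n) == pytest.approx(oracle, rel=1e-6)


# -- point-plane energy ----------------------------------------------------

def test_point_plane_energy_minimum_and_decay(cc_pair):
    dstar = (cc_pair.B / cc_pair.A) ** (1 / 6)
    assert point_plane_energy(dstar, cc_pair) == pytest.approx(-7.63e-2, rel=5e-3)
    # numerical 1-D minimization lands on the analytic root of A d^6 = B
    res = sopt.minimize_scalar(
        lambda d: point_plane_energy(d, cc_pair), bounds=(1.0, 10.0),
        method="bounded",
    )
    assert res.x == pytest.approx(dstar, abs=1e-5)
    assert abs(point_plane_energy(1e6, cc_pair)) < 1e-18
    with pytest.raises(GuardError):
        point_plane_energy(0.05, cc_pair)
    assert point_plane_energy(0.05, cc_pair, mode="penalized") == PENALTY_ENERGY


def test_continuum_matches_discrete_lattice_sum(cc_pair):
    """Registry-averaged honeycomb sum vs the analytic plane integral.

    The continuum plane carries the *mean* areal density, so its discrete
    counterpart is the lattice sum averaged over lateral registry; a single
    fixed registry is also checked at 3.5 A where corrugation is small.
    """
    bond = 1.421
    eta = graphene_surface_density(bond)
    pts = np.array([a.position for a in make_graphene_patch(60.0, bond)])[:, :2]
    a1 = np.array([1.5 * bond, math.sqrt(3) / 2 * bond])
    a2 = np.array([1.5 * bond, -math.sqrt(3) / 2 * bond])
    offs = np.array(
        [(i + 0.5) / 4 * a1 + (j + 0.5) / 4 * a2 for i in range(4) for j in range(4)]
    )

    def lattice_sum(d, shift):
        r2 = ((pts - shift) ** 2).sum(axis=1) + d * d
        inv6 = r2**-3.0
        return float(((cc_pair.B * inv6 - cc_pair.A) * inv6).sum())

    for d in (2.5, 3.5, 5.0, 8.0):
        avg = np.mean([lattice_sum(d, s) for s in offs])
        cont = point_plane_energy(d, cc_pair, eta=eta)
        assert abs(cont - avg) / max(abs(avg), abs(cont)) < 0.01
    single = lattice_sum(3.5, np.zeros(2))
    cont = point_plane_energy(3.5, cc_pair, eta=eta)
    assert abs(cont - single) / abs(single) < 0.01


# -- molecule-plane --------------------------------------------------------

def test_molecule_plane_reduces_to_point_plane(ff, cc_pair):
    plane = InfinitePlane()
    one = carbon_at(3.7)
    assert molecule_plane_energy(one, plane, ff) == pytest.approx(
        point_plane_energy(3.7, cc_pair, plane.eta), rel=1e-14
    )
    two = RigidMolecule(
        [Atom("C1", "C", (0, 0, 3.7)), Atom("C2", "C", (5, 2, 3.7))],
        plane_anchors=None,
    )
    assert molecule_plane_energy(two, plane, ff) == pytest.approx(
        2 * molecule_plane_energy(one, plane, ff), rel=1e-14
    )


def test_molecule_plane_matches_per_atom_summation(ff, mock_mol):
    plane = InfinitePlane()
    posed = apply_pose(mock_mol, Pose(1.0, -2.0, 6.0, 0.4, -0.2))
    hand = sum(
        point_plane_energy(abs(z), ff.pair(el, "C"), plane.eta)
        for el, z in zip(posed.elements, posed.coords[:, 2])
    )
    assert molecule_plane_energy(posed, plane, ff) == pytest.approx(hand, abs=1e-12)
    with pytest.raises(GuardError):
        molecule_plane_energy(carbon_at(0.0), plane, ff)


# -- molecule-molecule -----------------------------------------------------

def test_pair_energy_at_sigma_and_symmetry(ff, cc_pair, mock_mol):
    a, b = carbon_at(0.0), carbon_at(cc_pair.sigma, "C2")
    assert molecule_pair_energy(a, b, ff) == pytest.approx(
        -4.5150e-3, rel=1e-4
    )
    other = apply_pose(mock_mol, Pose(0, 0, 12.0, 0.7, 0.1))
    assert molecule_pair_energy(mock_mol, other, ff) == pytest.approx(
        molecule_pair_energy(other, mock_mol, ff), rel=1e-14
    )


def test_pair_energy_matches_brute_force_double_loop(ff, mock_mol):
    other = apply_pose(mock_mol, Pose(2.0, 1.0, 9.0, 0.5, -0.9))
    hand = 0.0
    for ai, ei in zip(mock_mol.coords, mock_mol.elements):
        for bj, ej in zip(other.coords, other.elements):
            rho = math.dist(ai, bj)
            p = ff.pair(ei, ej)
            hand += -p.A / rho**6 + p.B / rho**12
    assert molecule_pair_energy(mock_mol, other, ff) == pytest.approx(
        hand, rel=1e-12
    )


# -- composite systems -----------------------------------------------------

def test_system_requires_an_interaction(mock_mol):
    with pytest.raises(InvalidParameterError):
        SystemSpec((mock_mol,), plane=None)


def test_system_energy_reductions_and_decoupling(ff, mock_mol):
    plane = InfinitePlane()
    spec_ii = SystemSpec((mock_mol,), plane=plane, forcefield=ff)
    pose = Pose(0, 0, 5.0, 0.2, 0.1)
    assert system_energy(spec_ii, [pose]) == pytest.approx(
        molecule_plane_energy(apply_pose(mock_mol, pose), plane, ff), rel=1e-14
    )
    # far-apart molecules above the plane decouple into two independent terms
    spec_iii = SystemSpec((mock_mol, mock_mol), plane=plane, forcefield=ff)
    p1 = Pose(-40.0, 0, 5.0, 0.0, 0.0)
    p2 = Pose(40.0, 0, 5.0, 0.0, 0.0)
    coupled = system_energy(spec_iii, [p1, p2])
    independent = system_energy(spec_ii, [p1]) + system_energy(spec_ii, [p2])
    assert abs(coupled - independent) < 1e-6


def test_plane_energy_invariances(ff, mock_mol):
    plane = InfinitePlane()
    spec = SystemSpec((mock_mol,), plane=plane, forcefield=ff)
    base = system_energy(spec, [Pose(0, 0, 5.0, 0.3, 0.2)])
    shifted = system_energy(spec, [Pose(3.7, -8.1, 5.0, 0.3, 0.2)])
    assert shifted == pytest.approx(base, abs=1e-12)
    # continuum isotropy: rotating the posed body about z changes nothing
    posed = apply_pose(mock_mol, Pose(0, 0, 5.0, 0.3, 0.2))
    t = 1.234
    Rz = np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )
    rotated = posed.with_coords(posed.coords @ Rz.T)
    assert molecule_plane_energy(rotated, plane, ff) == pytest.approx(
        molecule_plane_energy(posed, plane, ff), abs=1e-12
    )


def test_energy_model_consistent_with_reference_path(ff, mock_mol, rng):
    spec = SystemSpec((mock_mol, mock_mol), plane=InfinitePlane(), forcefield=ff)
    model = EnergyModel(spec)
    for _ in range(5):
        v = rng.uniform(-1, 1, 10) * np.array([8, 8, 4, np.pi, np.pi] * 2)
        v[2] += 8.0
        v[7] += 16.0
        poses = [Pose(*v[:5]), Pose(*v[5:])]
        assert model.energy(v) == pytest.approx(
            system_energy(spec, poses, mode="penalized"), rel=1e-12
        )


def test_penalized_mode_returns_finite_energy_for_overlap(ff, mock_mol):
    spec = SystemSpec((mock_mol, mock_mol), plane=None, forcefield=ff)
    poses = [Pose(0, 0, 0, 0, 0), Pose(0, 0, 0, 0, 0)]  # perfect overlap
    e = system_energy(spec, poses, mode="penalized")
    assert e >= PENALTY_ENERGY
    with pytest.raises(GuardError):
        system_energy(spec, poses, mode="strict")
    assert system_energy_from_molecules(
        [mock_mol, mock_mol], None, ff, mode="penalized"
    ) >= PENALTY_ENERGY
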