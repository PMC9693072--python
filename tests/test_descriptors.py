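"""Configuration descriptors, type classification and tuning scans."""

import math
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from nanopose.descriptors import (
    ClassifierThresholds,
    PairDescriptors,
    classify_two_doxh,
    classify_two_doxh_on_graphene,
    pair_descriptors,
    plane_descriptors,
    scan_profile,
    type_frequencies,
)
from nanopose.energy import InfinitePlane, SystemSpec, system_energy
from nanopose.structures import (
    Atom,
    Pose,
    RigidMolecule,
    apply_pose,
    center_of_mass,
)


def _rotated(mol, axis, deg):
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    R = {
        "x": np.array([[1, 0, 0], [0, c, -s], [0, s, c]]),
        "y": np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]]),
        "z": np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]),
    }[axis]
    com = center_of_mass(mol)
    return mol.with_coords((mol.coords - com) @ R.T + com)


def _shifted(mol, vec):
    return mol.with_coords(mol.coords + np.asarray(vec, dtype=float))


def flat_ring(z=0.0):
    """Planar ring-bearing molecule lying in the z-plane."""
    atoms = [
        Atom("C20", "C", (0, 0, z)),
        Atom("C3", "C", (1.4, 0, z)),
        Atom("C19", "C", (0, 1.4, z)),
        Atom("C2", "C", (1.4, 1.4, z)),
        Atom("H1", "H", (-0.8, -0.8, z + 0.4)),
    ]
    return RigidMolecule(atoms)


# -- pair descriptors ------------------------------------------------------

def test_pair_descriptors_duplicate_in_place(mock_mol):
    d = pair_descriptors(mock_mol, mock_mol)
    assert d.d_doxh == pytest.approx(0.0, abs=1e-12)
    assert d.alpha_doxh == pytest.approx(0.0, abs=1e-6)
    assert d.beta == pytest.approx(0.0, abs=1e-6)


def test_pair_descriptors_constructed_rotations(mock_mol):
    # 180 deg about an in-plane axis flips the oriented normal
    flipped = _rotated(mock_mol, "x", 180.0)
    assert pair_descriptors(mock_mol, flipped).alpha_doxh == pytest.approx(
        180.0, abs=1e-6
    )
    # 90 deg about the ring's own normal: beta = 90, alpha = 0
    ring = flat_ring()  # normal along z
    spun = _rotated(ring, "z", 90.0)
    d = pair_descriptors(ring, spun)
    assert d.alpha_doxh == pytest.approx(0.0, abs=1e-6)
    assert d.beta == pytest.approx(90.0, abs=1e-6)


def test_pair_descriptors_invariant_under_global_rigid_motion(mock_mol):
    other = apply_pose(mock_mol, Pose(3, 1, 8, 0.6, -0.4))
    ref = pair_descriptors(mock_mol, other)
    moved = [
        _shifted(_rotated(m, "z", 37.0), (5.0, -2.0, 1.0))
        for m in (mock_mol, other)
    ]
    got = pair_descriptors(*moved)
    assert got.d_doxh == pytest.approx(ref.d_doxh, abs=1e-9)
    assert got.alpha_doxh == pytest.approx(ref.alpha_doxh, abs=1e-6)
    assert got.beta == pytest.approx(ref.beta, abs=1e-6)


# -- plane descriptors -----------------------------------------------------

def test_plane_descriptors_flat_and_tilted():
    ring = _shifted(flat_ring(), (0, 0, 4.0))
    d = plane_descriptors(ring, ring_labels=("C2", "C3", "C19", "C20"))
    assert d.d_gra == pytest.approx(center_of_mass(ring)[2], abs=1e-12)
    assert d.alpha_gra == pytest.approx(0.0, abs=1e-9)
    assert d.d_star == pytest.approx(4.0, abs=1e-12)
    assert d.closest_label == "C20" or d.closest_label.startswith("C")
    tilted = _shifted(_rotated(flat_ring(), "x", 90.0), (0, 0, 6.0))
    dt = plane_descriptors(tilted, ring_labels=("C2", "C3", "C19", "C20"))
    assert dt.alpha_gra == pytest.approx(90.0, abs=1e-6)


def test_plane_descriptors_closest_atom_matches_hand_computation(mock_mol):
    posed = apply_pose(mock_mol, Pose(1.0, 2.0, 6.0, 0.5, 0.3))
    d = plane_descriptors(posed)
    heights = np.abs(posed.coords[:, 2])
    k = int(np.argmin(heights))
    assert d.closest_label == posed.labels[k]
    assert d.delta_closest == pytest.approx(heights[k], abs=1e-12)
    ring_idx = [posed.index_of(f"C{i}") for i in range(1, 21)]
    assert d.d_star == pytest.approx(heights[ring_idx].mean(), abs=1e-12)


def test_plane_descriptors_invariant_under_rotation_about_z(mock_mol):
    posed = apply_pose(mock_mol, Pose(0, 0, 5.0, 0.4, 0.2))
    ref = plane_descriptors(posed)
    spun = _rotated(posed, "z", 123.0)
    got = plane_descriptors(spun)
    assert got.d_gra == pytest.approx(ref.d_gra, abs=1e-9)
    assert got.alpha_gra == pytest.approx(ref.alpha_gra, abs=1e-6)
    assert got.d_star == pytest.approx(ref.d_star, abs=1e-9)


# -- classification --------------------------------------------------------

def _reference_rows(name):
    text = resources.files("nanopose.data").joinpath(name)
    with resources.as_file(text) as path:
        return pd.read_csv(path)


def test_two_molecule_classifier_reproduces_reference_table():
    df = _reference_rows("two_doxh_reference.csv")
    for _, row in df.iterrows():
        desc = PairDescriptors(row.d_doxh, row.alpha_doxh, row.beta)
        assert classify_two_doxh(desc) == row.type, row.tag


def test_on_graphene_classifier_reproduces_reference_table():
    df = _reference_rows("two_doxh_graphene_reference.csv")
    for _, row in df.iterrows():
        desc = PairDescriptors(row.d_doxh, row.alpha_doxh, row.beta)
        label = classify_two_doxh_on_graphene(
            desc, alpha_gra=(row.alpha_gra_1, row.alpha_gra_2)
        )
        assert label == row.type, row.tag


def test_classifier_edge_cases():
    assert classify_two_doxh_on_graphene(
        PairDescriptors(8.0, 5.0, 90.0)
    ) == "failure"
    # steep tilt vetoes otherwise-clean beta
    assert classify_two_doxh_on_graphene(
        PairDescriptors(8.0, 5.0, 1.0), alpha_gra=(45.0, 3.0)
    ) == "failure"
    # classification is a pure function of descriptors
    d = PairDescriptors(4.28, 4.5, 47.0)
    assert classify_two_doxh(d) == classify_two_doxh(d) == "A2"
    loose = ClassifierThresholds(overlap_low=10.0)
    assert classify_two_doxh(
        PairDescriptors(4.9, 2.4, 20.2), thresholds=loose
    ) == "A2"


def test_type_frequencies_counting():
    freq = type_frequencies(["A1", "A1", "A2", "failure"])
    assert freq == {"A1": 0.5, "A2": 0.25, "failure": 0.25}
    assert "A3" not in freq
    rng = np.random.default_rng(0)
    labels = list(rng.choice(["A1", "A2", "A3", "failure"], size=50))
    freq = type_frequencies(labels)
    assert sum(freq.values()) == pytest.approx(1.0)
    for k, v in freq.items():
        assert v == labels.count(k) / 50
    with pytest.raises(ValueError):
        type_frequencies([])


# -- tuning scans ----------------------------------------------------------

def test_scan_profile_consistency_and_argmin(ff, cc_pair):
    # converged-by-construction toy: single C at the analytic plane minimum
    dstar = (cc_pair.B / cc_pair.A) ** (1 / 6)
    atom = RigidMolecule([Atom("C1", "C", (0, 0, 0))], plane_anchors=None)
    spec = SystemSpec((atom,), plane=InfinitePlane(), forcefield=ff)
    poses = [Pose(0, 0, dstar, 0, 0)]
    grid = np.linspace(-0.5, 0.5, 21)
    prof = scan_profile(spec, poses, "translate-z", grid)
    assert prof.argmin_offset == pytest.approx(0.0, abs=1e-12)
    i0 = list(prof.offsets).index(0.0)
    assert prof.energies[i0] == pytest.approx(
        system_energy(spec, poses), rel=1e-12
    )
    # symmetric system: a lateral scan of a dimer at its minimum is even
    atom2 = RigidMolecule([Atom("C1", "C", (0, 0, 0))], plane_anchors=None)
    dimer = SystemSpec((atom2, atom2), plane=None, forcefield=ff)
    dposes = [Pose(0, 0, 0, 0, 0), Pose(cc_pair.sigma, 0, 0, 0, 0)]
    lateral = scan_profile(dimer, dposes, "translate-x", grid, mol_index=1)
    # moving along x from the minimum is not even, but the energy only
    # depends on |separation|, so a perpendicular scan would be; check the
    # translate-x profile has its minimum at 0 instead
    assert lateral.argmin_offset == pytest.approx(0.0, abs=1e-12)
    e = np.array(
        scan_profile(
            dimer,
            [Pose(0, 0, 0, 0, 0), Pose(0, 0, cc_pair.sigma, 0, 0)],
            "translate-x",
            grid,
            mol_index=1,
        ).energies
    )
    # distance = sqrt(sigma^2 + o^2) is even in the lateral offset o
    assert np.allclose(e, e[::-1], rtol=1e-9)


def test_scan_profile_validation(ff):
    atom = RigidMolecule([Atom("C1", "C", (0, 0, 0))], plane_anchors=None)
    spec = SystemSpec((atom,), plane=InfinitePlane(), forcefield=ff)
    poses = [Pose(0, 0, 3.4, 0, 0)]
    with pytest.raises(ValueError):
        scan_profile(spec, poses, "translate-z", [0.1, 0.2])
    with pytest.raises(ValueError):
        scan_profile(spec, poses, "twist", [0.0, 0.1])
    # grid points that dive through the plane are flagged invalid
    prof = scan_profile(spec, poses, "translate-z", [-3.4, 0.0, 0.2])
    assert prof.valid == (False, True, True)
    assert prof.argmin_offset == 0.0
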