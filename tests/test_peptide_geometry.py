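"""Peptide descriptors: COM depth, ellipse axes, orientation angle,
hydrophobic moment, entry-side normalization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from permeatrace import synthetic_data as sd
from permeatrace.membrane_frame import reference_series
from permeatrace.peptide_geometry import (DegenerateGeometryError,
                                          backbone_ellipse_axes,
                                          ellipse_atom_indices, entry_side,
                                          flip_about_x, fold_angle,
                                          hydrophobic_moment,
                                          normalize_entry_side,
                                          orientation_angle, peptide_com_z,
                                          peptide_normal)

from conftest import flat_ref, peptide_frame


# ---------------------------------------------------------------------------
# COM depth
# ---------------------------------------------------------------------------

def test_com_z_examples(peptide_roles):
    frame = peptide_frame(center=True)
    assert peptide_com_z(frame, peptide_roles, flat_ref()) == pytest.approx(0.0)
    frame5 = peptide_frame(center=True, com=(0, 0, 5.0))
    # 3 nm above headgroups at z_head_upper = 2 -> 5 nm above the center
    assert peptide_com_z(frame5, peptide_roles, flat_ref()) == pytest.approx(5.0)


def test_com_z_matches_weighted_mean_oracle(peptide_roles):
    rng = np.random.default_rng(1)
    frame = rng.normal(size=(50, 3))
    masses = rng.uniform(1, 12, 50)
    got = peptide_com_z(frame, peptide_roles, flat_ref(0.3), masses)
    idx = peptide_roles.peptide_atoms
    oracle = np.average(frame[idx, 2], weights=masses[idx]) - 0.3
    assert got == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# Ellipse axes
# ---------------------------------------------------------------------------

def test_planar_ellipse_axes(peptide_roles):
    """Points on a 0.7/0.5 ellipse in the xy-plane give major ∥ x and
    minor ∥ y up to sign."""
    frame = peptide_frame(center=True)
    phi = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    cas = ellipse_atom_indices(peptide_roles)
    frame[cas] = np.column_stack([0.7 * np.cos(phi), 0.5 * np.sin(phi),
                                  np.zeros(10)])
    major, minor = backbone_ellipse_axes(frame, peptide_roles)
    assert abs(abs(major[0]) - 1) < 1e-9
    assert abs(abs(minor[1]) - 1) < 1e-9
    assert abs(np.dot(major, minor)) < 1e-9


def test_axes_rotation_equivariance(peptide_roles):
    frame = peptide_frame(center=True)
    m0, n0 = backbone_ellipse_axes(frame, peptide_roles)
    rot = Rotation.from_rotvec([0.4, -1.1, 0.8])
    m1, n1 = backbone_ellipse_axes(rot.apply(frame), peptide_roles)
    assert np.allclose(m1, rot.apply(m0), atol=1e-9)
    assert np.allclose(n1, rot.apply(n0), atol=1e-9)


def test_noisy_ring_axes_close_to_construction(peptide_roles):
    rng = np.random.default_rng(5)
    frame = peptide_frame(center=True) + rng.normal(0, 0.05, (50, 3))
    major, minor = backbone_ellipse_axes(frame, peptide_roles)
    m0, n0 = backbone_ellipse_axes(peptide_frame(center=True), peptide_roles)
    ang = np.degrees(np.arccos(np.clip(abs(np.dot(major, m0)), -1, 1)))
    assert ang < 5.0


def test_collinear_backbone_is_degenerate(peptide_roles):
    frame = peptide_frame()
    cas = ellipse_atom_indices(peptide_roles)
    frame[cas] = np.column_stack([np.linspace(0, 1, 10),
                                  np.zeros(10), np.zeros(10)])
    with pytest.raises(DegenerateGeometryError):
        backbone_ellipse_axes(frame, peptide_roles)


# ---------------------------------------------------------------------------
# Orientation angle
# ---------------------------------------------------------------------------

def test_orientation_angle_flat_and_upright():
    """Ring in the membrane plane: θ = 0°; ring standing perpendicular to
    the membrane (the anchored pose): θ = 90°."""
    assert orientation_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)
    assert orientation_angle([0, 0, 1], [0, 1, 0]) == pytest.approx(90.0)


def test_orientation_angle_matches_arccos_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10_000):
        major = rng.normal(size=3)
        major /= np.linalg.norm(major)
        v = rng.normal(size=3)
        minor = v - np.dot(v, major) * major
        minor /= np.linalg.norm(minor)
        got = orientation_angle(major, minor)
        a = np.cross(major, minor)
        a /= np.linalg.norm(a)
        oracle = np.degrees(np.arctan2(np.hypot(a[0], a[1]), a[2]))
        assert got == pytest.approx(oracle, abs=1e-9)


def test_theta_fold_invariants():
    rng = np.random.default_rng(2)
    for _ in range(200):
        major = rng.normal(size=3)
        major /= np.linalg.norm(major)
        v = rng.normal(size=3)
        minor = v - v @ major * major
        minor /= np.linalg.norm(minor)
        t = orientation_angle(major, minor)
        t_flipped = orientation_angle(major, -minor)   # flips a⃗
        assert t_flipped == pytest.approx(180.0 - t, abs=1e-9)
        assert fold_angle(t) == pytest.approx(fold_angle(t_flipped), abs=1e-9)
        assert 0.0 <= fold_angle(t) <= 90.0


def test_parallel_axes_error():
    with pytest.raises(DegenerateGeometryError):
        peptide_normal(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]))


# ---------------------------------------------------------------------------
# Hydrophobic moment
# ---------------------------------------------------------------------------

def test_hydrophobic_moment_construction_and_oracle(peptide_roles):
    rng = np.random.default_rng(3)
    frame = rng.normal(size=(50, 3))
    pol = {"LEU": "apolar", "PHE": "apolar", "PRO": "apolar", "SER": "polar"}
    got = hydrophobic_moment(frame, peptide_roles, pol)
    apolar, polar = [], []
    for label in peptide_roles.residue_order:
        resname = label.rstrip("0123456789")
        atoms = (list(peptide_roles.peptide_sidechains[label])
                 + list(peptide_roles.backbone_atoms_by_residue[label].values()))
        (apolar if pol[resname] == "apolar" else polar).extend(atoms)
    oracle = frame[apolar].mean(0) - frame[polar].mean(0)
    assert np.allclose(got, oracle, atol=1e-12)


def test_hydrophobic_moment_single_class_warns(peptide_roles):
    frame = peptide_frame()
    with pytest.warns(UserWarning):
        v = hydrophobic_moment(frame, peptide_roles,
                               {r: "apolar" for r in set(sd.SEQUENCE)})
    assert np.allclose(v, 0.0)


# ---------------------------------------------------------------------------
# Entry-side normalization
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def entry_pair():
    spec_u = sd.scenario_anchor(seed=17, n_side=4)
    upper, _ = sd.generate_scenario(spec_u)
    spec_l = sd.scenario_anchor(seed=17, n_side=4)
    spec_l.entry_side = "lower"
    lower, _ = sd.generate_scenario(spec_l)
    return upper, lower


def test_upper_entry_unchanged(entry_pair):
    upper, _ = entry_pair
    assert entry_side(upper) == "upper"
    assert normalize_entry_side(upper) is upper


def test_lower_entry_normalized_to_upper(entry_pair):
    _, lower = entry_pair
    assert entry_side(lower) == "lower"
    fixed = normalize_entry_side(lower)
    assert entry_side(fixed) == "upper"


def test_flip_is_involution(entry_pair):
    upper, _ = entry_pair
    refs = reference_series(upper)
    twice = flip_about_x(flip_about_x(upper, refs))
    assert np.abs(twice.coords - upper.coords).max() < 1e-12


def test_flip_preserves_mirror_symmetric_descriptors(entry_pair):
    """|z_com| and the folded orientation angle are invariant under the
    entry-side flip."""
    upper, _ = entry_pair
    refs = reference_series(upper)
    flipped = flip_about_x(upper, refs)
    refs_f = reference_series(flipped)
    for k in (0, 30, 60):
        z0 = peptide_com_z(upper.coords[k], upper.roles, refs[k])
        z1 = peptide_com_z(flipped.coords[k], flipped.roles, refs_f[k])
        assert abs(z0) == pytest.approx(abs(z1), abs=1e-9)
        m0, n0 = backbone_ellipse_axes(upper.coords[k], upper.roles)
        m1, n1 = backbone_ellipse_axes(flipped.coords[k], flipped.roles)
        t0 = fold_angle(orientation_angle(m0, n0))
        t1 = fold_angle(orientation_angle(m1, n1))
        assert t0 == pytest.approx(t1, abs=1e-9)


def test_no_contact_trajectory_returned_unchanged():
    traj, _ = sd.generate_null(30, seed=23, n_side=4)
    assert entry_side(traj) is None
    assert normalize_entry_side(traj) is traj
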