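"""Conformational classification: RMSD, intramolecular hydrogen bonds,
register shift, lock state."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from permeatrace import synthetic_data as sd
from permeatrace.config import AnalysisConfig, HBondCriterion
from permeatrace.conformation import (classify_conformation,
                                      detect_register_shift, intra_hbonds,
                                      lock_state, pairs_to_positions,
                                      rmsd_to_closed,
                                      sidechain_plane_projections,
                                      superposed_rmsd)

from conftest import flat_ref, peptide_frame


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def test_rmsd_identity_and_rigid_invariance(peptide_roles):
    ref = sd.closed_reference_backbone()
    frame = peptide_frame("closed")
    assert rmsd_to_closed(frame, ref, peptide_roles) == pytest.approx(0.0,
                                                                      abs=1e-12)
    rot = Rotation.from_rotvec([0.3, 1.2, -0.7])
    moved = rot.apply(frame) + np.array([1.0, -2.0, 0.5])
    assert rmsd_to_closed(moved, ref, peptide_roles) == pytest.approx(0.0,
                                                                      abs=1e-9)


def test_rmsd_matches_independent_kabsch_oracle():
    """Random coordinate pairs against MDAnalysis' superposition RMSD."""
    from MDAnalysis.analysis.rms import rmsd as mda_rmsd

    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(4, 20))
        P = rng.normal(size=(n, 3))
        Q = P + rng.normal(0, 0.3, (n, 3))
        got = superposed_rmsd(P, Q)
        oracle = mda_rmsd(P, Q, center=True, superposition=True)
        assert got == pytest.approx(oracle, abs=1e-9)


def test_rmsd_zero_iff_congruent():
    rng = np.random.default_rng(9)
    P = rng.normal(size=(10, 3))
    assert superposed_rmsd(P, P) == pytest.approx(0.0, abs=1e-12)
    assert superposed_rmsd(P, P + rng.normal(0, 0.2, (10, 3))) > 1e-3


def test_rmsd_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        superposed_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


# ---------------------------------------------------------------------------
# Intramolecular hydrogen bonds
# ---------------------------------------------------------------------------

def test_closed_fixture_has_four_canonical_bonds(peptide_roles):
    """The closed conformation carries exactly the four cross-ring
    backbone hydrogen bonds."""
    pairs = intra_hbonds(peptide_frame("closed"), peptide_roles)
    pos = set(pairs_to_positions(pairs, peptide_roles.residue_order))
    assert pos == set(sd.CANONICAL_PAIRS)


def test_open_ring_has_no_bonds(peptide_roles):
    assert intra_hbonds(peptide_frame("open"), peptide_roles) == []


def test_hbonds_invariant_under_rigid_motion(peptide_roles):
    frame = peptide_frame("half_closed")
    rot = Rotation.from_rotvec([1.0, 0.2, 0.4])
    a = intra_hbonds(frame, peptide_roles)
    b = intra_hbonds(rot.apply(frame) + 3.0, peptide_roles)
    assert sorted(a) == sorted(b)


def test_hbonds_match_bruteforce_oracle(peptide_roles):
    """Randomly perturbed rings against an exhaustive pair scan that
    reimplements the distance + angle criterion independently."""
    crit = HBondCriterion()
    order = peptide_roles.residue_order
    rng = np.random.default_rng(13)
    n = len(order)
    for trial in range(100):
        conf = ("closed", "open", "half_closed")[trial % 3]
        frame = peptide_frame(conf) + rng.normal(0, 0.04, (50, 3))
        got = sorted(intra_hbonds(frame, peptide_roles, crit))
        oracle = []
        for d in order:
            for a in order:
                pd = order.index(d)
                pa = order.index(a)
                sep = abs(pd - pa)
                if min(sep, n - sep) <= 1:
                    continue
                N = frame[peptide_roles.backbone_atoms_by_residue[d]["N"]]
                H = frame[peptide_roles.backbone_atoms_by_residue[d]["H"]]
                O = frame[peptide_roles.backbone_atoms_by_residue[a]["O"]]
                if np.linalg.norm(O - N) > crit.d_max:
                    continue
                v1, v2 = N - H, O - H
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= crit.angle_min:
                    oracle.append((d, a))
        assert got == sorted(oracle)


def test_heavy_atom_fallback_without_hydrogens(peptide_roles):
    frame = peptide_frame("closed")
    roles = peptide_roles
    stripped = {lab: {k: v for k, v in atoms.items() if k != "H"}
                for lab, atoms in roles.backbone_atoms_by_residue.items()}
    import dataclasses
    roles2 = dataclasses.replace(roles, backbone_atoms_by_residue=stripped)
    with pytest.warns(UserWarning, match="heavy-atom"):
        pairs = intra_hbonds(frame, roles2)
    assert set(pairs_to_positions(pairs, roles2.residue_order)) >= set(
        sd.CANONICAL_PAIRS)


# ---------------------------------------------------------------------------
# Classification and register shift
# ---------------------------------------------------------------------------

def test_classification_examples():
    assert classify_conformation(0.05, 4, False) == "closed"
    assert classify_conformation(0.35, 0, False) == "open"
    assert classify_conformation(0.35, 2, False) == "half_closed"
    assert classify_conformation(0.35, 4, True) == "open"


def test_classification_flips_exactly_at_threshold():
    """The closed/open boundary sits exactly at RMSD = 0.2 nm."""
    thr = AnalysisConfig().rmsd_closed_threshold
    assert classify_conformation(thr, 0, False) == "closed"
    assert classify_conformation(np.nextafter(thr, 1.0), 0, False) == "open"
    for r in np.linspace(0.0, 0.4, 81):
        label = classify_conformation(float(r), 0, False)
        assert label == ("closed" if r <= thr else "open")


def test_register_shift_examples():
    canon = sd.CANONICAL_PAIRS
    assert detect_register_shift(canon, canon, 10) is False
    shifted = [((d % 10) + 1, (a % 10) + 1) for d, a in canon]
    assert detect_register_shift(shifted, canon, 10) is True
    assert detect_register_shift([], canon, 10) is False
    # partial shifted subset still reads as shifted
    assert detect_register_shift(shifted[:2], canon, 10) is True


def test_register_shift_matches_offset_oracle():
    rng = np.random.default_rng(17)
    canon = list(sd.CANONICAL_PAIRS)
    n = 10
    for _ in range(300):
        k = int(rng.integers(0, n))
        size = int(rng.integers(1, 5))
        chosen = [canon[i] for i in rng.choice(4, size=size, replace=False)]
        observed = [((d - 1 + k) % n + 1, (a - 1 + k) % n + 1)
                    for d, a in chosen]
        got = detect_register_shift(observed, canon, n)
        # oracle: exhaustively find all shifts containing the observation
        shifts = [s for s in range(n)
                  if set(observed) <= {((d - 1 + s) % n + 1, (a - 1 + s) % n + 1)
                                       for d, a in canon}]
        oracle = 0 not in shifts and bool({1, n - 1} & set(shifts))
        assert got == oracle


def test_register_shifted_template_classifies_open(peptide_roles):
    frame = peptide_frame("register_shifted")
    pairs = intra_hbonds(frame, peptide_roles)
    pos = pairs_to_positions(pairs, peptide_roles.residue_order)
    assert detect_register_shift(pos, sd.CANONICAL_PAIRS, 10) is True
    rmsd = rmsd_to_closed(frame, sd.closed_reference_backbone(), peptide_roles)
    assert classify_conformation(rmsd, len(pairs), True) == "open"


# ---------------------------------------------------------------------------
# Lock state
# ---------------------------------------------------------------------------

def test_lock_state_constructions(peptide_roles):
    """Both turn side chains toward the aqueous phase: unlocked; the
    phenylalanine rotated toward the membrane center: locked."""
    ref = flat_ref()
    up = peptide_frame("closed", com=(0, 0, 1.7), s_lock=+1.0)
    assert lock_state(up, peptide_roles, ["PHE5"], ref) == "unlocked"
    down = peptide_frame("closed", com=(0, 0, 1.7), s_lock=-1.0)
    assert lock_state(down, peptide_roles, ["PHE5"], ref) == "locked"
    assert lock_state(up, peptide_roles, [], ref) == "n/a"


def test_lock_flips_exactly_at_zero_projection(peptide_roles):
    ref = flat_ref()
    for s in (-0.2, -1e-6, 1e-6, 0.2):
        frame = peptide_frame("closed", com=(0, 0, 1.7), s_lock=s)
        proj = sidechain_plane_projections(frame, peptide_roles, ["PHE5"],
                                           ref)["PHE5"]
        state = lock_state(frame, peptide_roles, ["PHE5"], ref)
        assert (proj < 0) == (state == "locked")


def test_lock_respects_lower_leaflet_aqueous_direction(peptide_roles):
    """In the lower leaflet the aqueous phase is below: the same local
    geometry mirrored in z keeps its lock state."""
    ref = flat_ref()
    upper = peptide_frame("closed", com=(0, 0, 1.7), s_lock=-1.0)
    lower = upper.copy()
    lower[:, 2] *= -1.0
    assert lock_state(upper, peptide_roles, ["PHE5"], ref) == "locked"
    assert lock_state(lower, peptide_roles, ["PHE5"], ref) == "locked"
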