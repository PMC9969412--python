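"""Per-frame peptide descriptors.

The peptide normal a⃗ is the normalized cross product of the major and
minor axes of the backbone ellipse; the orientation angle θ is the angle
between a⃗ and the membrane normal b⃗ (the z-axis),

    θ = arccos( a⃗·b⃗ / (|a⃗||b⃗|) ),

reported raw in [0, 180]° and folded to [0, 90]° for parallel-vs-
perpendicular plots.  Axis signs follow a body-fixed convention (reference
residues have positive projections) so that 180° rolls about the major
axis — the A/B discriminator — are trackable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .membrane_frame import MembraneFrameRef, reference_series
from .trajio import AtomRoleMap, Trajectory


class DegenerateGeometryError(ValueError):
    """Backbone atoms are collinear (no ellipse plane defined)."""


@dataclass
class OrientationState:
    """Orientation descriptors of one frame."""

    a_vec: np.ndarray          # peptide normal (unit)
    b_vec: np.ndarray          # membrane normal (unit, z-axis)
    theta: float               # deg, raw in [0, 180]
    theta_folded: float        # deg, folded to [0, 90]
    major_axis: np.ndarray
    minor_axis: np.ndarray
    z_com: float               # nm, signed, relative to bilayer center
    hydrophobic_moment: Optional[np.ndarray] = None


def peptide_com_z(frame: np.ndarray, roles: AtomRoleMap,
                  ref: MembraneFrameRef,
                  masses: Optional[np.ndarray] = None) -> float:
    """Mass-weighted peptide COM z relative to the bilayer center."""
    idx = roles.peptide_atoms
    if len(idx) == 0:
        raise ValueError("empty peptide selection")
    w = np.ones(len(idx)) if masses is None else np.asarray(masses)[idx]
    z = float(np.average(frame[idx, 2], weights=w))
    return z - ref.z_center


def ellipse_atom_indices(roles: AtomRoleMap, definition: str = "ca") -> np.ndarray:
    """Backbone atoms used for the ellipse fit: Cα-equivalent beads by
    default, or all backbone heavy atoms with ``definition="all"``."""
    if definition == "all":
        return roles.peptide_backbone
    idx = []
    for label in roles.residue_order:
        atoms = roles.backbone_atoms_by_residue.get(label, {})
        if "CA" in atoms:
            idx.append(atoms["CA"])
    if not idx:
        return roles.peptide_backbone
    return np.array(idx, dtype=int)


def _reference_positions(frame: np.ndarray, roles: AtomRoleMap
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """CA positions of the two sign-reference residues (1 and ~n/4)."""
    order = roles.residue_order
    if len(order) < 3:
        raise DegenerateGeometryError("need at least 3 residues")
    r1 = roles.backbone_atoms_by_residue[order[0]].get("CA")
    rq = roles.backbone_atoms_by_residue[order[max(1, len(order) // 4)]].get("CA")
    if r1 is None or rq is None:
        raise DegenerateGeometryError("reference residues lack CA beads")
    return frame[r1], frame[rq]


def backbone_ellipse_axes(frame: np.ndarray, roles: AtomRoleMap,
                          definition: str = "ca") -> Tuple[np.ndarray, np.ndarray]:
    """Principal axes of the backbone atom cloud.

    Second-moment (PCA) decomposition: the major axis is the direction of
    largest spread, the minor axis the second.  Signs are fixed so that
    residue 1 projects positively on the major axis and the quarter-ring
    residue projects positively on the minor axis, giving body-fixed axes.
    """
    idx = ellipse_atom_indices(roles, definition)
    if len(idx) < 3:
        raise DegenerateGeometryError("need >= 3 backbone atoms")
    pts = frame[idx]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order
    major = evecs[:, 2]
    minor = evecs[:, 1]
    if evals[1] < 1e-12 * max(evals[2], 1e-30):
        raise DegenerateGeometryError("backbone atoms are collinear")
    p1, pq = _reference_positions(frame, roles)
    if np.dot(p1 - centroid, major) < 0:
        major = -major
    if np.dot(pq - centroid, minor) < 0:
        minor = -minor
    return major, minor


def peptide_normal(major_axis: np.ndarray, minor_axis: np.ndarray) -> np.ndarray:
    """a⃗ = normalized cross product of the major and minor axes."""
    a = np.cross(major_axis, minor_axis)
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise DegenerateGeometryError("major and minor axes are parallel")
    return a / norm


def orientation_angle(major_axis: np.ndarray, minor_axis: np.ndarray,
                      b_vec: Sequence[float] = (0.0, 0.0, 1.0)) -> float:
    """θ in degrees in [0, 180] between the peptide and membrane normals."""
    a = peptide_normal(major_axis, minor_axis)
    b = np.asarray(b_vec, dtype=float)
    b = b / np.linalg.norm(b)
    cosang = np.clip(np.dot(a, b), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def fold_angle(theta: float) -> float:
    """Fold θ from [0, 180] to [0, 90] (parallel vs perpendicular)."""
    return float(min(theta, 180.0 - theta))


def hydrophobic_moment(frame: np.ndarray, roles: AtomRoleMap,
                       polarity_map: Dict[str, str]) -> np.ndarray:
    """Vector from the polar-residue COM to the apolar-residue COM.

    ``polarity_map`` maps residue labels or residue names to
    ``"polar"``/``"apolar"`` and must cover every residue.  If all residues
    fall in one class the zero vector is returned (with a warning).
    """
    import warnings

    polar_idx, apolar_idx = [], []
    for label in roles.residue_order:
        resname = "".join(c for c in label if not c.isdigit())
        cls = polarity_map.get(label, polarity_map.get(resname))
        if cls is None:
            raise ValueError(f"polarity map does not cover residue {label}")
        atoms = list(roles.peptide_sidechains.get(label, []))
        bb = roles.backbone_atoms_by_residue.get(label, {})
        atoms += list(bb.values())
        (apolar_idx if cls == "apolar" else polar_idx).extend(atoms)
    if not polar_idx or not apolar_idx:
        warnings.warn("all residues in one polarity class; hydrophobic "
                      "moment is the zero vector")
        return np.zeros(3)
    return frame[apolar_idx].mean(axis=0) - frame[polar_idx].mean(axis=0)


# ---------------------------------------------------------------------------
# Entry-side normalization
# ---------------------------------------------------------------------------

def first_contact_frame(traj: Trajectory, refs=None) -> Optional[int]:
    """First frame with any peptide atom inside the headgroup slab."""
    if refs is None:
        refs = reference_series(traj)
    idx = traj.roles.peptide_atoms
    for k, ref in enumerate(refs):
        z = traj.coords[k][idx, 2]
        if np.any((z < ref.z_head_upper) & (z > ref.z_head_lower)):
            return k
    return None


def entry_side(traj: Trajectory, refs=None) -> Optional[str]:
    """Which leaflet the peptide first contacts (``None`` if no contact)."""
    if refs is None:
        refs = reference_series(traj)
    k = first_contact_frame(traj, refs)
    if k is None:
        return None
    z_com = peptide_com_z(traj.coords[k], traj.roles, refs[k], traj.masses)
    return "upper" if z_com >= 0 else "lower"


def flip_about_x(traj: Trajectory, refs=None) -> Trajectory:
    """180° rotation of the box around the x-axis.

    Implemented as a mirror of y about the box midline and of z about the
    per-frame bilayer center, so that the bilayer stays in place and the
    transform is an exact involution.
    """
    if refs is None:
        refs = reference_series(traj)
    coords = traj.coords.copy()
    for k in range(traj.n_frames):
        cy = 0.5 * traj.box[k][1]
        cz = refs[k].z_center
        coords[k, :, 1] = 2.0 * cy - coords[k, :, 1]
        coords[k, :, 2] = 2.0 * cz - coords[k, :, 2]
    return Trajectory(coords=coords, box=traj.box.copy(),
                      times=traj.times.copy(), roles=traj.roles,
                      masses=traj.masses, atom_names=traj.atom_names,
                      resnames=traj.resnames, resids=traj.resids)


def normalize_entry_side(traj: Trajectory, refs=None) -> Trajectory:
    """Rotate the box 180° about x if the peptide entered at the lower
    leaflet, so all trajectories enter at the upper leaflet.  Trajectories
    without membrane contact are returned unchanged."""
    if refs is None:
        refs = reference_series(traj)
    side = entry_side(traj, refs)
    if side != "lower":
        return traj
    return flip_about_x(traj, refs)
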