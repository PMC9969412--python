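"""Conformational classification of the cyclic peptide.

A frame is *closed* when the backbone RMSD to the closed reference is at
most 0.2 nm (the closed state carries four intramolecular backbone
hydrogen bonds shielding its polar groups); *half-closed* when the RMSD is
above the threshold but a partial subset of the canonical hydrogen-bond
pattern is formed with resolved register; otherwise *open*.  A *register
shift* is a hydrogen-bond pattern displaced by one residue position from
the canonical closed pattern.  The *lock* descriptor reports whether a
bulky turn residue (phenylalanine class) points toward the membrane
center, sterically preventing ring closure.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig, HBondCriterion
from .membrane_frame import MembraneFrameRef
from .peptide_geometry import (backbone_ellipse_axes, ellipse_atom_indices,
                               peptide_com_z, peptide_normal)
from .trajio import AtomRoleMap


@dataclass
class ConformationState:
    """Per-frame conformational descriptors."""

    rmsd_closed: float
    n_intra_hbonds: int
    hbond_pairs: List[Tuple[int, int]]        # donor, acceptor positions (1-based)
    label: str                                 # closed | half_closed | open
    register_shift: bool
    lock_state: str                            # locked | unlocked | n/a


# ---------------------------------------------------------------------------
# RMSD (Kabsch superposition)
# ---------------------------------------------------------------------------

def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal rigid
    superposition (Kabsch, via SVD), in the units of the inputs."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"atom mismatch: {P.shape} vs {Q.shape}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def rmsd_to_closed(frame: np.ndarray, reference: np.ndarray,
                   roles: AtomRoleMap, definition: str = "ca") -> float:
    """Backbone RMSD of a frame to the closed-conformation reference.

    ``reference`` is either a full-system coordinate array (the backbone
    subset is extracted with the same atom correspondence) or an array
    already restricted to the backbone atoms in ring order.
    """
    idx = ellipse_atom_indices(roles, definition)
    P = frame[idx]
    reference = np.asarray(reference, dtype=float)
    Q = reference[idx] if reference.shape[0] > len(idx) else reference
    return superposed_rmsd(P, Q)


# ---------------------------------------------------------------------------
# Intramolecular hydrogen bonds
# ---------------------------------------------------------------------------

def _position_of(label: str, order: Sequence[str]) -> int:
    return list(order).index(label) + 1


def hbond_geometry_ok(d_pos: np.ndarray, h_pos: Optional[np.ndarray],
                      a_pos: np.ndarray, criterion: HBondCriterion) -> bool:
    """Apply the geometric criterion to one donor/H/acceptor triple."""
    dist = float(np.linalg.norm(a_pos - d_pos))
    if dist > criterion.d_max:
        return False
    if h_pos is None:
        return True
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return False
    ang = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1)))
    return ang >= criterion.angle_min


def intra_hbonds(frame: np.ndarray, roles: AtomRoleMap,
                 criterion: Optional[HBondCriterion] = None,
                 ) -> List[Tuple[str, str]]:
    """Backbone N-H -> carbonyl-O hydrogen bonds within the peptide ring.

    Pairs with |donor - acceptor| ring distance <= 1 are excluded.  If a
    donor has no hydrogen position the heavy-atom distance criterion is
    used alone (with a warning, once).
    """
    criterion = criterion or HBondCriterion()
    order = roles.residue_order
    n = len(order)
    warned = False
    out: List[Tuple[str, str]] = []
    for dlab in order:
        datoms = roles.backbone_atoms_by_residue.get(dlab, {})
        if "N" not in datoms:
            continue
        d_pos = frame[datoms["N"]]
        h_pos = frame[datoms["H"]] if "H" in datoms else None
        if h_pos is None and not warned:
            warnings.warn(f"no H position for donor {dlab}; falling back to "
                          "heavy-atom distance criterion")
            warned = True
        dpos_ring = _position_of(dlab, order)
        for alab in order:
            aatoms = roles.backbone_atoms_by_residue.get(alab, {})
            if "O" not in aatoms:
                continue
            apos_ring = _position_of(alab, order)
            sep = abs(dpos_ring - apos_ring)
            sep = min(sep, n - sep)              # ring adjacency
            if sep <= 1:
                continue
            if hbond_geometry_ok(d_pos, h_pos, frame[aatoms["O"]], criterion):
                out.append((dlab, alab))
    return out


def pairs_to_positions(pairs: Iterable[Tuple[str, str]],
                       order: Sequence[str]) -> List[Tuple[int, int]]:
    return [(_position_of(d, order), _position_of(a, order)) for d, a in pairs]


# ---------------------------------------------------------------------------
# Register shift and classification
# ---------------------------------------------------------------------------

def _shifted(pattern: Iterable[Tuple[int, int]], k: int, n: int) -> set:
    return {((d - 1 + k) % n + 1, (a - 1 + k) % n + 1) for d, a in pattern}


def detect_register_shift(observed: Iterable[Tuple[int, int]],
                          canonical: Iterable[Tuple[int, int]],
                          n_residues: int) -> bool:
    """True iff the observed donor->acceptor pairs equal (a nonempty subset
    of) the canonical pattern shifted by one ring position."""
    obs = set(tuple(p) for p in observed)
    if not obs:
        return False
    canonical = list(canonical)
    if obs <= _shifted(canonical, 0, n_residues):
        return False
    return (obs <= _shifted(canonical, 1, n_residues)
            or obs <= _shifted(canonical, -1, n_residues))


def classify_conformation(rmsd_closed: float, n_intra_hbonds: int,
                          register_shift: bool,
                          config: Optional[AnalysisConfig] = None) -> str:
    """closed / half_closed / open from RMSD, H-bond count and register."""
    config = config or AnalysisConfig()
    if not np.isfinite(rmsd_closed):
        raise ValueError("rmsd must be finite")
    if rmsd_closed <= config.rmsd_closed_threshold:
        return "closed"
    n_full = len(config.canonical_hbonds)
    if 1 <= n_intra_hbonds < n_full and not register_shift:
        return "half_closed"
    return "open"


# ---------------------------------------------------------------------------
# Lock descriptor
# ---------------------------------------------------------------------------

def aqueous_normal(frame: np.ndarray, roles: AtomRoleMap,
                   ref: MembraneFrameRef, masses=None,
                   definition: str = "ca") -> np.ndarray:
    """Peptide-plane normal oriented toward the aqueous phase.

    The aqueous side is +z for a peptide in the upper leaflet and -z in
    the lower leaflet (sign of the COM z relative to the bilayer center).
    """
    major, minor = backbone_ellipse_axes(frame, roles, definition)
    a = peptide_normal(major, minor)
    z_com = peptide_com_z(frame, roles, ref, masses)
    aq_sign = 1.0 if z_com >= 0 else -1.0
    if a[2] * aq_sign < 0:
        a = -a
    return a


def sidechain_plane_projections(frame: np.ndarray, roles: AtomRoleMap,
                                residues: Sequence[str],
                                ref: MembraneFrameRef, masses=None,
                                definition: str = "ca") -> Dict[str, float]:
    """Signed height of each residue's side-chain centroid above the ring
    plane, along the aqueous-pointing normal (positive = aqueous side)."""
    n_aq = aqueous_normal(frame, roles, ref, masses, definition)
    idx = ellipse_atom_indices(roles, definition)
    centroid = frame[idx].mean(axis=0)
    out: Dict[str, float] = {}
    for label in residues:
        sc = roles.peptide_sidechains.get(label)
        if sc is None or len(sc) == 0:
            raise ValueError(f"residue {label} has no side-chain atoms")
        out[label] = float(np.dot(frame[sc].mean(axis=0) - centroid, n_aq))
    return out


def lock_state(frame: np.ndarray, roles: AtomRoleMap,
               lock_residues: Sequence[str], ref: MembraneFrameRef,
               masses=None, definition: str = "ca") -> str:
    """locked / unlocked / n/a for the configured bulky turn residues.

    Unlocked iff every configured residue projects toward the aqueous
    side; locked iff at least one projects toward the membrane center.
    """
    if not lock_residues:
        return "n/a"
    proj = sidechain_plane_projections(frame, roles, lock_residues, ref,
                                       masses, definition)
    return "locked" if min(proj.values()) < 0 else "unlocked"
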