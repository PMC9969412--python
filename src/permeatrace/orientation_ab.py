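"""Orientation A/B assignment, rotation and flip detection, occupancy.

In the membrane the peptide lies nearly parallel to the membrane plane in
one of two poses related by a ~180° roll about its major axis.  The
discriminator is the direction of the reporter (proline-class) turn
residues: toward the membrane middle in orientation A, toward the aqueous
phase in orientation B.  For a peptide in the lower leaflet the aqueous
direction flips sign, which the reporter projection handles by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .conformation import sidechain_plane_projections
from .membrane_frame import MembraneFrameRef
from .peptide_geometry import fold_angle
from .trajio import AtomRoleMap


@dataclass
class OrientationLabel:
    """Per-frame A/B assignment."""

    label: str                   # "A" | "B" | "none"
    reporter_projection: float   # signed, positive toward the aqueous phase
    in_membrane: bool


def classify_orientation(frame: np.ndarray, roles: AtomRoleMap,
                         ref: MembraneFrameRef, theta_folded: float,
                         reporter_residues: Sequence[str],
                         config: Optional[AnalysisConfig] = None,
                         masses=None) -> OrientationLabel:
    """Assign one frame to orientation A, B or none.

    ``none`` when the peptide COM is outside the membrane (above the upper
    headgroup surface / below the lower one) or the ring is not parallel
    to the membrane plane (folded θ above the parallel threshold).
    Otherwise A when the reporter side chains point toward the membrane
    center, B toward the aqueous phase.
    """
    config = config or AnalysisConfig()
    if not reporter_residues:
        raise ValueError("no reporter residues configured")
    from .peptide_geometry import peptide_com_z

    z_com = peptide_com_z(frame, roles, ref, masses)
    in_mem = ((ref.z_head_lower - ref.z_center) < z_com
              < (ref.z_head_upper - ref.z_center))
    proj = sidechain_plane_projections(frame, roles, reporter_residues, ref,
                                       masses, config.backbone_definition)
    mean_proj = float(np.mean(list(proj.values())))
    if not in_mem or theta_folded > config.parallel_max_theta:
        return OrientationLabel("none", mean_proj, in_mem)
    label = "B" if mean_proj >= 0 else "A"
    return OrientationLabel(label, mean_proj, in_mem)


# ---------------------------------------------------------------------------
# Rotation events
# ---------------------------------------------------------------------------

def run_length_encode(labels: Sequence[str]) -> List[Tuple[str, int, int]]:
    """(label, start, end_inclusive) runs of a label series."""
    runs: List[Tuple[str, int, int]] = []
    if not len(labels):
        return runs
    start = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    runs.append((labels[start], start, len(labels) - 1))
    return runs


def detect_rotation_events(labels: Sequence[str], dwell: int,
                           times: Optional[np.ndarray] = None,
                           z_com: Optional[np.ndarray] = None) -> list:
    """A↔B rotation events: persistent label changes (both flanks with at
    least ``dwell`` frames of the respective orientation).

    When ``z_com`` is given, label changes across a leaflet crossing are
    not rotations (the aqueous-relative label flips with the leaflet) and
    are skipped.
    """
    from .events import EventRecord

    runs = [(lab, s, e) for lab, s, e in run_length_encode(list(labels))
            if lab in ("A", "B") and (e - s + 1) >= dwell]
    events = []
    for (l0, _, e0), (l1, s1, _) in zip(runs[:-1], runs[1:]):
        if z_com is not None and (z_com[e0] >= 0) != (z_com[s1] >= 0):
            continue
        if l0 != l1:
            t = float(times[s1]) if times is not None else float(s1)
            events.append(EventRecord(
                type="rotation_AB", start_frame=s1, end_frame=s1,
                start_time_ps=t, end_time_ps=t, residues=[],
                attributes={"from": l0, "to": l1}))
    return events


# ---------------------------------------------------------------------------
# Flip detection
# ---------------------------------------------------------------------------

def cumulative_roll(majors: np.ndarray, minors: np.ndarray) -> np.ndarray:
    """Cumulative signed rotation (deg) about the instantaneous major axis.

    Per step, the minor axis of the next frame is projected into the plane
    perpendicular to the current major axis and the signed angle from the
    current minor axis is accumulated.
    """
    majors = np.asarray(majors, dtype=float)
    minors = np.asarray(minors, dtype=float)
    n = len(majors)
    roll = np.zeros(n)
    for k in range(1, n):
        m0 = majors[k - 1]
        v0 = minors[k - 1]
        v1 = minors[k] - np.dot(minors[k], m0) * m0
        nv = np.linalg.norm(v1)
        if nv < 1e-12:
            roll[k] = roll[k - 1]
            continue
        v1 = v1 / nv
        ang = np.degrees(np.arctan2(np.dot(np.cross(v0, v1), m0),
                                    np.clip(np.dot(v0, v1), -1, 1)))
        roll[k] = roll[k - 1] + ang
    return roll


def detect_flip(majors: np.ndarray, minors: np.ndarray,
                labels: Sequence[str], interval: Tuple[int, int],
                config: Optional[AnalysisConfig] = None
                ) -> Tuple[bool, np.ndarray]:
    """Whether a leaflet-crossing interval is accompanied by a ~180° roll
    about the major axis ending in orientation B in the new leaflet.

    Returns the flip flag and the cumulative roll-angle series over the
    interval.
    """
    config = config or AnalysisConfig()
    s, e = interval
    roll = cumulative_roll(majors[s:e + 1], minors[s:e + 1])
    net = abs(roll[-1]) % 360.0 if len(roll) else 0.0
    rotated = abs(net - 180.0) <= config.flip_tolerance_deg
    post = "none"
    for lab in list(labels)[e:]:
        if lab in ("A", "B"):
            post = lab
            break
    return bool(rotated and post == "B"), roll


# ---------------------------------------------------------------------------
# Occupancy statistics
# ---------------------------------------------------------------------------

def orientation_fractions(labels: Sequence[str],
                          equilibration_cut: int = 0) -> Dict[str, float]:
    """Percent of labelled frames (after the cut) in orientation A and B.

    ``none`` frames are excluded; the two percentages sum to exactly 100.
    """
    labs = list(labels)[equilibration_cut:]
    n_a = sum(1 for l in labs if l == "A")
    n_b = sum(1 for l in labs if l == "B")
    if n_a + n_b == 0:
        raise ValueError("no A/B-labelled frames after the equilibration cut")
    frac_a = 100.0 * n_a / (n_a + n_b)
    return {"A": frac_a, "B": 100.0 - frac_a}


def occupancy_heatmap(z_series: np.ndarray, theta_series: np.ndarray,
                      bins: Tuple[int, int] = (40, 36),
                      z_range: Optional[Tuple[float, float]] = None,
                      theta_range: Tuple[float, float] = (0.0, 90.0),
                      density: bool = False):
    """2-D histogram of (distance to bilayer center, folded θ).

    Counts, not free energies: the underlying ensembles are not at
    equilibrium, so the densities are reported as plain occupancies.
    Returns (hist, z_edges, theta_edges).
    """
    z = np.abs(np.asarray(z_series, dtype=float))
    theta = np.array([fold_angle(t) for t in np.asarray(theta_series, float)])
    if z_range is None:
        z_range = (0.0, max(float(z.max()), 1e-9))
    hist, z_edges, t_edges = np.histogram2d(
        z, theta, bins=bins, range=[z_range, theta_range], density=density)
    return hist, z_edges, t_edges
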