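"""End-to-end analysis orchestration.

``analyze_trajectory`` runs the full descriptor/classifier/detector stack
on one trajectory: membrane reference geometry, entry-side normalization,
per-frame peptide descriptors (depth, orientation angle, RMSD to the
closed reference, intramolecular hydrogen bonds, conformation, lock,
orientation A/B), the four event detectors, occupancy statistics, and the
assembled timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import conformation as conf_mod
from . import events as ev_mod
from . import membrane_frame as mf
from . import orientation_ab as ab
from . import peptide_geometry as pg
from .config import AnalysisConfig
from .trajio import Trajectory


@dataclass
class AnalysisResult:
    descriptors: pd.DataFrame
    refs: List[mf.MembraneFrameRef]
    events: List[ev_mod.EventRecord]
    summary: Dict
    fractions: Optional[Dict[str, float]]
    heatmap: Tuple[np.ndarray, np.ndarray, np.ndarray]
    majors: np.ndarray = field(repr=False, default=None)
    minors: np.ndarray = field(repr=False, default=None)


def compute_descriptors(traj: Trajectory,
                        refs: List[mf.MembraneFrameRef],
                        reference_closed: Optional[np.ndarray] = None,
                        config: Optional[AnalysisConfig] = None
                        ) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-frame descriptor table plus the body-fixed axis series."""
    config = config or AnalysisConfig()
    if reference_closed is None:
        from .synthetic_data import closed_reference_backbone
        reference_closed = closed_reference_backbone()
    n = traj.n_frames
    roles = traj.roles
    order = roles.residue_order
    rows = []
    majors = np.empty((n, 3))
    minors = np.empty((n, 3))
    for k in range(n):
        frame = traj.coords[k]
        ref = refs[k]
        major, minor = pg.backbone_ellipse_axes(frame, roles,
                                                config.backbone_definition)
        majors[k], minors[k] = major, minor
        theta = pg.orientation_angle(major, minor, ref.normal)
        z_com = pg.peptide_com_z(frame, roles, ref, traj.masses)
        rmsd = conf_mod.rmsd_to_closed(frame, reference_closed, roles,
                                       config.backbone_definition)
        pairs = conf_mod.intra_hbonds(frame, roles, config.hbond)
        pos_pairs = conf_mod.pairs_to_positions(pairs, order)
        reg = conf_mod.detect_register_shift(pos_pairs,
                                             config.canonical_hbonds,
                                             len(order))
        label = conf_mod.classify_conformation(rmsd, len(pairs), reg, config)
        ori = ab.classify_orientation(frame, roles, ref, pg.fold_angle(theta),
                                      config.reporter_residues, config,
                                      traj.masses)
        # the lock descriptor is membrane-referenced (toward center vs
        # aqueous): meaningful only while the ring lies parallel inside
        # the membrane, like the A/B label
        if ori.in_membrane and pg.fold_angle(theta) <= config.parallel_max_theta:
            lock = conf_mod.lock_state(frame, roles, config.lock_residues,
                                       ref, traj.masses,
                                       config.backbone_definition)
        else:
            lock = "n/a"
        rows.append({
            "frame": k, "time_ps": traj.times[k], "z_com": z_com,
            "theta_deg": theta, "theta_folded": pg.fold_angle(theta),
            "rmsd_closed": rmsd, "n_intra_hbonds": len(pairs),
            "register_shift": reg, "conformation": label,
            "lock_state": lock, "orientation": ori.label,
            "reporter_projection": ori.reporter_projection,
            "in_membrane": ori.in_membrane,
        })
    return pd.DataFrame(rows), majors, minors


def analyze_trajectory(traj: Trajectory,
                       config: Optional[AnalysisConfig] = None,
                       reference_closed: Optional[np.ndarray] = None,
                       normalize: bool = True) -> AnalysisResult:
    """Full pipeline on one trajectory (entry-side normalized by default)."""
    config = config or AnalysisConfig()
    refs = mf.reference_series(traj, config.midplane_hysteresis,
                               config.smoothing_window)
    if normalize:
        flipped = pg.normalize_entry_side(traj, refs)
        if flipped is not traj:
            traj = flipped
            refs = mf.reference_series(traj, config.midplane_hysteresis,
                                       config.smoothing_window)

    desc, majors, minors = compute_descriptors(traj, refs, reference_closed,
                                               config)
    z_com = desc["z_com"].to_numpy()
    conf_labels = list(desc["conformation"])
    lock_labels = list(desc["lock_state"])
    ori_labels = list(desc["orientation"])

    hb_series = ev_mod.track_peptide_lipid_hbonds(traj, config)
    anchoring = ev_mod.detect_anchoring(traj, refs, z_com, config,
                                        conf_labels, hb_series)
    insertion = ev_mod.detect_insertion(z_com, refs, traj.times, traj.dt_ps,
                                        config, desc["theta_folded"].to_numpy())
    conf_events = ev_mod.detect_conformation_events(
        conf_labels, lock_labels, traj.times, traj.dt_ps, config, ori_labels)
    crossings = ev_mod.detect_leaflet_crossing(
        traj, refs, z_com, config, majors, minors, ori_labels)
    dwell = config.dwell_frames(config.dwell_conformation_ps, traj.dt_ps)
    rotations = ab.detect_rotation_events(ori_labels, dwell, traj.times, z_com)

    events, summary = ev_mod.assemble_timeline(
        anchoring, insertion, conf_events, crossings, rotations)

    fractions = None
    try:
        fractions = ab.orientation_fractions(ori_labels,
                                             config.equilibration_cut_frames)
    except ValueError:
        pass
    heatmap = ab.occupancy_heatmap(z_com, desc["theta_deg"].to_numpy())
    return AnalysisResult(descriptors=desc, refs=refs, events=events,
                          summary=summary, fractions=fractions,
                          heatmap=heatmap, majors=majors, minors=minors)


def analyze_pulling_run(traj: Trajectory, peptide_id: str,
                        pulled_residue: str,
                        config: Optional[AnalysisConfig] = None,
                        reference_closed: Optional[np.ndarray] = None
                        ) -> ev_mod.PullingRunResult:
    """Classify one pulling run: success = an anchoring event persisting
    to the end of the run (the configured success rule)."""
    config = config or AnalysisConfig()
    if reference_closed is None:
        from .synthetic_data import closed_reference_backbone
        reference_closed = closed_reference_backbone()
    refs = mf.reference_series(traj, config.midplane_hysteresis)
    z_com = np.array([pg.peptide_com_z(traj.coords[k], traj.roles, refs[k],
                                       traj.masses)
                      for k in range(traj.n_frames)])
    anchoring = ev_mod.detect_anchoring(traj, refs, z_com, config)
    rmsd0 = conf_mod.rmsd_to_closed(traj.coords[0], reference_closed,
                                    traj.roles, config.backbone_definition)
    start_conf = ("closed" if rmsd0 <= config.rmsd_closed_threshold else "open")
    success = False
    first = None
    tail_slack = config.max_gap_frames
    for e in anchoring:
        if first is None:
            first = e.start_frame
        if e.end_frame >= traj.n_frames - 1 - tail_slack:
            success = True
    if not success:
        first = first if anchoring else None
    return ev_mod.PullingRunResult(
        peptide_id=peptide_id, pulled_residue=pulled_residue,
        start_conformation=start_conf, success=success,
        first_anchor_frame=first if anchoring else None)
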