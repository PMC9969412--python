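"""Detection of the four permeation-step events and pulling statistics.

The permeation mechanism proceeds through (1) anchoring — an apolar side
chain engages exposed lipid tails through a transient headgroup gap while
the peptide COM is still above the headgroup surface; (2) insertion — the
COM drops below the upper headgroup surface and stays there, the peptide
rotating from perpendicular to parallel; (3) in-membrane conformational
events — closing via a half-closed intermediate, opening, lock release;
(4) leaflet crossing — the COM translocates across the bilayer midplane,
permanently or transiently, typically with a ~180° flip about the major
axis.  Each detector runs on per-frame descriptors with a dwell
requirement so that single-frame flicker never produces events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .membrane_frame import MembraneFrameRef
from .orientation_ab import detect_flip
from .trajio import AtomRoleMap, Trajectory

EVENT_TYPES = ("anchoring", "insertion", "closing", "half_closing", "opening",
               "lock_release", "crossing_permanent", "crossing_transient",
               "flip", "rotation_AB")


@dataclass
class EventRecord:
    """A typed interval on a trajectory."""

    type: str
    start_frame: int
    end_frame: int
    start_time_ps: float = 0.0
    end_time_ps: float = 0.0
    residues: List[str] = field(default_factory=list)
    attributes: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("event start after end")
        if self.type == "anchoring" and not self.residues:
            raise ValueError("anchoring events must carry >= 1 residue")
        if self.type.startswith("crossing"):
            if not {"leaflet_from", "leaflet_to"} <= set(self.attributes):
                raise ValueError("crossing events must carry leaflet_from/to")

    def to_dict(self) -> Dict:
        return {"type": self.type, "start_frame": int(self.start_frame),
                "end_frame": int(self.end_frame),
                "start_time_ps": float(self.start_time_ps),
                "end_time_ps": float(self.end_time_ps),
                "residues": list(self.residues),
                "attributes": dict(self.attributes)}


@dataclass
class PullingRunResult:
    """Outcome of one pulling run."""

    peptide_id: str
    pulled_residue: str
    start_conformation: str        # "open" | "closed"
    success: bool
    first_anchor_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.success and self.first_anchor_frame is None:
            raise ValueError("successful runs must define first_anchor_frame")


# ---------------------------------------------------------------------------
# Run utilities
# ---------------------------------------------------------------------------

def runs_from_mask(mask: Sequence[bool], max_gap: int = 0,
                   min_length: int = 1) -> List[Tuple[int, int]]:
    """Contiguous True runs, bridging interruptions of up to ``max_gap``
    frames, keeping runs of at least ``min_length`` frames."""
    idx = np.flatnonzero(np.asarray(mask, dtype=bool))
    if len(idx) == 0:
        return []
    runs: List[Tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > max_gap + 1:
            runs.append((int(start), int(prev)))
            start = i
        prev = i
    runs.append((int(start), int(prev)))
    return [(s, e) for s, e in runs if e - s + 1 >= min_length]


def smooth_labels(labels: Sequence[str], min_run: int) -> List[str]:
    """Suppress label runs shorter than ``min_run`` frames by carrying the
    nearest persistent label (dwell smoothing)."""
    from .orientation_ab import run_length_encode

    labels = list(labels)
    runs = run_length_encode(labels)
    persistent = [(lab, s, e) for lab, s, e in runs if e - s + 1 >= min_run]
    if not persistent:
        return labels
    out = list(labels)
    for lab, s, e in runs:
        if e - s + 1 >= min_run:
            continue
        prev = [p for p in persistent if p[2] < s]
        nxt = [p for p in persistent if p[1] > e]
        fill = prev[-1][0] if prev else nxt[0][0]
        for k in range(s, e + 1):
            out[k] = fill
    return out


def _transitions(labels: Sequence[str]) -> List[Tuple[str, str, int]]:
    """(from, to, frame-of-change) for a (smoothed) label series."""
    out = []
    for k in range(1, len(labels)):
        if labels[k] != labels[k - 1]:
            out.append((labels[k - 1], labels[k], k))
    return out


# ---------------------------------------------------------------------------
# Anchoring
# ---------------------------------------------------------------------------

def _apolar_sidechain_atoms(roles: AtomRoleMap, polarity: Dict[str, str]
                            ) -> Dict[str, np.ndarray]:
    out = {}
    for label, atoms in roles.peptide_sidechains.items():
        resname = "".join(c for c in label if not c.isdigit())
        cls = polarity.get(label, polarity.get(resname))
        if cls == "apolar" and len(atoms):
            out[label] = atoms
    return out


def sidechain_tail_contacts(frame: np.ndarray, roles: AtomRoleMap,
                            cutoff: float, polarity: Dict[str, str],
                            tail_subset: Optional[np.ndarray] = None
                            ) -> Dict[str, int]:
    """Contact counts per apolar residue: side-chain heavy atoms within
    ``cutoff`` of any lipid tail atom."""
    tails = roles.tail_atoms if tail_subset is None else tail_subset
    if len(tails) == 0:
        return {}
    tree = cKDTree(frame[tails])
    counts: Dict[str, int] = {}
    for label, atoms in _apolar_sidechain_atoms(roles, polarity).items():
        neighbors = tree.query_ball_point(frame[atoms], r=cutoff)
        c = sum(len(nb) for nb in neighbors)
        if c:
            counts[label] = c
    return counts


def detect_anchoring(traj: Trajectory, refs: Sequence[MembraneFrameRef],
                     z_com: np.ndarray,
                     config: Optional[AnalysisConfig] = None,
                     conf_labels: Optional[Sequence[str]] = None,
                     hbond_series: Optional[Sequence[list]] = None,
                     ) -> List[EventRecord]:
    """Anchoring events: apolar side-chain/tail contact while the peptide
    COM is still above the headgroup surface, persisting for the dwell."""
    config = config or AnalysisConfig()
    dwell = config.dwell_frames(config.dwell_anchoring_ps, traj.dt_ps)
    n = traj.n_frames
    contact_by_frame: List[Dict[str, int]] = []
    mask = np.zeros(n, dtype=bool)
    for k in range(n):
        above = z_com[k] > (refs[k].z_head_upper - refs[k].z_center)
        counts = {}
        if above:
            counts = sidechain_tail_contacts(
                traj.coords[k], traj.roles, config.anchor_contact_cutoff,
                config.polarity)
        contact_by_frame.append(counts)
        mask[k] = above and bool(counts)

    events: List[EventRecord] = []
    for s, e in runs_from_mask(mask, config.max_gap_frames, dwell):
        total: Dict[str, int] = {}
        for k in range(s, e + 1):
            for lab, c in contact_by_frame[k].items():
                total[lab] = total.get(lab, 0) + c
        residues = sorted(total, key=lambda l: -total[l])
        attrs: Dict = {"contact_counts": total}
        if conf_labels is not None:
            attrs["conformation_at_contact"] = conf_labels[s]
        if hbond_series is not None:
            attrs["peptide_lipid_hbonds_at_start"] = len(hbond_series[s])
            attrs["stabilizing_hbond_partners"] = [
                (d, m) for d, _a, m in hbond_series[s]]
        events.append(EventRecord(
            type="anchoring", start_frame=s, end_frame=e,
            start_time_ps=float(traj.times[s]), end_time_ps=float(traj.times[e]),
            residues=residues, attributes=attrs))
    return events


# ---------------------------------------------------------------------------
# Peptide-lipid hydrogen bonds
# ---------------------------------------------------------------------------

def track_peptide_lipid_hbonds(traj: Trajectory,
                               config: Optional[AnalysisConfig] = None,
                               ) -> List[List[Tuple[str, int, str]]]:
    """Per-frame (donor-residue, lipid-atom-index, moiety) hydrogen bonds
    between the peptide backbone N-H donors and phosphate/ester acceptors."""
    from .conformation import hbond_geometry_ok

    config = config or AnalysisConfig()
    roles = traj.roles
    acceptors: List[Tuple[int, str]] = (
        [(int(i), "phosphate") for i in roles.phosphate_atoms]
        + [(int(i), "ester") for i in roles.ester_carbons])
    out: List[List[Tuple[str, int, str]]] = []
    if not acceptors:
        return [[] for _ in range(traj.n_frames)]
    acc_idx = np.array([a for a, _ in acceptors])
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        tree = cKDTree(frame[acc_idx])
        bonds: List[Tuple[str, int, str]] = []
        for label in roles.residue_order:
            atoms = roles.backbone_atoms_by_residue.get(label, {})
            if "N" not in atoms:
                continue
            d_pos = frame[atoms["N"]]
            h_pos = frame[atoms["H"]] if "H" in atoms else None
            for j in tree.query_ball_point(d_pos, r=config.hbond.d_max):
                a_i, moiety = acceptors[j]
                if hbond_geometry_ok(d_pos, h_pos, frame[a_i], config.hbond):
                    bonds.append((label, a_i, moiety))
        out.append(bonds)
    return out


# ---------------------------------------------------------------------------
# Insertion
# ---------------------------------------------------------------------------

def detect_insertion(z_com: np.ndarray, refs: Sequence[MembraneFrameRef],
                     times: np.ndarray, dt_ps: float,
                     config: Optional[AnalysisConfig] = None,
                     theta_folded: Optional[np.ndarray] = None,
                     ) -> List[EventRecord]:
    """Insertion: COM drops below the upper headgroup surface and stays
    there for the dwell.  One event per persistent below-surface run."""
    config = config or AnalysisConfig()
    dwell = config.dwell_frames(config.dwell_insertion_ps, dt_ps)
    below = np.array([z_com[k] < (refs[k].z_head_upper - refs[k].z_center)
                      for k in range(len(z_com))])
    events: List[EventRecord] = []
    for s, e in runs_from_mask(below, config.max_gap_frames, dwell):
        attrs: Dict = {}
        head = refs[e].z_head_upper - refs[e].z_center
        tail = refs[e].z_tail_upper - refs[e].z_center
        attrs["final_z_com"] = float(z_com[e])
        attrs["at_interface"] = bool(tail <= z_com[e] <= head)
        if theta_folded is not None:
            attrs["theta_at_start"] = float(theta_folded[s])
            attrs["theta_at_end"] = float(theta_folded[e])
            attrs["rotated_to_parallel"] = bool(
                theta_folded[s] > 60.0
                and theta_folded[e] < config.parallel_max_theta)
        events.append(EventRecord(
            type="insertion", start_frame=s, end_frame=e,
            start_time_ps=float(times[s]), end_time_ps=float(times[e]),
            attributes=attrs))
    return events


# ---------------------------------------------------------------------------
# Conformational events
# ---------------------------------------------------------------------------

def detect_conformation_events(conf_labels: Sequence[str],
                               lock_labels: Sequence[str],
                               times: np.ndarray, dt_ps: float,
                               config: Optional[AnalysisConfig] = None,
                               orientation_labels: Optional[Sequence[str]] = None,
                               ) -> List[EventRecord]:
    """Closing / half-closing / opening and lock-release events from the
    per-frame conformation and lock label series (dwell-smoothed)."""
    config = config or AnalysisConfig()
    dwell = config.dwell_frames(config.dwell_conformation_ps, dt_ps)
    conf = smooth_labels(conf_labels, dwell)
    events: List[EventRecord] = []
    for frm, to, k in _transitions(conf):
        if to == "closed" and frm in ("open", "half_closed"):
            etype = "closing"
        elif to == "half_closed" and frm == "open":
            etype = "half_closing"
        elif to == "open" and frm in ("closed", "half_closed"):
            etype = "opening"
        else:
            continue
        attrs: Dict = {"from": frm, "to": to}
        if orientation_labels is not None:
            attrs["orientation_at_onset"] = orientation_labels[k]
        if lock_labels is not None and len(lock_labels):
            attrs["lock_before_onset"] = lock_labels[max(0, k - 1)]
        events.append(EventRecord(
            type=etype, start_frame=k, end_frame=k,
            start_time_ps=float(times[k]), end_time_ps=float(times[k]),
            attributes=attrs))
    if lock_labels is not None and len(lock_labels):
        lock = smooth_labels(lock_labels, dwell)
        for frm, to, k in _transitions(lock):
            if frm == "locked" and to == "unlocked":
                events.append(EventRecord(
                    type="lock_release", start_frame=k, end_frame=k,
                    start_time_ps=float(times[k]), end_time_ps=float(times[k])))
    events.sort(key=lambda e: e.start_frame)
    return events


# ---------------------------------------------------------------------------
# Leaflet crossing
# ---------------------------------------------------------------------------

def detect_leaflet_crossing(traj: Trajectory, refs: Sequence[MembraneFrameRef],
                            z_com: np.ndarray,
                            config: Optional[AnalysisConfig] = None,
                            majors: Optional[np.ndarray] = None,
                            minors: Optional[np.ndarray] = None,
                            orientation_labels: Optional[Sequence[str]] = None,
                            ) -> List[EventRecord]:
    """Leaflet-crossing events: COM sign changes across the bilayer center.

    A crossing is permanent when the residence in the new leaflet reaches
    the persistence threshold or lasts until the end of the trajectory
    (end-truncation counts as permanent); otherwise transient.  Attributes
    carry the destination-leaflet anchor residue (tail contact in the new
    leaflet around the transit) and the flip result when orientation axes
    are supplied.
    """
    config = config or AnalysisConfig()
    dt = traj.dt_ps
    persistence = config.dwell_frames(config.crossing_persistence_ps, dt)
    n = len(z_com)
    sign = np.where(z_com >= 0, 1, -1)

    # runs of constant leaflet sign
    from .orientation_ab import run_length_encode
    runs = run_length_encode([int(s) for s in sign])
    events: List[EventRecord] = []
    skip_next = False
    for r in range(1, len(runs)):
        lab, s, e = runs[r]
        if skip_next:
            # the return leg of a transient excursion is part of that event
            skip_next = False
            continue
        length = e - s + 1
        is_last = (e == n - 1)
        etype = ("crossing_permanent"
                 if (length >= persistence or is_last) else "crossing_transient")
        if etype == "crossing_transient":
            skip_next = True
        frm = "upper" if runs[r - 1][0] > 0 else "lower"
        to = "upper" if lab > 0 else "lower"
        attrs: Dict = {"leaflet_from": frm, "leaflet_to": to,
                       "residence_frames": int(length)}

        # transit interval: frames around the sign change inside the tail slab
        tail_mag = refs[s].z_tail_upper - refs[s].z_center
        t0 = s
        while t0 > 0 and abs(z_com[t0 - 1]) < tail_mag:
            t0 -= 1
        t1 = s
        while t1 < n - 1 and abs(z_com[t1 + 1]) < tail_mag:
            t1 += 1
        attrs["transit_interval"] = [int(t0), int(t1)]

        anchor = _destination_anchor(traj, refs, config, to, t0, s)
        if anchor is not None:
            attrs["anchor_residue"] = anchor
        if majors is not None and minors is not None and orientation_labels is not None:
            flip, roll = detect_flip(majors, minors, orientation_labels,
                                     (t0, t1), config)
            attrs["flip"] = bool(flip)
            attrs["net_roll_deg"] = float(roll[-1]) if len(roll) else 0.0
            if flip:
                events.append(EventRecord(
                    type="flip", start_frame=t0, end_frame=t1,
                    start_time_ps=float(traj.times[t0]),
                    end_time_ps=float(traj.times[t1])))
        events.append(EventRecord(
            type=etype, start_frame=s, end_frame=e,
            start_time_ps=float(traj.times[s]),
            end_time_ps=float(traj.times[e]), attributes=attrs))
    events.sort(key=lambda e: e.start_frame)
    return events


def _destination_anchor(traj: Trajectory, refs, config: AnalysisConfig,
                        dest: str, t0: int, s: int) -> Optional[str]:
    """Apolar residue with most destination-leaflet tail contacts during
    the approach to the midplane (frames t0..s)."""
    roles = traj.roles
    total: Dict[str, int] = {}
    for k in range(t0, s + 1):
        leaflets = refs[k].leaflet_of_lipid
        subset = np.array([i for i in roles.tail_atoms
                           if leaflets.get(roles.lipid_of_atom.get(int(i))) == dest],
                          dtype=int)
        counts = sidechain_tail_contacts(
            traj.coords[k], roles, config.anchor_contact_cutoff,
            config.polarity, tail_subset=subset)
        for lab, c in counts.items():
            total[lab] = total.get(lab, 0) + c
    if not total:
        return None
    return max(total, key=total.get)


# ---------------------------------------------------------------------------
# Pulling statistics
# ---------------------------------------------------------------------------

def anchor_probability(results: Sequence[PullingRunResult]):
    """Anchor probability per (pulled residue, start conformation).

    Pools runs across peptides sharing the pulled residue position; the
    probability is successes/runs per cell, with the run count reported.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    if not results:
        return pd.DataFrame(columns=["residue", "start_conformation",
                                     "n_runs", "n_success", "probability"])
    rows = [{"residue": r.pulled_residue,
             "start_conformation": r.start_conformation,
             "success": int(r.success)} for r in results]
    df = pd.DataFrame(rows)
    grouped = (df.groupby(["residue", "start_conformation"])["success"]
               .agg(n_runs="count", n_success="sum").reset_index())
    grouped["probability"] = grouped["n_success"] / grouped["n_runs"]
    return grouped


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------

def assemble_timeline(*event_lists: Sequence[EventRecord]
                      ) -> Tuple[List[EventRecord], Dict]:
    """Merge detector outputs into one chronological timeline plus a
    summary (counts by type, counts by start conformation, and flagged
    inconsistencies such as a closing with no preceding insertion)."""
    events: List[EventRecord] = [e for lst in event_lists for e in lst]
    events.sort(key=lambda e: (e.start_frame, e.end_frame,
                               EVENT_TYPES.index(e.type)
                               if e.type in EVENT_TYPES else 99))
    counts: Dict[str, int] = {}
    by_conf: Dict[Tuple[str, str], int] = {}
    for e in events:
        counts[e.type] = counts.get(e.type, 0) + 1
        conf = e.attributes.get("conformation_at_contact")
        if conf is not None:
            key = (e.type, conf)
            by_conf[key] = by_conf.get(key, 0) + 1

    inconsistencies: List[str] = []
    insertion_starts = [e.start_frame for e in events if e.type == "insertion"]
    for e in events:
        if e.type in ("closing", "half_closing"):
            if not any(s <= e.start_frame for s in insertion_starts):
                inconsistencies.append(
                    f"{e.type} at frame {e.start_frame} without prior insertion")
    summary = {"counts": counts,
               "counts_by_start_conformation": {
                   f"{t}|{c}": v for (t, c), v in by_conf.items()},
               "inconsistencies": inconsistencies}
    return events, summary
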