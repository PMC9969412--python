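"""Synthetic trajectories with scripted ground truth.

The generator emulates the statistical and kinematic structure that the
analysis assumes, without any molecular dynamics:

* a planar two-leaflet bilayer of pseudo-lipids, each with a headgroup
  nitrogen bead, a phosphate bead, an ester-carbon bead and three tail
  beads, on a lattice at ~0.65 nm² per lipid with Gaussian thermal jitter
  and a schedule of removable headgroups that opens packing gaps;
* a ring-shaped decapeptide of 10 residues (N/H/CA/O backbone beads plus
  one side-chain bead each), with anchor-capable apolar residues and two
  turn residues (a phenylalanine lock at position 5, a proline reporter
  at position 10), driven rigidly through scripted kinematic phases
  (diffuse, approach, anchor, insert, rotate-parallel, set-orientation,
  lock/unlock, half-close/close/open, cross, flip) with additive noise;
* ensembles of pulling runs with Bernoulli per-run success ground truth.

Every phase emits its ground-truth event interval, and fixed seeds give
bitwise-reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.spatial.transform import Rotation, Slerp

from .config import AnalysisConfig
from .events import EventRecord, PullingRunResult, runs_from_mask
from .trajio import AtomRoleMap, Trajectory, resolve_roles

RING_N = 10
SEQUENCE = ("LEU", "SER", "LEU", "SER", "PHE",
            "LEU", "SER", "LEU", "SER", "PRO")
#: donor -> acceptor ring positions of the closed-state hydrogen bonds
CANONICAL_PAIRS = ((1, 9), (9, 1), (3, 7), (7, 3))
STRAND1, STRAND2, TURNS = (1, 2, 3, 4), (6, 7, 8, 9), (5, 10)
LOCK_RESIDUE, REPORTER_RESIDUE = "PHE5", "PRO10"

CONFORMATIONS = ("closed", "open", "half_closed", "register_shifted")


class ScenarioError(ValueError):
    """Invalid scenario specification (e.g. inconsistent phase order)."""


# ---------------------------------------------------------------------------
# Peptide templates (local frame; ring roughly in the xy-plane)
# ---------------------------------------------------------------------------

def _strand_of(pos: int) -> Optional[int]:
    if pos in STRAND1:
        return 1
    if pos in STRAND2:
        return 2
    return None


def _closed_ca() -> Dict[int, np.ndarray]:
    ca = {}
    for k, pos in enumerate(STRAND1):
        ca[pos] = np.array([-0.525 + 0.35 * k, 0.24, 0.0])
    ca[5] = np.array([0.80, 0.0, 0.0])
    for k, pos in enumerate(STRAND2):
        ca[pos] = np.array([0.525 - 0.35 * k, -0.24, 0.0])
    ca[10] = np.array([-0.80, 0.0, 0.0])
    return ca


_DONOR_OF = {d: a for d, a in CANONICAL_PAIRS}
_BONDED = {p for pair in CANONICAL_PAIRS for p in pair}

_SC_STRAND = 0.35     # nm, side-chain bead offset for strand residues
_SC_TURN = 0.22       # nm, in-plane and out-of-plane turn side-chain offsets


def _place_backbone(ca: Dict[int, np.ndarray], inward: Dict[int, np.ndarray],
                    outward: Dict[int, np.ndarray],
                    lateral: Dict[int, np.ndarray]) -> Dict[int, Dict[str, np.ndarray]]:
    """N/H/O beads around each CA; bonded residues point N/O at their
    partner so the canonical contacts sit at ~0.29-0.30 nm, near-linear."""
    beads: Dict[int, Dict[str, np.ndarray]] = {}
    for pos in range(1, RING_N + 1):
        v = inward[pos] if pos in _BONDED else outward[pos]
        e = lateral[pos]
        beads[pos] = {
            "CA": ca[pos].copy(),
            "N": ca[pos] + 0.105 * v + 0.04 * e,
            "O": ca[pos] + 0.10 * v - 0.04 * e,
        }
    for pos in range(1, RING_N + 1):
        n = beads[pos]["N"]
        if pos in _DONOR_OF:
            target = beads[_DONOR_OF[pos]]["O"]
        else:
            target = n + (inward[pos] if pos in _BONDED else outward[pos])
        u = target - n
        beads[pos]["H"] = n + 0.12 * u / np.linalg.norm(u)
    return beads


def _template_closed() -> Dict[int, Dict[str, np.ndarray]]:
    ca = _closed_ca()
    inward, outward, lateral = {}, {}, {}
    for pos in range(1, RING_N + 1):
        st = _strand_of(pos)
        if st == 1:
            inward[pos] = np.array([0.0, -1.0, 0.0])
            outward[pos] = np.array([0.0, 1.0, 0.0])
            lateral[pos] = np.array([1.0, 0.0, 0.0])
        elif st == 2:
            inward[pos] = np.array([0.0, 1.0, 0.0])
            outward[pos] = np.array([0.0, -1.0, 0.0])
            lateral[pos] = np.array([1.0, 0.0, 0.0])
        else:
            sgn = 1.0 if pos == 5 else -1.0
            inward[pos] = outward[pos] = np.array([sgn, 0.0, 0.0])
            lateral[pos] = np.array([0.0, 1.0, 0.0])
    beads = _place_backbone(ca, inward, outward, lateral)
    for pos in range(1, RING_N + 1):
        if _strand_of(pos):
            beads[pos]["SC"] = ca[pos] + _SC_STRAND * outward[pos]
        else:
            # out-of-plane component (lock/reporter side) added at build time
            beads[pos]["SC_BASE"] = ca[pos] + _SC_TURN * outward[pos]
    return beads


def _template_open() -> Dict[int, Dict[str, np.ndarray]]:
    rx, ry = 1.0, 0.70
    ring_order = [10, 1, 2, 3, 4, 5, 6, 7, 8, 9]
    beads: Dict[int, Dict[str, np.ndarray]] = {}
    ca, outward, lateral = {}, {}, {}
    for k, pos in enumerate(ring_order):
        phi = np.radians(180.0 - 36.0 * k)
        ca[pos] = np.array([rx * np.cos(phi), ry * np.sin(phi), 0.0])
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        outward[pos] = u
        lateral[pos] = np.array([-np.sin(phi), np.cos(phi), 0.0])
    inward = {p: -outward[p] for p in outward}
    # all N/O point radially outward: no intramolecular contacts
    beads = _place_backbone(ca, {p: outward[p] for p in outward}.copy(),
                            outward, lateral)
    # overwrite: treat every residue as non-bonded (outward)
    for pos in range(1, RING_N + 1):
        v = outward[pos]
        e = lateral[pos]
        beads[pos]["N"] = ca[pos] + 0.105 * v + 0.04 * e
        beads[pos]["O"] = ca[pos] + 0.10 * v - 0.04 * e
        beads[pos]["H"] = beads[pos]["N"] + 0.12 * v
        if _strand_of(pos):
            beads[pos]["SC"] = ca[pos] + _SC_STRAND * v
        else:
            # deeper in-plane turn side chain than in the compact closed
            # state: the open ring splays its turn residues outward
            beads[pos]["SC_BASE"] = ca[pos] + _SC_STRAND * v
    return beads


def _template_half_closed() -> Dict[int, Dict[str, np.ndarray]]:
    """Closed geometry opened into a wedge on the 1/9 side: the 3->7 and
    7->3 bonds stay formed, the 1->9 and 9->1 bonds break."""
    beads = _template_closed()
    for pos in range(1, RING_N + 1):
        capos = beads[pos]["CA"]
        if capos[0] < -0.05:
            shift = np.array([-0.15 if pos == 10 else 0.0,
                              1.5 * capos[1], 0.0])
            for key, val in beads[pos].items():
                if isinstance(val, np.ndarray) and val.shape == (3,):
                    beads[pos][key] = val + shift
    return beads


def _template_register_shifted() -> Dict[int, Dict[str, np.ndarray]]:
    """Ring rotated by one position: residue i occupies the closed-template
    slot of residue i-1, so the bonded pattern appears shifted by +1."""
    closed = _template_closed()
    beads = {}
    for pos in range(1, RING_N + 1):
        slot = ((pos - 2) % RING_N) + 1
        beads[pos] = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                      for k, v in closed[slot].items()}
    return beads


_TEMPLATES = {
    "closed": _template_closed,
    "open": _template_open,
    "half_closed": _template_half_closed,
    "register_shifted": _template_register_shifted,
}
_TEMPLATE_CACHE: Dict[str, Dict] = {}


def peptide_template(conf: str, s_lock: float = 1.0, s_reporter: float = 1.0
                     ) -> Dict[int, Dict[str, np.ndarray]]:
    """Local-frame bead coordinates for one conformation.

    ``s_lock``/``s_reporter`` set the out-of-plane side (+1 = local +z) of
    the phenylalanine lock and proline reporter side chains.
    """
    if conf not in _TEMPLATES:
        raise ScenarioError(f"unknown conformation {conf!r}")
    if conf not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[conf] = _TEMPLATES[conf]()
    base = _TEMPLATE_CACHE[conf]
    out: Dict[int, Dict[str, np.ndarray]] = {}
    for pos, bd in base.items():
        out[pos] = {k: bd[k].copy() for k in ("N", "H", "CA", "O")}
        if "SC" in bd:
            out[pos]["SC"] = bd["SC"].copy()
        else:
            s = s_lock if pos == 5 else s_reporter
            out[pos]["SC"] = (bd["SC_BASE"]
                              + _SC_TURN * s * np.array([0.0, 0.0, 1.0]))
    return out


def closed_reference_backbone() -> np.ndarray:
    """CA coordinates of the closed reference, ring order (10, 3)."""
    t = peptide_template("closed")
    return np.array([t[p]["CA"] for p in range(1, RING_N + 1)])


def sidechain_reach(conf: str, pos: int) -> float:
    """Distance from the ring centroid to the residue's side-chain bead."""
    t = peptide_template(conf, 1.0, 1.0)
    centroid = np.mean([t[p]["CA"] for p in range(1, RING_N + 1)], axis=0)
    return float(np.linalg.norm(t[pos]["SC"] - centroid))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class MembraneSpec:
    """Pseudo-POPC bilayer geometry (nm)."""

    n_side: int = 8               # lipids per leaflet = n_side^2
    area_per_lipid: float = 0.65  # nm^2
    z_head: float = 2.0           # headgroup nitrogen |z|
    z_phosphate: float = 1.8
    z_ester: float = 1.5          # carbon succeeding the ester group
    tail_z: Tuple[float, ...] = (1.2, 0.9, 0.6)
    jitter: float = 0.08          # nm, per-bead Gaussian thermal jitter
    stiffness: float = 1.0        # >1 stiffens the surface (cholesterol-like)
    #: (start_frame, end_frame_inclusive, list of removed lipid ids)
    gap_schedule: List[Tuple[int, int, List[int]]] = field(default_factory=list)

    @property
    def spacing(self) -> float:
        return float(np.sqrt(self.area_per_lipid))

    @property
    def box_xy(self) -> float:
        return self.n_side * self.spacing

    @property
    def n_per_leaflet(self) -> int:
        return self.n_side ** 2

    def effective_jitter(self) -> float:
        return self.jitter / max(self.stiffness, 1e-9)


@dataclass
class Phase:
    type: str
    frames: int
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames <= 0:
            raise ScenarioError(f"phase {self.type!r} must have frames > 0")


@dataclass
class ScenarioSpec:
    phases: List[Phase]
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    noise: float = 0.015          # nm, peptide positional noise
    dt_ps: float = 100.0
    seed: int = 0
    start_conformation: str = "open"
    anchor_residue: str = "PHE5"
    entry_side: str = "upper"
    box_z: float = 12.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        violations = []
        seen_insert = False
        seen_approach = False
        needs_insert = {"close", "half_close", "open_conf", "register_shift",
                        "set_orientation", "set_lock", "cross", "return"}
        for ph in self.phases:
            if ph.type == "anchor" and not seen_approach:
                violations.append("anchor before approach")
            if ph.type in needs_insert and not seen_insert:
                violations.append(f"{ph.type} before insert")
            if ph.type == "approach":
                seen_approach = True
            if ph.type == "insert":
                if not seen_approach:
                    violations.append("insert before approach")
                seen_insert = True
        if self.start_conformation not in ("open", "closed"):
            violations.append(f"bad start_conformation {self.start_conformation}")
        if violations:
            raise ScenarioError("inconsistent phase order: " + "; ".join(violations))

    def to_yaml(self, path) -> None:
        data = {
            "phases": [{"type": p.type, "frames": p.frames, "params": p.params}
                       for p in self.phases],
            "membrane": asdict(self.membrane),
            "noise": self.noise, "dt_ps": self.dt_ps, "seed": self.seed,
            "start_conformation": self.start_conformation,
            "anchor_residue": self.anchor_residue,
            "entry_side": self.entry_side, "box_z": self.box_z,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        phases = [Phase(p["type"], p["frames"], p.get("params", {}))
                  for p in data.pop("phases")]
        mem = data.pop("membrane", None)
        membrane = MembraneSpec(**mem) if mem else MembraneSpec()
        if membrane.gap_schedule:
            membrane.gap_schedule = [
                (int(a), int(b), list(c)) for a, b, c in membrane.gap_schedule]
        membrane.tail_z = tuple(membrane.tail_z)
        return cls(phases=phases, membrane=membrane, **data)


@dataclass
class GroundTruth:
    """Scripted truth accompanying a generated trajectory."""

    events: List[EventRecord]
    conformation_labels: List[str]
    orientation_labels: List[str]       # "A" | "B" | "none"
    lock_labels: List[str]              # "locked"|"unlocked"|"undefined"
    register_flags: List[bool]
    z_com: np.ndarray                   # scripted COM z (noise-free)
    anchor_residue: Optional[str] = None
    mirrored: bool = False


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

_LIPID_BEADS = ("NH", "PH", "CE", "CT1", "CT2", "CT3")
_PEP_BEADS = ("N", "H", "CA", "O", "SC")
_PARK_Z = 0.3       # |z| where removed headgroup/phosphate/ester beads park


def _atom_metadata(membrane: MembraneSpec):
    names: List[str] = []
    resnames: List[str] = []
    resids: List[int] = []
    for pos in range(1, RING_N + 1):
        for bead in _PEP_BEADS:
            names.append(bead if bead != "SC" else "SC1")
            resnames.append(SEQUENCE[pos - 1])
            resids.append(pos)
    n_lip = 2 * membrane.n_per_leaflet
    for lid in range(n_lip):
        for bead in _LIPID_BEADS:
            names.append(bead)
            resnames.append("LIP")
            resids.append(RING_N + 1 + lid)
    return names, resnames, resids


def _lipid_base_coords(membrane: MembraneSpec) -> np.ndarray:
    """(n_lipids, 6, 3) base bead positions; upper leaflet first."""
    a = membrane.spacing
    pts = []
    for sign in (1.0, -1.0):
        zs = [sign * membrane.z_head, sign * membrane.z_phosphate,
              sign * membrane.z_ester] + [sign * z for z in membrane.tail_z]
        for i in range(membrane.n_side):
            for j in range(membrane.n_side):
                x, y = (i + 0.5) * a, (j + 0.5) * a
                pts.append([[x, y, z] for z in zs])
    return np.array(pts)


def lipid_site(membrane: MembraneSpec, i: int, j: int,
               leaflet: str = "upper") -> int:
    """Lipid id of lattice site (i, j) on the given leaflet."""
    base = 0 if leaflet == "upper" else membrane.n_per_leaflet
    return base + i * membrane.n_side + j


def site_xy(membrane: MembraneSpec, i: int, j: int) -> Tuple[float, float]:
    a = membrane.spacing
    return ((i + 0.5) * a, (j + 0.5) * a)


# ---------------------------------------------------------------------------
# Phase engine
# ---------------------------------------------------------------------------

def _pose_parallel(orientation: str) -> Rotation:
    if orientation == "B":
        return Rotation.identity()
    return Rotation.from_rotvec([np.pi, 0.0, 0.0])     # 180° roll about major


def _pose_anchored(conf: str, residue: str) -> Rotation:
    pos = _residue_position(residue)
    t = peptide_template(conf, 1.0, 1.0)
    centroid = np.mean([t[p]["CA"] for p in range(1, RING_N + 1)], axis=0)
    u = t[pos]["SC"] - centroid
    u = u / np.linalg.norm(u)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, -1.0]], [u])
    return rot


def _residue_position(label: str) -> int:
    digits = "".join(c for c in label if c.isdigit())
    if not digits:
        raise ScenarioError(f"residue label {label!r} lacks a position")
    return int(digits)


def anchored_com_z(membrane: MembraneSpec, conf: str, residue: str,
                   clearance: float = 0.05, contact_gap: float = 0.11) -> float:
    """COM height placing the anchor side chain within contact of the top
    tail beads while the COM stays above the headgroup surface."""
    reach = sidechain_reach(conf, _residue_position(residue))
    z_target = membrane.tail_z[0] + contact_gap + reach
    return max(membrane.z_head + clearance, z_target)


def _slerp_steps(r0: Rotation, r1: Rotation, n: int) -> List[Rotation]:
    if n <= 0:
        return []
    key = Rotation.concatenate([r0, r1])
    sl = Slerp([0.0, 1.0], key)
    return [sl(t) for t in np.linspace(1.0 / n, 1.0, n)]


@dataclass
class _FrameState:
    com: np.ndarray
    rot: Rotation
    conf: str
    lock: str            # desired world lock state or "undefined"
    orient: str          # "A" | "B" | "none"
    anchored: bool
    register: bool


def _script_phases(spec: ScenarioSpec) -> Tuple[List[_FrameState], Dict]:
    """Run the phase state machine; returns per-frame scripted states plus
    markers used for ground-truth events."""
    mem = spec.membrane
    cx = cy = mem.box_xy / 2.0
    site_i = site_j = mem.n_side // 2
    sx, sy = site_xy(mem, site_i, site_j)

    com = np.array([cx, cy, 5.0])
    rot = Rotation.identity()
    conf = spec.start_conformation
    lock = "undefined"
    orient = "none"
    anchor_res = spec.anchor_residue
    rng = np.random.default_rng(spec.seed + 7919)

    frames: List[_FrameState] = []
    markers: Dict = {"rotations": [], "lock_releases": [], "flip_phases": [],
                     "conf_changes": []}

    def emit(n: int, coms, rots, anchored=False):
        nonlocal com, rot
        for k in range(n):
            com = np.asarray(coms[k], dtype=float)
            rot = rots[k]
            frames.append(_FrameState(com.copy(), rot, conf, lock, orient,
                                      anchored, conf == "register_shifted"))

    def linear(a, b, n):
        return [a + (b - a) * (k + 1) / n for k in range(n)]

    for ph in spec.phases:
        n, p = ph.frames, ph.params
        if ph.type == "diffuse":
            z0 = p.get("z", 5.0)
            lo, hi = p.get("z_min", 4.5), p.get("z_max", 5.5)
            zs = []
            z = max(lo, min(hi, com[2] if frames else z0))
            for _ in range(n):
                z = float(np.clip(z + rng.normal(0, p.get("wander", 0.05)),
                                  lo, hi))
                zs.append(z)
            emit(n, [[com[0], com[1], z] for z in zs], [rot] * n)
        elif ph.type == "approach":
            z_end = p.get("z_end", anchored_com_z(mem, conf, anchor_res))
            target = np.array([sx, sy, z_end])
            pose = _pose_anchored(conf, anchor_res)
            emit(n, linear(com, target, n), _slerp_steps(rot, pose, n))
        elif ph.type == "anchor":
            markers.setdefault("anchor_intervals", []).append(
                (len(frames), len(frames) + n - 1))
            emit(n, [com] * n, [rot] * n, anchored=True)
        elif ph.type == "insert":
            z_end = p.get("z_end", 1.75)
            emit(n, linear(com, np.array([com[0], com[1], z_end]), n),
                 [rot] * n)
        elif ph.type == "rotate_parallel":
            target_orient = p.get("orientation", "B")
            pose = _pose_parallel(target_orient)
            emit(n, [com] * n, _slerp_steps(rot, pose, n))
            orient = target_orient
            if lock == "undefined":
                lock = "unlocked"
            frames[-1].orient = orient
            frames[-1].lock = lock
        elif ph.type == "set_orientation":
            to = p["to"]
            if to == orient:
                emit(n, [com] * n, [rot] * n)
            else:
                prev_orient = orient
                orient = "none"
                major_world = rot.apply([1.0, 0.0, 0.0])
                target = Rotation.from_rotvec(np.pi * major_world) * rot
                emit(n, [com] * n, _slerp_steps(rot, target, n))
                orient = to
                frames[-1].orient = to
                markers["rotations"].append((prev_orient, to, len(frames) - 1))
        elif ph.type == "set_lock":
            new = p["state"]
            if lock == "locked" and new == "unlocked":
                markers["lock_releases"].append(len(frames))
            lock = new
            emit(n, [com] * n, [rot] * n)
        elif ph.type in ("close", "half_close", "open_conf", "register_shift"):
            new_conf = {"close": "closed", "half_close": "half_closed",
                        "open_conf": "open",
                        "register_shift": "register_shifted"}[ph.type]
            if new_conf != conf:
                markers["conf_changes"].append((conf, new_conf, len(frames)))
            conf = new_conf
            emit(n, [com] * n, [rot] * n)
        elif ph.type in ("cross", "return"):
            z_to = p.get("z_to", -1.75 if ph.type == "cross" else 1.75)
            roll = bool(p.get("roll", False))
            prev_orient = orient
            orient = "none"
            coms = linear(com, np.array([com[0], com[1], z_to]), n)
            if roll:
                major_world = rot.apply([1.0, 0.0, 0.0])
                target = Rotation.from_rotvec(np.pi * major_world) * rot
                rots = _slerp_steps(rot, target, n)
                markers["flip_phases"].append((len(frames), len(frames) + n - 1))
            else:
                rots = [rot] * n
            emit(n, coms, rots)
            # in the destination leaflet the aqueous direction flips:
            # a roll preserves the label, no roll swaps it
            if prev_orient in ("A", "B"):
                orient = prev_orient if roll else {"A": "B", "B": "A"}[prev_orient]
                frames[-1].orient = orient
        elif ph.type == "hold":
            emit(n, [com] * n, [rot] * n)
        else:
            raise ScenarioError(f"unknown phase type {ph.type!r}")

    # propagate orientation through constant-pose stretches
    for k in range(1, len(frames)):
        if frames[k].orient == "none" and frames[k - 1].orient in ("A", "B"):
            same_pose = np.allclose(
                (frames[k].rot * frames[k - 1].rot.inv()).magnitude(), 0.0,
                atol=1e-9)
            if same_pose and abs(frames[k].com[2] - frames[k - 1].com[2]) < 1e-9:
                frames[k].orient = frames[k - 1].orient
    return frames, markers


# ---------------------------------------------------------------------------
# Trajectory emission
# ---------------------------------------------------------------------------

def _build_roles(membrane: MembraneSpec) -> AtomRoleMap:
    names, resnames, resids = _atom_metadata(membrane)
    return resolve_roles(names, resnames, resids)


def _emit_trajectory(spec: ScenarioSpec, states: List[_FrameState]
                     ) -> Tuple[Trajectory, np.ndarray]:
    mem = spec.membrane
    rng = np.random.default_rng(spec.seed)
    n_frames = len(states)
    names, resnames, resids = _atom_metadata(mem)
    n_pep = RING_N * len(_PEP_BEADS)
    lip_base = _lipid_base_coords(mem)            # (n_lip, 6, 3)
    n_lip = lip_base.shape[0]
    n_atoms = n_pep + n_lip * len(_LIPID_BEADS)

    removed_by_frame: Dict[int, set] = {}
    for (f0, f1, lids) in mem.gap_schedule:
        for f in range(f0, min(f1, n_frames - 1) + 1):
            removed_by_frame.setdefault(f, set()).update(lids)

    coords = np.empty((n_frames, n_atoms, 3))
    z_com = np.empty(n_frames)
    jit = mem.effective_jitter()
    aq_eps = 1e-9
    for k, st in enumerate(states):
        # peptide: lock side resolved so the desired world state holds;
        # before any parallel pose (lock undefined) the local side stays
        # +1, which is what the anchored-pose alignment assumes
        if st.lock == "undefined":
            s5 = 1.0
        else:
            a_world_z = st.rot.apply([0.0, 0.0, 1.0])[2]
            aq_sign = 1.0 if st.com[2] >= 0 else -1.0
            factor = np.sign(a_world_z * aq_sign) or 1.0
            desired = -1.0 if st.lock == "locked" else 1.0
            s5 = desired * factor
        tpl = peptide_template(st.conf, s_lock=s5, s_reporter=1.0)
        pep_local = np.array([tpl[p][b] for p in range(1, RING_N + 1)
                              for b in _PEP_BEADS])
        pep_world = st.com + st.rot.apply(pep_local)
        frame = np.empty((n_atoms, 3))
        frame[:n_pep] = pep_world + rng.normal(0, spec.noise, (n_pep, 3))

        lip = lip_base + rng.normal(0, jit, lip_base.shape)
        removed = removed_by_frame.get(k, set())
        for lid in removed:
            sign = 1.0 if lid < mem.n_per_leaflet else -1.0
            lip[lid, :3, 2] = sign * _PARK_Z + rng.normal(0, 0.02, 3)
        frame[n_pep:] = lip.reshape(-1, 3)
        coords[k] = frame
        z_com[k] = st.com[2]

    box = np.tile([mem.box_xy, mem.box_xy, spec.box_z], (n_frames, 1))
    times = np.arange(n_frames, dtype=float) * spec.dt_ps
    roles = resolve_roles(names, resnames, resids)
    traj = Trajectory(coords=coords, box=box, times=times, roles=roles,
                      atom_names=names, resnames=resnames,
                      resids=np.array(resids))
    return traj, z_com


def _derive_truth(spec: ScenarioSpec, states: List[_FrameState],
                  markers: Dict, z_com: np.ndarray,
                  config: Optional[AnalysisConfig] = None) -> GroundTruth:
    config = config or AnalysisConfig()
    mem = spec.membrane
    dt = spec.dt_ps
    times = np.arange(len(states)) * dt
    events: List[EventRecord] = []

    def ev(etype, s, e, residues=(), **attrs):
        events.append(EventRecord(type=etype, start_frame=int(s),
                                  end_frame=int(e),
                                  start_time_ps=float(times[s]),
                                  end_time_ps=float(times[e]),
                                  residues=list(residues),
                                  attributes=attrs))

    dwell_anchor = config.dwell_frames(config.dwell_anchoring_ps, dt)
    for (s, e) in markers.get("anchor_intervals", []):
        if e - s + 1 >= dwell_anchor:
            ev("anchoring", s, e, residues=[spec.anchor_residue])

    below = z_com < mem.z_head
    dwell_ins = config.dwell_frames(config.dwell_insertion_ps, dt)
    for (s, e) in runs_from_mask(below, 0, dwell_ins):
        ev("insertion", s, e)

    for (frm, to, k) in markers.get("conf_changes", []):
        if to == "closed":
            etype = "closing"
        elif to == "half_closed" and frm == "open":
            etype = "half_closing"
        elif to == "open":
            etype = "opening"
        else:
            continue
        ev(etype, k, k, orientation_at_onset=states[k].orient,
           lock_before_onset=states[max(0, k - 1)].lock)

    for k in markers.get("lock_releases", []):
        ev("lock_release", k, k)

    for (frm, to, k) in markers.get("rotations", []):
        ev("rotation_AB", k, k, **{"from": frm, "to": to})

    # crossings from the scripted COM sign
    from .orientation_ab import run_length_encode
    sign = [1 if z >= 0 else -1 for z in z_com]
    runs = run_length_encode(sign)
    persistence = config.dwell_frames(config.crossing_persistence_ps, dt)
    flip_phases = markers.get("flip_phases", [])
    skip_next = False
    for r in range(1, len(runs)):
        lab, s, e = runs[r]
        if skip_next:
            skip_next = False
            continue
        length = e - s + 1
        etype = ("crossing_permanent"
                 if (length >= persistence or e == len(states) - 1)
                 else "crossing_transient")
        if etype == "crossing_transient":
            skip_next = True
        phase = next(((p0, p1) for (p0, p1) in flip_phases if p0 <= s <= p1),
                     None)
        ev(etype, s, e,
           leaflet_from="upper" if runs[r - 1][0] > 0 else "lower",
           leaflet_to="upper" if lab > 0 else "lower", flip=phase is not None)
        if phase is not None:
            ev("flip", phase[0], phase[1])

    events.sort(key=lambda e: (e.start_frame, e.end_frame))
    return GroundTruth(
        events=events,
        conformation_labels=[
            "open" if st.conf == "register_shifted" else st.conf
            for st in states],
        orientation_labels=[st.orient for st in states],
        lock_labels=[st.lock for st in states],
        register_flags=[st.register for st in states],
        z_com=z_com,
        anchor_residue=spec.anchor_residue)


def _mirror(traj: Trajectory, z_center: float = 0.0) -> Trajectory:
    coords = traj.coords.copy()
    coords[:, :, 1] = traj.box[:, None, 1] - coords[:, :, 1]
    coords[:, :, 2] = 2.0 * z_center - coords[:, :, 2]
    return Trajectory(coords=coords, box=traj.box.copy(),
                      times=traj.times.copy(), roles=traj.roles,
                      masses=traj.masses, atom_names=traj.atom_names,
                      resnames=traj.resnames, resids=traj.resids)


def generate_scenario(spec: ScenarioSpec,
                      config: Optional[AnalysisConfig] = None
                      ) -> Tuple[Trajectory, GroundTruth]:
    """Generate a deterministic scripted trajectory and its ground truth."""
    spec.validate()
    states, markers = _script_phases(spec)
    traj, z_com = _emit_trajectory(spec, states)
    truth = _derive_truth(spec, states, markers, z_com, config)
    if spec.entry_side == "lower":
        traj = _mirror(traj)
        truth.mirrored = True
    return traj, truth


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

def _anchor_gap(mem: MembraneSpec, f0: int, f1: int) -> None:
    i = j = mem.n_side // 2
    mem.gap_schedule.append((f0, f1, [lipid_site(mem, i, j, "upper")]))


def scenario_four_step(seed: int = 0, anchor_residue: str = "PHE5",
                       flip: bool = True, closing_orientation: str = "B",
                       n_side: int = 8, diffuse_frames: int = 20
                       ) -> ScenarioSpec:
    """The full permeation pathway: anchoring -> insertion -> closing ->
    permanent leaflet crossing (with flip by default)."""
    phases = [
        Phase("diffuse", diffuse_frames),
        Phase("approach", 25),
        Phase("anchor", 40),
        Phase("insert", 30),
        Phase("rotate_parallel", 20, {"orientation": closing_orientation}),
        Phase("hold", 10),
        Phase("close", 40),
        Phase("cross", 30, {"roll": flip}),
        Phase("hold", 60),
    ]
    mem = MembraneSpec(n_side=n_side)
    spec = ScenarioSpec(phases=phases, membrane=mem, seed=seed,
                        anchor_residue=anchor_residue,
                        start_conformation="open")
    a0 = diffuse_frames
    _anchor_gap(mem, a0, a0 + 25 + 40 + 15)
    return spec


def scenario_anchor(seed: int = 0, anchor_residue: str = "PHE5",
                    diffuse_frames: int = 20, anchor_frames: int = 40,
                    n_side: int = 8, start_conformation: str = "open"
                    ) -> ScenarioSpec:
    phases = [Phase("diffuse", diffuse_frames), Phase("approach", 20),
              Phase("anchor", anchor_frames)]
    mem = MembraneSpec(n_side=n_side)
    spec = ScenarioSpec(phases=phases, membrane=mem, seed=seed,
                        anchor_residue=anchor_residue,
                        start_conformation=start_conformation)
    _anchor_gap(mem, diffuse_frames, diffuse_frames + 20 + anchor_frames)
    return spec


def scenario_transient_crossing(seed: int = 0, n_side: int = 8
                                ) -> ScenarioSpec:
    """Insertion followed by a transient crossing without flip."""
    phases = [
        Phase("diffuse", 10),
        Phase("approach", 20),
        Phase("anchor", 20),
        Phase("insert", 25),
        Phase("rotate_parallel", 15, {"orientation": "B"}),
        Phase("cross", 15, {"z_to": -0.8, "roll": False}),
        Phase("hold", 10),
        Phase("return", 15, {"z_to": 1.75}),
        Phase("hold", 45),
    ]
    mem = MembraneSpec(n_side=n_side)
    spec = ScenarioSpec(phases=phases, membrane=mem, seed=seed)
    _anchor_gap(mem, 10, 10 + 20 + 20 + 10)
    return spec


def scenario_closing(seed: int = 0, orientation: str = "B",
                     via_half_closed: bool = True, with_lock: bool = True,
                     n_side: int = 8) -> ScenarioSpec:
    """In-membrane closing (optionally via half-closed, preceded by a
    lock release) in the requested orientation."""
    phases = [
        Phase("diffuse", 10),
        Phase("approach", 20),
        Phase("anchor", 15),
        Phase("insert", 25),
        Phase("rotate_parallel", 15, {"orientation": orientation}),
    ]
    if with_lock:
        phases += [Phase("set_lock", 25, {"state": "locked"}),
                   Phase("set_lock", 25, {"state": "unlocked"})]
    else:
        phases += [Phase("hold", 25)]
    if via_half_closed:
        phases += [Phase("half_close", 25)]
    phases += [Phase("close", 40)]
    mem = MembraneSpec(n_side=n_side)
    spec = ScenarioSpec(phases=phases, membrane=mem, seed=seed)
    _anchor_gap(mem, 10, 10 + 20 + 15 + 10)
    return spec


def scenario_null(seed: int = 0, frames: int = 100, n_side: int = 8
                  ) -> ScenarioSpec:
    """Peptide diffusing far above the membrane; no events."""
    return ScenarioSpec(phases=[Phase("diffuse", frames)],
                        membrane=MembraneSpec(n_side=n_side), seed=seed)


def generate_null(duration: int = 100, seed: int = 0, n_side: int = 8
                  ) -> Tuple[Trajectory, GroundTruth]:
    traj, truth = generate_scenario(scenario_null(seed, duration, n_side))
    return traj, truth


def scripted_battery(n: int = 20, seed: int = 0) -> List[ScenarioSpec]:
    """A battery of scripted scenarios covering all four permeation steps,
    transient vs permanent crossings, flip vs no-flip, randomized anchor
    residues and onsets."""
    rng = np.random.default_rng(seed)
    anchors = ["PHE5", "LEU3", "LEU8", "PRO10"]
    specs: List[ScenarioSpec] = []
    for k in range(n):
        kind = k % 4
        s = int(rng.integers(0, 2 ** 31 - 1))
        diffuse = int(rng.integers(10, 30))
        anchor_res = anchors[int(rng.integers(0, len(anchors)))]
        if kind == 0:
            specs.append(scenario_four_step(seed=s, anchor_residue=anchor_res,
                                            flip=True, diffuse_frames=diffuse))
        elif kind == 1:
            specs.append(scenario_anchor(seed=s, anchor_residue=anchor_res,
                                         diffuse_frames=diffuse,
                                         anchor_frames=int(rng.integers(30, 60))))
        elif kind == 2:
            specs.append(scenario_transient_crossing(seed=s))
        else:
            specs.append(scenario_closing(
                seed=s, orientation="B" if rng.random() < 0.7 else "A",
                via_half_closed=bool(rng.random() < 0.7)))
    return specs


def scenario_orientation_occupancy(frac_A: float = 0.7, n_frames: int = 10000,
                                   mean_dwell: int = 10, seed: int = 0,
                                   n_side: int = 4) -> ScenarioSpec:
    """In-membrane A/B switching with geometric dwell times whose scripted
    occupancy targets ``frac_A``; switches are instantaneous (1-frame
    rolls).  Uses a small bilayer patch to keep long series cheap."""
    if not (0.0 < frac_A < 1.0):
        raise ScenarioError("frac_A must be in (0, 1)")
    rng = np.random.default_rng(seed + 13)
    phases = [Phase("approach", 5), Phase("insert", 10),
              Phase("rotate_parallel", 4, {"orientation": "B"})]
    mean_a = max(2.0, 2.0 * mean_dwell * frac_A)
    mean_b = max(2.0, 2.0 * mean_dwell * (1.0 - frac_A))
    state = "B"
    total = 0
    while total < n_frames:
        mean = mean_a if state == "A" else mean_b
        d = int(min(rng.geometric(1.0 / mean), n_frames - total))
        phases.append(Phase("hold", d))
        total += d
        if total >= n_frames:
            break
        other = "A" if state == "B" else "B"
        phases.append(Phase("set_orientation", 1, {"to": other}))
        state = other
        total += 1
    return ScenarioSpec(phases=phases, membrane=MembraneSpec(n_side=n_side),
                        seed=seed)


# ---------------------------------------------------------------------------
# Pulling ensembles
# ---------------------------------------------------------------------------

def scenario_pulling(seed: int, anchor_residue: str, success: bool,
                     start_conformation: str = "open", n_side: int = 6,
                     frames: int = 60) -> ScenarioSpec:
    if success:
        phases = [Phase("diffuse", 5), Phase("approach", 15),
                  Phase("anchor", frames - 20)]
    else:
        # brief touch (shorter than any dwell), then retreat
        phases = [Phase("diffuse", 5), Phase("approach", 15),
                  Phase("anchor", 2),
                  Phase("diffuse", frames - 22, {"z": 4.0})]
    mem = MembraneSpec(n_side=n_side)
    spec = ScenarioSpec(phases=phases, membrane=mem, seed=seed,
                        anchor_residue=anchor_residue,
                        start_conformation=start_conformation)
    _anchor_gap(mem, 5, frames - 1)
    return spec


def generate_pulling_ensemble(n_runs: int,
                              success_p,
                              seed: int = 0,
                              residues: Sequence[str] = ("LEU3", "LEU8",
                                                         "PHE5", "PRO10"),
                              peptide_ids: Sequence[str] = tuple(
                                  f"CDP{i}" for i in range(1, 9)),
                              start_conformations: Sequence[str] = ("open",
                                                                    "closed"),
                              frames: int = 60,
                              ) -> Tuple[List[Tuple[ScenarioSpec, Trajectory]],
                                         List[PullingRunResult]]:
    """Pulling-run ensemble with Bernoulli per-run success.

    ``success_p`` is a scalar probability or a residue->probability map.
    Returns the generated runs and the ground-truth results.
    """
    rng = np.random.default_rng(seed)
    runs: List[Tuple[ScenarioSpec, Trajectory]] = []
    truth: List[PullingRunResult] = []
    for k in range(n_runs):
        residue = residues[k % len(residues)]
        conf = start_conformations[(k // len(residues)) % len(start_conformations)]
        p = success_p.get(residue) if isinstance(success_p, dict) else success_p
        if not (0.0 <= p <= 1.0):
            raise ValueError("success probability must be in [0, 1]")
        success = bool(rng.random() < p)
        s = int(rng.integers(0, 2 ** 31 - 1))
        spec = scenario_pulling(s, residue, success,
                                start_conformation=conf, frames=frames)
        traj, gt = generate_scenario(spec)
        first_anchor = None
        if success:
            first_anchor = next(e.start_frame for e in gt.events
                                if e.type == "anchoring")
        runs.append((spec, traj))
        truth.append(PullingRunResult(
            peptide_id=peptide_ids[k % len(peptide_ids)],
            pulled_residue=residue, start_conformation=conf,
            success=success, first_anchor_frame=first_anchor))
    return runs, truth


# ---------------------------------------------------------------------------
# Membrane-only surfaces (gap statistics)
# ---------------------------------------------------------------------------

def generate_membrane_only(n_frames: int, removal_rate: float = 0.0,
                           seed: int = 0, n_side: int = 8,
                           jitter: float = 0.08, stiffness: float = 1.0,
                           dt_ps: float = 10.0) -> Trajectory:
    """Bilayer-only trajectory; each upper-leaflet headgroup is removed
    independently per frame with probability ``removal_rate`` (Poisson-like
    thermal gap openings)."""
    mem = MembraneSpec(n_side=n_side, jitter=jitter, stiffness=stiffness)
    rng = np.random.default_rng(seed)
    names, resnames, resids = [], [], []
    for lid in range(2 * mem.n_per_leaflet):
        for bead in _LIPID_BEADS:
            names.append(bead)
            resnames.append("LIP")
            resids.append(lid + 1)
    base = _lipid_base_coords(mem)
    jit = mem.effective_jitter()
    n_atoms = base.shape[0] * len(_LIPID_BEADS)
    coords = np.empty((n_frames, n_atoms, 3))
    for k in range(n_frames):
        lip = base + rng.normal(0, jit, base.shape)
        removed = np.flatnonzero(rng.random(mem.n_per_leaflet) < removal_rate)
        for lid in removed:
            lip[lid, :3, 2] = _PARK_Z + rng.normal(0, 0.02, 3)
        coords[k] = lip.reshape(-1, 3)
    box = np.tile([mem.box_xy, mem.box_xy, 12.0], (n_frames, 1))
    times = np.arange(n_frames, dtype=float) * dt_ps
    roles = resolve_roles(names, resnames, resids)
    return Trajectory(coords=coords, box=box, times=times, roles=roles,
                      atom_names=names, resnames=resnames,
                      resids=np.array(resids))
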