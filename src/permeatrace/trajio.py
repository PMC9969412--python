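"""Trajectory input/output and role-tagged atom selections.

Structure and trajectory files are read through MDAnalysis (GRO/PDB
structures; XTC/DCD-class trajectories), then converted into a neutral
in-memory :class:`Trajectory` with coordinates in nm and times in ps
regardless of the input dialect.  Atom roles (peptide backbone, side
chains, lipid headgroups, ester carbons, tails, solvent) are resolved from
declarative residue-name/atom-name rules so that the same pipeline handles
real lipid naming dialects and the synthetic pseudo-lipids.

A plain multi-frame text trajectory format (``.trj``) is provided as a
fully portable fallback for fixtures.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

NM_PER_ANGSTROM = 0.1


class RoleResolutionError(ValueError):
    """A selection rule matched zero atoms for a required role."""


@dataclass
class AtomRoleMap:
    """Role-tagged atom-index sets for one molecular system.

    Indices are 0-based positions into the coordinate array.  Peptide
    residue labels are ``f"{resname}{position}"`` with 1-based ring
    positions (e.g. ``"LEU3"``).
    """

    peptide_backbone: np.ndarray
    peptide_sidechains: Dict[str, np.ndarray]
    headgroup_nitrogens: np.ndarray
    phosphate_atoms: np.ndarray
    ester_carbons: np.ndarray
    tail_atoms: np.ndarray
    solvent: np.ndarray
    #: peptide residue labels in ring order
    residue_order: Tuple[str, ...] = ()
    #: residue label -> {"N": idx, "H": idx, "CA": idx, "O": idx}
    backbone_atoms_by_residue: Dict[str, Dict[str, int]] = field(default_factory=dict)
    #: lipid atom index -> lipid id (0-based)
    lipid_of_atom: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("peptide_backbone", "headgroup_nitrogens",
                     "phosphate_atoms", "ester_carbons", "tail_atoms",
                     "solvent"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.peptide_sidechains = {
            k: np.asarray(v, dtype=int) for k, v in self.peptide_sidechains.items()
        }
        self.validate()

    def validate(self) -> None:
        groups = [self.peptide_backbone, self.headgroup_nitrogens,
                  self.phosphate_atoms, self.ester_carbons, self.tail_atoms,
                  self.solvent] + list(self.peptide_sidechains.values())
        seen: set = set()
        for g in groups:
            s = set(int(i) for i in g)
            if seen & s:
                raise ValueError(
                    f"atom role sets are not disjoint: {sorted(seen & s)[:5]}")
            seen |= s
        labels = list(self.peptide_sidechains)
        if len(labels) != len(set(labels)):
            raise ValueError("peptide residue labels are not unique")
        has_lipids = (len(self.headgroup_nitrogens) > 0 or
                      len(self.tail_atoms) > 0)
        if has_lipids and len(self.ester_carbons) == 0:
            raise ValueError("ester_carbons empty although lipids are present")

    @property
    def peptide_atoms(self) -> np.ndarray:
        parts = [self.peptide_backbone] + list(self.peptide_sidechains.values())
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)

    def n_lipids(self) -> int:
        return len(set(self.lipid_of_atom.values()))


@dataclass
class Trajectory:
    """Ordered frames of one peptide/bilayer system.

    Coordinates in nm, box lengths in nm, times in ps.
    """

    coords: np.ndarray        # (n_frames, n_atoms, 3)
    box: np.ndarray           # (n_frames, 3)
    times: np.ndarray         # (n_frames,)
    roles: AtomRoleMap
    masses: Optional[np.ndarray] = None        # (n_atoms,), default unit masses
    atom_names: Optional[Sequence[str]] = None
    resnames: Optional[Sequence[str]] = None
    resids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if len(self.times) != self.n_frames:
            raise ValueError("times length mismatch")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.masses is None:
            self.masses = np.ones(self.n_atoms)
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt_ps(self) -> float:
        if self.n_frames < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------

#: Selection rules matching the synthetic pseudo-lipid/peptide dialect.
DEFAULT_SELECTION: Dict[str, object] = {
    "peptide_resnames": ["LEU", "SER", "PHE", "PRO", "ALA", "GLY"],
    "backbone_atom_names": ["N", "H", "CA", "O"],
    "ca_name": "CA",
    "sidechain_name_pattern": "SC*",
    "lipid_resnames": ["LIP", "POPC"],
    "headgroup_nitrogen_names": ["NH", "N4", "N"],
    "phosphate_names": ["PH", "P", "O1P", "O2P", "O3P", "O4P"],
    "ester_carbon_names": ["CE", "C22", "C32"],
    "tail_name_pattern": "CT*",
    "solvent_resnames": ["SOL", "W", "HOH"],
}


def _match_any(name: str, patterns: Sequence[str]) -> bool:
    return any(fnmatch.fnmatchcase(name, p) for p in patterns)


def resolve_roles(atom_names: Sequence[str], resnames: Sequence[str],
                  resids: Sequence[int], selection: Optional[dict] = None,
                  ) -> AtomRoleMap:
    """Resolve role sets from per-atom names via declarative rules.

    Raises :class:`RoleResolutionError` naming the first required role that
    matches zero atoms.
    """
    sel = dict(DEFAULT_SELECTION)
    if selection:
        sel.update(selection)
    atom_names = [str(n) for n in atom_names]
    resnames = [str(r) for r in resnames]
    resids = np.asarray(resids, dtype=int)
    n = len(atom_names)
    if not (len(resnames) == n and len(resids) == n):
        raise ValueError("atom metadata arrays must have equal length")

    pep_res = set(sel["peptide_resnames"])
    lip_res = set(sel["lipid_resnames"])
    sol_res = set(sel["solvent_resnames"])

    backbone: List[int] = []
    sidechains: Dict[str, List[int]] = {}
    headgroups: List[int] = []
    phosphates: List[int] = []
    esters: List[int] = []
    tails: List[int] = []
    solvent: List[int] = []
    residue_order: List[str] = []
    bb_by_res: Dict[str, Dict[str, int]] = {}
    lipid_of_atom: Dict[int, int] = {}

    # peptide residues are numbered by order of first appearance
    pep_position: Dict[int, int] = {}
    lipid_id: Dict[int, int] = {}
    for i in range(n):
        rn, an, rid = resnames[i], atom_names[i], int(resids[i])
        if rn in pep_res:
            if rid not in pep_position:
                pep_position[rid] = len(pep_position) + 1
            label = f"{rn}{pep_position[rid]}"
            if label not in sidechains:
                sidechains[label] = []
                residue_order.append(label)
                bb_by_res[label] = {}
            if an in sel["backbone_atom_names"]:
                backbone.append(i)
                bb_by_res[label][an] = i
            elif _match_any(an, [sel["sidechain_name_pattern"]]):
                sidechains[label].append(i)
        elif rn in lip_res:
            if rid not in lipid_id:
                lipid_id[rid] = len(lipid_id)
            lid = lipid_id[rid]
            if an in sel["headgroup_nitrogen_names"]:
                headgroups.append(i)
            elif an in sel["phosphate_names"]:
                phosphates.append(i)
            elif an in sel["ester_carbon_names"]:
                esters.append(i)
            elif _match_any(an, [sel["tail_name_pattern"]]):
                tails.append(i)
            else:
                continue
            lipid_of_atom[i] = lid
        elif rn in sol_res:
            solvent.append(i)

    has_lipids = bool(lipid_id)
    has_peptide = bool(pep_position)
    required = {}
    if has_peptide:
        required["peptide_backbone"] = backbone
    if has_lipids:
        required.update({
            "headgroup_nitrogens": headgroups,
            "ester_carbons": esters,
            "tail_atoms": tails,
        })
    for role, members in required.items():
        if not members:
            raise RoleResolutionError(
                f"selection rules matched zero atoms for role '{role}'")

    return AtomRoleMap(
        peptide_backbone=np.array(backbone, dtype=int),
        peptide_sidechains={k: np.array(v, dtype=int) for k, v in sidechains.items()},
        headgroup_nitrogens=np.array(headgroups, dtype=int),
        phosphate_atoms=np.array(phosphates, dtype=int),
        ester_carbons=np.array(esters, dtype=int),
        tail_atoms=np.array(tails, dtype=int),
        solvent=np.array(solvent, dtype=int),
        residue_order=tuple(residue_order),
        backbone_atoms_by_residue=bb_by_res,
        lipid_of_atom=lipid_of_atom,
    )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_trajectory(structure_path, trajectory_path=None,
                    selection_config=None) -> Trajectory:
    """Load structure + trajectory into a :class:`Trajectory`.

    ``structure_path`` is a PDB or GRO file; ``trajectory_path`` is an
    XTC/DCD-class binary trajectory, a ``.trj`` plain-text trajectory, or
    None (single-frame structure).  ``selection_config`` is a rules dict or
    a path to a YAML file with rules (see :data:`DEFAULT_SELECTION`).
    """
    import MDAnalysis as mda

    structure_path = Path(structure_path)
    if isinstance(selection_config, (str, Path)):
        with open(selection_config) as fh:
            selection_config = yaml.safe_load(fh)

    u = mda.Universe(str(structure_path))
    atom_names = [a.name for a in u.atoms]
    resnames = [a.resname.strip() for a in u.atoms]
    resids = np.array([a.resid for a in u.atoms])
    roles = resolve_roles(atom_names, resnames, resids, selection_config)

    if trajectory_path is not None and str(trajectory_path).endswith(".trj"):
        coords, box, times = read_text_trajectory(trajectory_path)
        if coords.shape[1] != len(u.atoms):
            raise ValueError(
                f"atom-count mismatch: structure has {len(u.atoms)} atoms, "
                f"trajectory has {coords.shape[1]}")
    else:
        if trajectory_path is not None:
            try:
                u = mda.Universe(str(structure_path), str(trajectory_path))
            except ValueError as err:
                raise ValueError(
                    f"atom-count mismatch between structure and trajectory: {err}"
                ) from err
        nf = len(u.trajectory)
        na = len(u.atoms)
        coords = np.empty((nf, na, 3))
        box = np.empty((nf, 3))
        times = np.empty(nf)
        for k, ts in enumerate(u.trajectory):
            coords[k] = u.atoms.positions * NM_PER_ANGSTROM
            box[k] = ts.dimensions[:3] * NM_PER_ANGSTROM
            times[k] = ts.time if ts.time is not None else float(k)
        if nf > 1 and np.all(np.diff(times) == 0):
            times = np.arange(nf, dtype=float)

    return Trajectory(coords=coords, box=box, times=times, roles=roles,
                      atom_names=atom_names, resnames=resnames, resids=resids)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_structure(traj: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as a GRO (or PDB) structure file via MDAnalysis."""
    import MDAnalysis as mda

    if traj.atom_names is None or traj.resnames is None or traj.resids is None:
        raise ValueError("trajectory lacks atom metadata; cannot write structure")
    resids = np.asarray(traj.resids)
    # map resids to contiguous residue indices in order of appearance
    order: Dict[int, int] = {}
    for r in resids:
        if int(r) not in order:
            order[int(r)] = len(order)
    resindex = np.array([order[int(r)] for r in resids])
    n_res = len(order)
    res_names = [""] * n_res
    res_ids = [0] * n_res
    for i, r in enumerate(resids):
        res_names[resindex[i]] = traj.resnames[i]
        res_ids[resindex[i]] = int(r)
    u = mda.Universe.empty(traj.n_atoms, n_residues=n_res,
                           atom_resindex=resindex, trajectory=True)
    u.add_TopologyAttr("names", list(traj.atom_names))
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", res_ids)
    u.atoms.positions = traj.coords[frame] / NM_PER_ANGSTROM
    u.dimensions = [*(traj.box[frame] / NM_PER_ANGSTROM), 90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write all frames as XTC/DCD (by extension) or ``.trj`` plain text."""
    path = str(path)
    if path.endswith(".trj"):
        write_text_trajectory(traj, path)
        return

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    coords_A = traj.coords / NM_PER_ANGSTROM
    dims = np.column_stack([traj.box / NM_PER_ANGSTROM,
                            np.full((traj.n_frames, 3), 90.0)])
    resids = traj.resids if traj.resids is not None else np.ones(traj.n_atoms, int)
    order: Dict[int, int] = {}
    for r in resids:
        if int(r) not in order:
            order[int(r)] = len(order)
    resindex = np.array([order[int(r)] for r in resids])
    u = mda.Universe.empty(traj.n_atoms, n_residues=len(order),
                           atom_resindex=resindex, trajectory=True)
    u.load_new(coords_A.astype(np.float32), format=MemoryReader,
               dimensions=dims, dt=traj.dt_ps)
    with mda.Writer(path, n_atoms=traj.n_atoms) as w:
        for ts in u.trajectory:
            ts.time = traj.times[ts.frame]
            w.write(u.atoms)


_TRJ_HEADER = "# permeatrace text trajectory v1"


def write_text_trajectory(traj: Trajectory, path) -> None:
    """Plain multi-frame text trajectory (fixture-friendly fallback)."""
    with open(path, "w") as fh:
        fh.write(f"{_TRJ_HEADER}\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        for k in range(traj.n_frames):
            bx = traj.box[k]
            fh.write(f"frame {k} time {traj.times[k]:.6f} "
                     f"box {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f}\n")
            np.savetxt(fh, traj.coords[k], fmt="%.6f")


def read_text_trajectory(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _TRJ_HEADER:
            raise ValueError(f"not a permeatrace text trajectory: {path}")
        n_atoms = int(fh.readline().split()[1])
        frames, boxes, times = [], [], []
        while True:
            line = fh.readline()
            if not line:
                break
            parts = line.split()
            times.append(float(parts[3]))
            boxes.append([float(x) for x in parts[5:8]])
            block = np.array([fh.readline().split() for _ in range(n_atoms)],
                             dtype=float)
            frames.append(block)
    return np.array(frames), np.array(boxes), np.array(times)


# ---------------------------------------------------------------------------
# Event logs
# ---------------------------------------------------------------------------

def write_event_log(events, path) -> None:
    """Write an event list as CSV and/or JSON.

    ``path`` ending in ``.csv`` or ``.json`` selects one format; any other
    path is used as a base name and both files are written.  Events must be
    sorted by start frame.
    """
    import pandas as pd

    events = list(events)
    starts = [e.start_frame for e in events]
    if starts != sorted(starts):
        raise ValueError("events must be sorted by start frame")

    rows = [e.to_dict() for e in events]
    path = str(path)
    targets = []
    if path.endswith(".csv"):
        targets = [(path, "csv")]
    elif path.endswith(".json"):
        targets = [(path, "json")]
    else:
        targets = [(path + ".csv", "csv"), (path + ".json", "json")]

    columns = ["type", "start_frame", "end_frame", "start_time_ps",
               "end_time_ps", "residues", "attributes"]
    for target, kind in targets:
        if kind == "json":
            with open(target, "w") as fh:
                json.dump(rows, fh, indent=1, default=_json_default)
        else:
            flat = []
            for r in rows:
                r = dict(r)
                r["residues"] = ";".join(r["residues"])
                r["attributes"] = json.dumps(r["attributes"], default=_json_default)
                flat.append(r)
            pd.DataFrame(flat, columns=columns).to_csv(target, index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_event_log(path):
    """Read an event log written by :func:`write_event_log`."""
    import pandas as pd

    from .events import EventRecord

    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
    else:
        df = pd.read_csv(path)
        rows = []
        for _, r in df.iterrows():
            rows.append({
                "type": r["type"],
                "start_frame": int(r["start_frame"]),
                "end_frame": int(r["end_frame"]),
                "start_time_ps": float(r["start_time_ps"]),
                "end_time_ps": float(r["end_time_ps"]),
                "residues": [] if (pd.isna(r["residues"]) or r["residues"] == "")
                            else str(r["residues"]).split(";"),
                "attributes": json.loads(r["attributes"]),
            })
    return [EventRecord(type=r["type"], start_frame=r["start_frame"],
                        end_frame=r["end_frame"],
                        start_time_ps=r["start_time_ps"],
                        end_time_ps=r["end_time_ps"],
                        residues=list(r["residues"]),
                        attributes=dict(r["attributes"]))
            for r in rows]
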