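"""Per-frame membrane reference geometry.

The headgroup surface of each leaflet is the mean z of the choline-class
nitrogens, the tail-start surface the mean z of the carbons succeeding the
ester group, and the bilayer center the midpoint of the two tail-start
surfaces.  The membrane normal is fixed to the z-axis (the bilayer stays
planar and COM-motion free by construction of the simulations analyzed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .trajio import AtomRoleMap, Trajectory


class DegenerateMembraneError(ValueError):
    """A leaflet has zero lipids (or leaflet assignment is ambiguous)."""


@dataclass
class MembraneFrameRef:
    """Reference surfaces of one bilayer frame (all z in nm)."""

    z_head_upper: float
    z_head_lower: float
    z_tail_upper: float
    z_tail_lower: float
    z_center: float
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    area_per_lipid: Optional[float] = None
    leaflet_of_lipid: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.z_head_upper > self.z_tail_upper > self.z_center
                > self.z_tail_lower > self.z_head_lower):
            raise DegenerateMembraneError(
                "surface ordering violated: expected z_head_upper > z_tail_upper"
                " > z_center > z_tail_lower > z_head_lower, got "
                f"{self.z_head_upper:.3f} > {self.z_tail_upper:.3f} > "
                f"{self.z_center:.3f} > {self.z_tail_lower:.3f} > "
                f"{self.z_head_lower:.3f}")


def _lipid_group_z(coords: np.ndarray, indices: np.ndarray,
                   lipid_of_atom: Dict[int, int]) -> Dict[int, float]:
    """Mean z per lipid id over the given atom indices."""
    acc: Dict[int, List[float]] = {}
    for i in indices:
        lid = lipid_of_atom.get(int(i))
        if lid is None:
            continue
        acc.setdefault(lid, []).append(coords[i, 2])
    return {lid: float(np.mean(v)) for lid, v in acc.items()}


def assign_leaflets(frame: np.ndarray, roles: AtomRoleMap,
                    previous: Optional[Dict[int, str]] = None,
                    hysteresis: float = 0.2) -> Dict[int, str]:
    """Assign each lipid to the upper or lower leaflet.

    Assignment is by the sign of the lipid headgroup z relative to the
    bilayer midplane (estimated as the mean headgroup z).  Within
    ``hysteresis`` nm of the midplane the previous frame's assignment is
    carried over to avoid flicker; on the first frame such a lipid raises
    :class:`DegenerateMembraneError`.
    """
    if len(roles.headgroup_nitrogens) == 0:
        raise DegenerateMembraneError("no lipid headgroups present")
    head_z = _lipid_group_z(frame, roles.headgroup_nitrogens, roles.lipid_of_atom)
    mid = float(np.mean(list(head_z.values())))
    out: Dict[int, str] = {}
    for lid, z in head_z.items():
        dz = z - mid
        if abs(dz) <= hysteresis and previous is not None and lid in previous:
            out[lid] = previous[lid]
        elif dz > 0:
            out[lid] = "upper"
        elif dz < 0:
            out[lid] = "lower"
        else:
            if previous is not None and lid in previous:
                out[lid] = previous[lid]
            else:
                raise DegenerateMembraneError(
                    f"lipid {lid} sits exactly on the midplane in the first frame")
    return out


def reference_surfaces(frame: np.ndarray, roles: AtomRoleMap,
                       box: Optional[np.ndarray] = None,
                       previous_leaflets: Optional[Dict[int, str]] = None,
                       hysteresis: float = 0.2) -> MembraneFrameRef:
    """Compute headgroup/tail-start surfaces and bilayer center for one frame."""
    leaflets = assign_leaflets(frame, roles, previous_leaflets, hysteresis)
    upper = {l for l, s in leaflets.items() if s == "upper"}
    lower = {l for l, s in leaflets.items() if s == "lower"}
    if not upper or not lower:
        raise DegenerateMembraneError("one leaflet has zero lipids")

    head_z = _lipid_group_z(frame, roles.headgroup_nitrogens, roles.lipid_of_atom)
    tail_z = _lipid_group_z(frame, roles.ester_carbons, roles.lipid_of_atom)

    def mean_over(zmap: Dict[int, float], lids) -> float:
        vals = [zmap[l] for l in lids if l in zmap]
        if not vals:
            raise DegenerateMembraneError("leaflet without reference atoms")
        return float(np.mean(vals))

    z_head_upper = mean_over(head_z, upper)
    z_head_lower = mean_over(head_z, lower)
    z_tail_upper = mean_over(tail_z, upper)
    z_tail_lower = mean_over(tail_z, lower)
    z_center = 0.5 * (z_tail_upper + z_tail_lower)

    apl = None
    if box is not None:
        apl = area_per_lipid_value(box, len(upper), len(lower))

    return MembraneFrameRef(
        z_head_upper=z_head_upper, z_head_lower=z_head_lower,
        z_tail_upper=z_tail_upper, z_tail_lower=z_tail_lower,
        z_center=z_center, area_per_lipid=apl, leaflet_of_lipid=leaflets)


def area_per_lipid_value(box: np.ndarray, n_upper: int, n_lower: int) -> float:
    """Box XY area divided by lipids per leaflet (mean of the two counts)."""
    n_per_leaflet = 0.5 * (n_upper + n_lower)
    if n_per_leaflet <= 0:
        raise DegenerateMembraneError("zero lipids")
    return float(box[0] * box[1] / n_per_leaflet)


def area_per_lipid(frame: np.ndarray, roles: AtomRoleMap,
                   box: np.ndarray) -> float:
    leaflets = assign_leaflets(frame, roles)
    n_upper = sum(1 for s in leaflets.values() if s == "upper")
    n_lower = sum(1 for s in leaflets.values() if s == "lower")
    return area_per_lipid_value(box, n_upper, n_lower)


def reference_series(traj: Trajectory, hysteresis: float = 0.2,
                     smoothing_window: int = 0) -> List[MembraneFrameRef]:
    """Per-frame reference geometry over a whole trajectory.

    ``smoothing_window`` > 1 applies a centered moving average to the four
    surface series (and re-derives the center) after computation.
    """
    refs: List[MembraneFrameRef] = []
    prev: Optional[Dict[int, str]] = None
    for k in range(traj.n_frames):
        ref = reference_surfaces(traj.coords[k], traj.roles, traj.box[k],
                                 previous_leaflets=prev, hysteresis=hysteresis)
        prev = ref.leaflet_of_lipid
        refs.append(ref)
    if smoothing_window and smoothing_window > 1:
        refs = _smooth_refs(refs, smoothing_window)
    return refs


def _smooth_refs(refs: List[MembraneFrameRef], window: int) -> List[MembraneFrameRef]:
    fields = ["z_head_upper", "z_head_lower", "z_tail_upper", "z_tail_lower"]
    arr = {f: np.array([getattr(r, f) for r in refs]) for f in fields}
    kernel = np.ones(window) / window
    pad = window // 2
    sm = {}
    for f, a in arr.items():
        padded = np.pad(a, pad, mode="edge")
        sm[f] = np.convolve(padded, kernel, mode="same")[pad:pad + len(a)]
    out = []
    for k, r in enumerate(refs):
        out.append(MembraneFrameRef(
            z_head_upper=sm["z_head_upper"][k], z_head_lower=sm["z_head_lower"][k],
            z_tail_upper=sm["z_tail_upper"][k], z_tail_lower=sm["z_tail_lower"][k],
            z_center=0.5 * (sm["z_tail_upper"][k] + sm["z_tail_lower"][k]),
            area_per_lipid=r.area_per_lipid, leaflet_of_lipid=r.leaflet_of_lipid))
    return out


def reference_table(refs: List[MembraneFrameRef]):
    """Reference series as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame({
        "frame": np.arange(len(refs)),
        "z_head_upper": [r.z_head_upper for r in refs],
        "z_tail_upper": [r.z_tail_upper for r in refs],
        "z_center": [r.z_center for r in refs],
        "z_tail_lower": [r.z_tail_lower for r in refs],
        "z_head_lower": [r.z_head_lower for r in refs],
        "area_per_lipid": [r.area_per_lipid for r in refs],
    })
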