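"""Grid-based detection of transient headgroup gaps (packing defects).

The leaflet surface is rasterized onto a periodic XY grid.  Looking from
the solvent side, the first atom encountered within a depth window around
the interfacial slab classifies each cell: *covered-polar* when it is a
headgroup/phosphate/ester atom, *exposed-apolar* when it is a lipid tail
atom, *empty* when nothing covers the cell.  Connected exposed-apolar
cells (4-connectivity, periodic in XY) form gaps; a gap's area is its
cell count times the cell area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .config import GapGridSpec
from .membrane_frame import MembraneFrameRef
from .trajio import AtomRoleMap

EMPTY, POLAR, APOLAR = 0, 1, 2


@dataclass
class GapMap:
    """Classified leaflet surface of one frame."""

    leaflet: str
    grid: np.ndarray                   # (nx, ny) int labels
    cell_area: float                   # nm^2
    gaps: List[Dict]                   # {"cells": (k,2) array, "area": nm^2}
    frame: int = 0

    @property
    def total_gap_area(self) -> float:
        return float(sum(g["area"] for g in self.gaps))

    @property
    def max_gap_area(self) -> float:
        return float(max((g["area"] for g in self.gaps), default=0.0))


def _footprint_cells(x: float, y: float, r: float, nx: int, ny: int,
                     dx: float, dy: float) -> Tuple[np.ndarray, np.ndarray]:
    """Periodic grid cells whose center lies within r of (x, y)."""
    i0 = int(np.floor(x / dx))
    j0 = int(np.floor(y / dy))
    ri = int(np.ceil(r / dx)) + 1
    rj = int(np.ceil(r / dy)) + 1
    ii, jj = np.meshgrid(np.arange(i0 - ri, i0 + ri + 1),
                         np.arange(j0 - rj, j0 + rj + 1), indexing="ij")
    cx = (ii + 0.5) * dx
    cy = (jj + 0.5) * dy
    ddx = cx - x
    ddy = cy - y
    # periodic minimum image
    Lx, Ly = nx * dx, ny * dy
    ddx -= Lx * np.round(ddx / Lx)
    ddy -= Ly * np.round(ddy / Ly)
    mask = ddx ** 2 + ddy ** 2 <= r ** 2
    return ii[mask] % nx, jj[mask] % ny


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _periodic_components(mask: np.ndarray) -> np.ndarray:
    """Connected components of a boolean grid, 4-connectivity with
    periodic wrap in both directions.  Returns an int label array
    (0 = background)."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels
    uf = _UnionFind(n + 1)
    # merge across x boundary
    for j in range(mask.shape[1]):
        a, b = labels[0, j], labels[-1, j]
        if a and b:
            uf.union(a, b)
    for i in range(mask.shape[0]):
        a, b = labels[i, 0], labels[i, -1]
        if a and b:
            uf.union(a, b)
    remap = np.zeros(n + 1, dtype=int)
    next_id = 0
    for lab in range(1, n + 1):
        root = uf.find(lab)
        if remap[root] == 0:
            next_id += 1
            remap[root] = next_id
        remap[lab] = remap[root]
    return remap[labels]


def scan_gaps(frame: np.ndarray, roles: AtomRoleMap, leaflet: str,
              ref: MembraneFrameRef, box: np.ndarray,
              grid: Optional[GapGridSpec] = None,
              frame_index: int = 0) -> GapMap:
    """Classify one leaflet surface and extract its gaps."""
    grid = grid or GapGridSpec()
    if grid.spacing <= 0:
        raise ValueError("grid spacing must be positive")
    Lx, Ly = float(box[0]), float(box[1])
    nx = max(1, int(round(Lx / grid.spacing)))
    ny = max(1, int(round(Ly / grid.spacing)))
    dx, dy = Lx / nx, Ly / ny
    cell_area = dx * dy

    if leaflet == "upper":
        z_lo = ref.z_tail_upper - grid.depth_pad
        z_hi = ref.z_head_upper + grid.depth_pad
        sense = 1.0            # first-from-solvent = largest z
    elif leaflet == "lower":
        z_lo = ref.z_head_lower - grid.depth_pad
        z_hi = ref.z_tail_lower + grid.depth_pad
        sense = -1.0           # first-from-solvent = smallest z
    else:
        raise ValueError(f"unknown leaflet {leaflet!r}")

    leaflet_of = ref.leaflet_of_lipid
    best = np.full((nx, ny), -np.inf)
    cls = np.full((nx, ny), EMPTY, dtype=int)

    polar_atoms = np.concatenate([roles.headgroup_nitrogens,
                                  roles.phosphate_atoms, roles.ester_carbons])
    for indices, radius, label in ((polar_atoms, grid.radius_polar, POLAR),
                                   (roles.tail_atoms, grid.radius_tail, APOLAR)):
        for i in indices:
            lid = roles.lipid_of_atom.get(int(i))
            if lid is None or leaflet_of.get(lid) != leaflet:
                continue
            x, y, z = frame[i]
            if not (z_lo <= z <= z_hi):
                continue
            key = sense * z
            ii, jj = _footprint_cells(x % Lx, y % Ly, radius, nx, ny, dx, dy)
            upd = key > best[ii, jj]
            best[ii[upd], jj[upd]] = key
            cls[ii[upd], jj[upd]] = label

    labels = _periodic_components(cls == APOLAR)
    gaps: List[Dict] = []
    for lab in range(1, labels.max() + 1):
        cells = np.argwhere(labels == lab)
        gaps.append({"cells": cells, "area": len(cells) * cell_area})
    gaps.sort(key=lambda g: -g["area"])
    return GapMap(leaflet=leaflet, grid=cls, cell_area=cell_area,
                  gaps=gaps, frame=frame_index)


# ---------------------------------------------------------------------------
# Statistics over frames
# ---------------------------------------------------------------------------

def gap_size_distribution(gapmaps: Sequence[GapMap],
                          bin_width: float = 0.05) -> Dict:
    """Normalized gap-area histogram plus an exponential-decay fit.

    Fits log-probability vs area by least squares over the nonzero bins
    and reports the decay constant (1/nm^2).  With no gaps the histogram
    is empty and the fit is skipped.
    """
    if not len(gapmaps):
        raise ValueError("need at least one frame")
    areas = np.array([g["area"] for gm in gapmaps for g in gm.gaps])
    out: Dict = {"areas": areas, "n_gaps": len(areas)}
    if len(areas) == 0:
        out.update({"hist": np.array([]), "bin_edges": np.array([]),
                    "max_area": 0.0, "decay_constant": None})
        return out
    max_area = float(areas.max())
    edges = np.arange(0.0, max_area + 2 * bin_width, bin_width)
    hist, edges = np.histogram(areas, bins=edges, density=True)
    out.update({"hist": hist, "bin_edges": edges, "max_area": max_area})
    centers = 0.5 * (edges[:-1] + edges[1:])
    pos = hist > 0
    if pos.sum() >= 2:
        fit = sps.linregress(centers[pos], np.log(hist[pos]))
        out["decay_constant"] = float(-fit.slope)
        out["fit_rvalue"] = float(fit.rvalue)
    else:
        out["decay_constant"] = None
    return out


def gap_accessibility(area: float, threshold: float = 0.23) -> bool:
    """Whether a gap can accommodate an anchor side chain.

    Default threshold 0.23 nm^2, the minimum gap size for a leucine side
    chain; the boundary value itself counts as accessible.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return bool(area >= threshold)


def gap_lifetimes(gapmaps: Sequence[GapMap], dt_ps: float = 1.0) -> List[Dict]:
    """Track gaps across consecutive frames by cell overlap (>= 1 cell).

    Returns one record per track: first/last frame, lifetime in ps
    ((last - first) * stride) and maximum area.
    """
    tracks: List[Dict] = []
    active: List[Dict] = []      # {"cells": set, "track": dict}
    for gm in gapmaps:
        new_active: List[Dict] = []
        used = [False] * len(active)
        for g in gm.gaps:
            cells = {(int(i), int(j)) for i, j in g["cells"]}
            match = None
            for k, a in enumerate(active):
                if not used[k] and (cells & a["cells"]):
                    match = k
                    break
            if match is None:
                track = {"start_frame": gm.frame, "end_frame": gm.frame,
                         "max_area": g["area"]}
                tracks.append(track)
            else:
                used[match] = True
                track = active[match]["track"]
                track["end_frame"] = gm.frame
                track["max_area"] = max(track["max_area"], g["area"])
            new_active.append({"cells": cells, "track": track})
        active = new_active
    for t in tracks:
        t["lifetime_ps"] = (t["end_frame"] - t["start_frame"]) * dt_ps
    return tracks
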