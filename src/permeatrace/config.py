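"""Analysis configuration.

All geometric thresholds and dwell times of the pipeline live in one
dataclass so that a single YAML file configures an entire analysis run.
Distances are in nm, times in ps, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import yaml

#: Donor->acceptor residue positions (1-based, ring order) of the four
#: intramolecular backbone hydrogen bonds of the closed conformation.
DEFAULT_CANONICAL_HBONDS: Tuple[Tuple[int, int], ...] = (
    (1, 9), (9, 1), (3, 7), (7, 3),
)


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    A donor-H...acceptor triple counts as bonded when the donor-acceptor
    heavy-atom distance is at most ``d_max`` and the donor-H-acceptor angle
    is at least ``angle_min``.  When no hydrogen position is available the
    criterion falls back to the heavy-atom distance alone.
    """

    d_max: float = 0.35           # nm, donor-acceptor heavy-atom distance
    angle_min: float = 150.0      # deg, donor-H-acceptor angle


@dataclass
class GapGridSpec:
    """Grid specification for headgroup-gap scanning."""

    spacing: float = 0.1          # nm, nominal cell edge
    radius_polar: float = 0.62    # nm, footprint of headgroup/phosphate/ester beads
    radius_tail: float = 0.45     # nm, footprint of tail beads (two tails spread)
    depth_pad: float = 0.5        # nm, depth window extends this far beyond the surfaces
    accessibility_threshold: float = 0.23  # nm^2, minimum gap area for a leucine-class anchor


@dataclass
class AnalysisConfig:
    """Thresholds, dwell times and residue roles for a full analysis run."""

    # --- conformation -----------------------------------------------------
    rmsd_closed_threshold: float = 0.2    # nm; above this the peptide is not closed
    canonical_hbonds: Tuple[Tuple[int, int], ...] = DEFAULT_CANONICAL_HBONDS
    hbond: HBondCriterion = field(default_factory=HBondCriterion)
    #: atoms used for the backbone ellipse / RMSD ("ca" or "all")
    backbone_definition: str = "ca"

    # --- residue roles ----------------------------------------------------
    lock_residues: Tuple[str, ...] = ("PHE5",)     # bulky turn residues (lock)
    reporter_residues: Tuple[str, ...] = ("PRO10",)  # A/B reporter turn residues
    #: residue-name -> "polar" | "apolar"
    polarity: Dict[str, str] = field(default_factory=lambda: {
        "LEU": "apolar", "PHE": "apolar", "PRO": "apolar",
        "SER": "polar", "GLY": "polar", "ALA": "polar",
    })

    # --- orientation ------------------------------------------------------
    parallel_max_theta: float = 30.0      # deg, folded theta below this = parallel
    midplane_hysteresis: float = 0.2      # nm, leaflet-assignment hysteresis band

    # --- event detection --------------------------------------------------
    anchor_contact_cutoff: float = 0.45   # nm, side-chain heavy atom to tail atom
    dwell_anchoring_ps: float = 1000.0    # 1 ns
    dwell_insertion_ps: float = 2000.0    # 2 ns
    dwell_conformation_ps: float = 1000.0  # 1 ns
    crossing_persistence_ps: float = 5000.0  # 5 ns ("a few nanoseconds")
    max_gap_frames: int = 2               # frames of interruption tolerated inside a run
    flip_tolerance_deg: float = 45.0      # |net roll - 180| tolerance for a flip
    #: pulling-run success = anchoring event persisting to the end of the run
    pulling_success_rule: str = "persists_to_end"

    # --- gaps -------------------------------------------------------------
    gap_grid: GapGridSpec = field(default_factory=GapGridSpec)

    # --- misc -------------------------------------------------------------
    smoothing_window: int = 0             # frames; 0 = no smoothing of z-references
    equilibration_cut_frames: int = 0     # frames excluded from orientation fractions

    def dwell_frames(self, dwell_ps: float, dt_ps: float) -> int:
        """Convert a dwell time in ps to a frame count (at least 1)."""
        if dt_ps <= 0:
            return 1
        return max(1, int(round(dwell_ps / dt_ps)))

    # --- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["canonical_hbonds"] = [list(p) for p in self.canonical_hbonds]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        kwargs = dict(data)
        if "hbond" in kwargs and isinstance(kwargs["hbond"], dict):
            kwargs["hbond"] = HBondCriterion(**kwargs["hbond"])
        if "gap_grid" in kwargs and isinstance(kwargs["gap_grid"], dict):
            kwargs["gap_grid"] = GapGridSpec(**kwargs["gap_grid"])
        if "canonical_hbonds" in kwargs:
            kwargs["canonical_hbonds"] = tuple(
                tuple(p) for p in kwargs["canonical_hbonds"])
        for key in ("lock_residues", "reporter_residues"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
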