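"""Shared fixtures: programmatically built peptide/bilayer systems."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from permeatrace import synthetic_data as sd
from permeatrace.membrane_frame import MembraneFrameRef
from permeatrace.pipeline import analyze_trajectory
from permeatrace.trajio import resolve_roles


def peptide_metadata():
    names, resnames, resids = [], [], []
    for pos in range(1, sd.RING_N + 1):
        for bead in sd._PEP_BEADS:
            names.append(bead if bead != "SC" else "SC1")
            resnames.append(sd.SEQUENCE[pos - 1])
            resids.append(pos)
    return names, resnames, resids


@pytest.fixture(scope="session")
def peptide_roles():
    return resolve_roles(*peptide_metadata())


def peptide_frame(conf="closed", com=(0.0, 0.0, 0.0), rot=None,
                  s_lock=1.0, s_reporter=1.0, center=False):
    """One noise-free peptide frame from the generator templates."""
    t = sd.peptide_template(conf, s_lock, s_reporter)
    loc = np.array([t[p][b] for p in range(1, sd.RING_N + 1)
                    for b in sd._PEP_BEADS])
    if center:
        loc = loc - loc.mean(axis=0)
    if rot is not None:
        loc = rot.apply(loc)
    return np.asarray(com, dtype=float) + loc


def flat_ref(center=0.0):
    return MembraneFrameRef(
        z_head_upper=2.0 + center, z_head_lower=-2.0 + center,
        z_tail_upper=1.5 + center, z_tail_lower=-1.5 + center,
        z_center=center)


@pytest.fixture(scope="session")
def four_step():
    """Four-step scenario: trajectory, ground truth, analysis result."""
    traj, gt = sd.generate_scenario(sd.scenario_four_step(seed=3))
    return traj, gt, analyze_trajectory(traj)


@pytest.fixture(scope="session")
def flat_membrane():
    """Jitter-free bilayer-only trajectory (1 frame)."""
    return sd.generate_membrane_only(1, 0.0, seed=0, jitter=0.0)


def park_headgroups(traj, sites, n_side=8, frame=0):
    """Remove the headgroup/phosphate/ester beads of the given lattice
    sites from the interfacial slab (mimics a headgroup gap)."""
    mem = sd.MembraneSpec(n_side=n_side)
    polar = (traj.roles.headgroup_nitrogens.tolist()
             + traj.roles.phosphate_atoms.tolist()
             + traj.roles.ester_carbons.tolist())
    for (i, j) in sites:
        lid = sd.lipid_site(mem, i, j)
        idx = [a for a in polar if traj.roles.lipid_of_atom[a] == lid]
        traj.coords[frame][idx, 2] = sd._PARK_Z
    return traj
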