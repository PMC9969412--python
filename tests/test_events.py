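"""Event detection: anchoring, insertion, conformational events, leaflet
crossing, pulling statistics, timeline assembly."""

import numpy as np
import pandas as pd
import pytest

from permeatrace import synthetic_data as sd
from permeatrace.config import AnalysisConfig, HBondCriterion
from permeatrace.conformation import hbond_geometry_ok
from permeatrace.events import (EventRecord, PullingRunResult,
                                anchor_probability, assemble_timeline,
                                detect_conformation_events,
                                detect_leaflet_crossing, runs_from_mask,
                                smooth_labels, track_peptide_lipid_hbonds)
from permeatrace.membrane_frame import reference_series
from permeatrace.pipeline import analyze_pulling_run, analyze_trajectory


# ---------------------------------------------------------------------------
# Run utilities
# ---------------------------------------------------------------------------

def test_runs_from_mask_bridges_gaps():
    mask = [True] * 5 + [False] * 2 + [True] * 5 + [False] * 6 + [True] * 3
    assert runs_from_mask(mask, max_gap=2, min_length=1) == [(0, 11), (18, 20)]
    assert runs_from_mask(mask, max_gap=0, min_length=4) == [(0, 4), (7, 11)]
    assert runs_from_mask([False] * 10) == []


def test_smooth_labels_suppresses_short_runs():
    labels = ["open"] * 20 + ["closed"] * 2 + ["open"] * 20 + ["closed"] * 15
    sm = smooth_labels(labels, 5)
    assert sm[:42] == ["open"] * 42
    assert sm[42:] == ["closed"] * 15


# ---------------------------------------------------------------------------
# Anchoring
# ---------------------------------------------------------------------------

def test_anchoring_scripted_and_null(four_step):
    traj, gt, res = four_step
    anchored = [e for e in res.events if e.type == "anchoring"]
    truth = [e for e in gt.events if e.type == "anchoring"]
    assert len(anchored) == len(truth) == 1
    assert anchored[0].residues[0] == gt.anchor_residue
    assert abs(anchored[0].start_frame - truth[0].start_frame) <= 10
    assert anchored[0].attributes["conformation_at_contact"] == "open"

    null, _ = sd.generate_null(60, seed=31, n_side=4)
    assert analyze_trajectory(null).events == []


def test_anchoring_randomized_residues():
    """Scripted scenarios with randomized anchor residue recover the
    event and name the correct residue."""
    for seed, residue in [(41, "LEU3"), (43, "LEU8"), (47, "PRO10")]:
        spec = sd.scenario_anchor(seed=seed, anchor_residue=residue,
                                  diffuse_frames=12 + seed % 9)
        traj, gt = sd.generate_scenario(spec)
        events = [e for e in analyze_trajectory(traj).events
                  if e.type == "anchoring"]
        assert len(events) == 1
        assert events[0].residues[0] == residue
        truth_start = next(e.start_frame for e in gt.events
                           if e.type == "anchoring")
        assert abs(events[0].start_frame - truth_start) <= 10


# ---------------------------------------------------------------------------
# Peptide-lipid hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_fixture(distance, n_side=4):
    """Anchored scenario frame with one backbone N-H aimed at a phosphate
    bead at the requested distance."""
    traj, _ = sd.generate_scenario(sd.scenario_anchor(seed=3, n_side=n_side))
    traj.coords[:] = traj.coords[0]          # freeze one frame everywhere
    frame = traj.coords[0]
    roles = traj.roles
    ph = roles.phosphate_atoms[0]
    don = roles.backbone_atoms_by_residue["LEU1"]
    target = frame[ph]
    n_pos = target + np.array([0.0, 0.0, distance])
    frame[don["N"]] = n_pos
    frame[don["H"]] = n_pos + 0.1 * (target - n_pos) / np.linalg.norm(
        target - n_pos)
    return traj


def test_peptide_lipid_hbond_fixture_detected():
    traj = _hbond_fixture(0.29)
    bonds = track_peptide_lipid_hbonds(traj)[0]
    assert ("LEU1", int(traj.roles.phosphate_atoms[0]), "phosphate") in bonds


def test_peptide_lipid_hbond_too_far():
    traj = _hbond_fixture(0.50)
    assert all(d != "LEU1" for d, _, _ in track_peptide_lipid_hbonds(traj)[0])


def test_peptide_lipid_hbonds_match_pair_scan_oracle():
    traj, _ = sd.generate_scenario(sd.scenario_anchor(seed=3, n_side=4))
    cfg = AnalysisConfig()
    got = track_peptide_lipid_hbonds(traj, cfg)
    roles = traj.roles
    acceptors = ([(int(i), "phosphate") for i in roles.phosphate_atoms]
                 + [(int(i), "ester") for i in roles.ester_carbons])
    for k in range(0, traj.n_frames, 7):
        frame = traj.coords[k]
        oracle = []
        for label in roles.residue_order:
            atoms = roles.backbone_atoms_by_residue[label]
            for ai, moiety in acceptors:
                if hbond_geometry_ok(frame[atoms["N"]], frame[atoms["H"]],
                                     frame[ai], cfg.hbond):
                    oracle.append((label, ai, moiety))
        assert sorted(got[k]) == sorted(oracle)


# ---------------------------------------------------------------------------
# Insertion ordering
# ---------------------------------------------------------------------------

def test_anchoring_precedes_insertion(four_step):
    _, _, res = four_step
    anchor = next(e for e in res.events if e.type == "anchoring")
    ins = next(e for e in res.events if e.type == "insertion")
    assert anchor.start_frame < ins.start_frame
    assert anchor.end_frame <= ins.start_frame


def test_anchored_but_detached_gives_no_insertion():
    spec = sd.scenario_pulling(seed=5, anchor_residue="PHE5", success=False)
    traj, _ = sd.generate_scenario(spec)
    res = analyze_trajectory(traj)
    assert all(e.type != "insertion" for e in res.events)


# ---------------------------------------------------------------------------
# Conformational events
# ---------------------------------------------------------------------------

def test_conformation_events_scripted_sequence():
    """open -> half-closed -> closed in orientation B yields one
    half-closing and one closing, both with onset orientation B."""
    spec = sd.scenario_closing(seed=10, orientation="B",
                               via_half_closed=True, with_lock=False)
    traj, gt = sd.generate_scenario(spec)
    res = analyze_trajectory(traj)
    by_type = {e.type: e for e in res.events}
    assert "half_closing" in by_type and "closing" in by_type
    assert by_type["half_closing"].start_frame < by_type["closing"].start_frame
    assert by_type["closing"].attributes["orientation_at_onset"] == "B"


def test_closing_in_orientation_A_is_still_reported():
    """Detectors must not hard-code the orientation-B finding: a scripted
    closing in orientation A is reported with onset orientation A."""
    spec = sd.scenario_closing(seed=12, orientation="A",
                               via_half_closed=False, with_lock=False)
    traj, _ = sd.generate_scenario(spec)
    res = analyze_trajectory(traj)
    closing = next(e for e in res.events if e.type == "closing")
    assert closing.attributes["orientation_at_onset"] == "A"


def test_lock_release_event_detected():
    spec = sd.scenario_closing(seed=9, orientation="A", via_half_closed=True,
                               with_lock=True)
    traj, gt = sd.generate_scenario(spec)
    res = analyze_trajectory(traj)
    got = [e for e in res.events if e.type == "lock_release"]
    truth = [e for e in gt.events if e.type == "lock_release"]
    assert len(got) == len(truth) == 1
    assert abs(got[0].start_frame - truth[0].start_frame) <= 10
    closing = next(e for e in res.events if e.type == "closing")
    assert closing.attributes["lock_before_onset"] == "unlocked"


def test_conformation_events_match_rle_oracle_on_random_paths():
    rng = np.random.default_rng(37)
    times = np.arange(400) * 100.0
    for _ in range(20):
        labels = []
        while len(labels) < 400:
            labels += [("open", "half_closed", "closed")[rng.integers(0, 3)]
                       ] * int(rng.integers(1, 40))
        labels = labels[:400]
        events = detect_conformation_events(labels, [], times, 100.0)
        sm = smooth_labels(labels, 10)
        emitted = {("open", "closed"), ("half_closed", "closed"),
                   ("open", "half_closed"), ("closed", "open"),
                   ("half_closed", "open")}
        oracle = sum(1 for a, b in zip(sm[:-1], sm[1:])
                     if a != b and (a, b) in emitted)
        assert len(events) == oracle
        assert all(e.start_frame <= e.end_frame for e in events)


def test_constant_series_no_events():
    times = np.arange(100) * 100.0
    assert detect_conformation_events(["closed"] * 100, ["unlocked"] * 100,
                                      times, 100.0) == []


# ---------------------------------------------------------------------------
# Leaflet crossing
# ---------------------------------------------------------------------------

def _crossing_events(z_com, dt=100.0):
    n = len(z_com)
    traj = sd.generate_membrane_only(n, 0.0, seed=1, n_side=4, dt_ps=dt)
    refs = reference_series(traj)
    return detect_leaflet_crossing(traj, refs, np.asarray(z_com))


def test_crossing_classification_threshold_oracle():
    """Residence-time sweep around the persistence threshold (50 frames
    at 100 ps): shorter residences are transient, longer permanent."""
    for residence in (5, 20, 49, 50, 80):
        z = [1.0] * 60 + [-1.0] * residence + [1.0] * 60
        ev = _crossing_events(z)
        kinds = [e.type for e in ev if e.type.startswith("crossing")]
        expected = ("crossing_permanent" if residence >= 50
                    else "crossing_transient")
        assert kinds[0] == expected
        assert ev[0].attributes["leaflet_from"] == "upper"
        assert ev[0].attributes["leaflet_to"] == "lower"


def test_transient_return_is_not_a_second_crossing():
    z = [1.0] * 60 + [-1.0] * 10 + [1.0] * 60
    ev = _crossing_events(z)
    assert [e.type for e in ev] == ["crossing_transient"]


def test_end_truncated_residence_counts_as_permanent():
    z = [1.0] * 60 + [-1.0] * 8
    ev = _crossing_events(z)
    assert [e.type for e in ev] == ["crossing_permanent"]


def test_two_frame_flicker_is_transient():
    z = [1.0] * 60 + [-0.05] * 2 + [1.0] * 60
    ev = _crossing_events(z)
    assert [e.type for e in ev] == ["crossing_transient"]


def test_crossing_carries_anchor_residue(four_step):
    _, _, res = four_step
    crossing = next(e for e in res.events if e.type == "crossing_permanent")
    assert crossing.attributes["flip"] is True
    assert isinstance(crossing.attributes.get("anchor_residue"), str)


# ---------------------------------------------------------------------------
# Pulling statistics
# ---------------------------------------------------------------------------

def test_anchor_probability_arithmetic():
    runs = [PullingRunResult("CDP1", "LEU8", "open", False)
            for _ in range(5)]
    tab = anchor_probability(runs)
    assert tab.loc[0, "probability"] == 0.0 and tab.loc[0, "n_runs"] == 5

    pooled = []
    k = 0
    for pep in range(7):
        for r in range(5):
            pooled.append(PullingRunResult(f"CDP{pep}", "LEU8", "open",
                                           k < 14, first_anchor_frame=5
                                           if k < 14 else None))
            k += 1
    tab = anchor_probability(pooled)
    assert tab.loc[0, "n_runs"] == 35
    assert tab.loc[0, "probability"] == pytest.approx(14 / 35)


def test_anchor_probability_order_invariant_and_bounded():
    rng = np.random.default_rng(5)
    runs = [PullingRunResult(f"CDP{rng.integers(1, 9)}",
                             ("LEU3", "PHE5")[rng.integers(0, 2)],
                             ("open", "closed")[rng.integers(0, 2)],
                             bool(rng.integers(0, 2)), first_anchor_frame=1)
            for _ in range(60)]
    t1 = anchor_probability(runs)
    t2 = anchor_probability(runs[::-1])
    pd.testing.assert_frame_equal(t1, t2)
    assert ((t1["probability"] >= 0) & (t1["probability"] <= 1)).all()


def test_pulling_success_invariant():
    with pytest.raises(ValueError):
        PullingRunResult("CDP1", "LEU3", "open", True, first_anchor_frame=None)


def test_pulling_ensemble_detection_matches_truth():
    runs, truth = sd.generate_pulling_ensemble(24, 0.5, seed=2)
    results = [analyze_pulling_run(traj, t.peptide_id, t.pulled_residue)
               for (_, traj), t in zip(runs, truth)]
    assert all(r.success == t.success for r, t in zip(results, truth))
    assert all(r.start_conformation == t.start_conformation
               for r, t in zip(results, truth))
    for r in results:
        if r.success:
            assert r.first_anchor_frame is not None


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------

def test_timeline_four_step_order(four_step):
    """The full scripted permeation scenario yields the ordered timeline
    anchoring -> insertion -> closing -> crossing."""
    _, _, res = four_step
    primary = [e.type for e in res.events
               if e.type in ("anchoring", "insertion", "closing",
                             "crossing_permanent")]
    assert primary == ["anchoring", "insertion", "closing",
                       "crossing_permanent"]
    assert res.summary["inconsistencies"] == []
    assert res.summary["counts"]["anchoring"] == 1


def test_timeline_empty_and_order_invariance(four_step):
    assert assemble_timeline([])[0] == []
    _, _, res = four_step
    ev = list(res.events)
    rng = np.random.default_rng(7)
    shuffled = [ev[i] for i in rng.permutation(len(ev))]
    merged, _ = assemble_timeline(shuffled)
    assert [e.to_dict() for e in merged] == [e.to_dict() for e in ev]


def test_timeline_flags_closing_without_insertion():
    closing = EventRecord("closing", 50, 50)
    _, summary = assemble_timeline([closing])
    assert summary["inconsistencies"]


def test_event_record_validation():
    with pytest.raises(ValueError):
        EventRecord("anchoring", 0, 10)                 # no residue
    with pytest.raises(ValueError):
        EventRecord("insertion", 10, 5)                 # start after end
    with pytest.raises(ValueError):
        EventRecord("crossing_transient", 0, 5)         # no leaflets
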