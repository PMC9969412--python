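# Methods

This note documents the models, conventions and parameter choices behind
`permeatrace`, and what the synthetic-data generator does and does not
emulate.

## Coordinate conventions and membrane frame

All coordinates are stored in nm and times in ps regardless of the input
dialect (PDB/GRO structures, XTC/DCD or plain-text trajectories); frames
are 0-based internally, and event logs report both frame indices and
times. The membrane normal is fixed to the z-axis rather than fitted per
frame: the pipeline targets planar bilayer simulations with COM-motion
removal, where the bilayer stays flat and axis-aligned. Per frame, the
headgroup surface of each leaflet is the mean z of the choline-class
nitrogens and the tail-start surface the mean z of the carbons succeeding
the ester group. The bilayer center is defined as the midpoint of the two
tail-start surfaces — symmetric and robust to leaflet-asymmetric jitter,
since no standard definition exists. Lipids are assigned to leaflets by
the sign of their headgroup z relative to the midplane, with a ±0.2 nm
hysteresis band carrying the previous frame's assignment to avoid flicker
during the crossing analyses; a lipid sitting exactly on the midplane in
the first frame is an error rather than a guess. Area per lipid is box
XY area over lipids per leaflet.

Atom roles (peptide backbone, side chains per residue, headgroup
nitrogens, phosphates, ester carbons, tails, solvent) are resolved from
declarative residue-name/atom-name rules in a YAML config, so one
pipeline handles real lipid naming dialects and the synthetic
pseudo-lipids without code changes.

## Peptide descriptors

The backbone ellipse uses the Cα-equivalent beads by default (`backbone
definition "ca"`; "all" uses every backbone heavy atom — the literature
does not fix which atoms define the ellipse, so it is configurable). Axes
come from a second-moment (PCA) decomposition of the centered backbone
cloud rather than a least-squares ellipse fit: it is unique, fast and
rotation-equivariant. Axis signs follow a body-fixed convention — residue
1 projects positively on the major axis and the quarter-ring residue on
the minor axis — so the axes track the body through rotations. This is
what makes a 180° roll about the major axis (the A/B discriminator and
the crossing flip) observable; without a sign convention the normal
**a** = major × minor would be defined only up to sign. The arccos
argument of the orientation angle is clamped to [−1, 1] as a
floating-point guard. θ is reported raw in [0°, 180°] and folded to
[0°, 90°]; folding discards the **a**-sign and is what
parallel-vs-perpendicular plots use.

The entry-side normalization rotates the box 180° about x when the
peptide's first headgroup-slab contact is at the lower leaflet, so all
trajectories enter at the upper leaflet. It is implemented as a mirror of
y about the box midline and of z about the per-frame bilayer center,
which makes the transform an exact involution and leaves the bilayer in
place; mirror-symmetric descriptors (|z_com|, folded θ) are preserved
exactly.

## Conformation, register, lock

Closed/open classification uses the backbone RMSD to the closed reference
after optimal rigid superposition (Kabsch via SVD), with the 0.2 nm
threshold for the open state. The half-closed intermediate requires an
RMSD above threshold plus a nonempty strict subset of the four canonical
cross-ring hydrogen bonds with resolved register; the exact bond-count
boundary is not fixed by the literature and is configurable through the
canonical pattern. Hydrogen bonds use donor–acceptor heavy-atom distance
≤ 0.35 nm and donor–H–acceptor angle ≥ 150° (standard MD values; the
criterion is configurable), excluding ring-adjacent pairs (i, i±1); when
hydrogen positions are absent the criterion falls back to the heavy-atom
distance with a warning. A register shift is detected when the observed
donor→acceptor pairs form a nonempty subset of the canonical pattern
shifted by ±1 ring position (and not of the unshifted pattern).

The lock descriptor projects each bulky turn residue's side-chain
centroid onto the ring-plane normal oriented toward the aqueous phase
(+z in the upper leaflet, −z in the lower): unlocked iff all configured
residues point toward the aqueous side, locked iff at least one points
toward the membrane center, flipping exactly at zero projection. In the
full pipeline the lock label is reported as `n/a` while the peptide is
outside the membrane or not parallel to it: the descriptor is
membrane-referenced, and in the anchored perpendicular pose "toward the
membrane center" is not meaningful — gating it also prevents spurious
lock-release events at the insertion rotation.

## Orientation A/B, rotations, flip

A/B labelling is gated on the peptide COM being inside the headgroup
surfaces and the folded θ being at most 30° (ring parallel to the
membrane plane; equivalently at least 60° between the ring plane and the
membrane normal — no numeric boundary is published, so it is
configurable). The discriminator is the mean signed projection of the
reporter (proline-class) turn side chains on the aqueous-pointing ring
normal: B at projection ≥ 0 (toward the aqueous phase), A below. The
leaflet-dependent aqueous sign makes the label swap automatically when a
peptide crosses without rolling.

Rotation events are persistent A↔B label changes (both flanks at least
one dwell long); label changes that coincide with a midplane crossing are
excluded, because there the aqueous-relative label flips without any
physical roll. The flip detector accumulates the signed per-step rotation
of the minor axis about the instantaneous major axis over the crossing
transit (the frames with |z_com| inside the tail-start surfaces) and
declares a flip when the net roll is within ±45° of 180° and the first
label in the new leaflet is B.

Orientation fractions are percentages over A/B-labelled frames only and
sum to exactly 100; the equilibration cut defaults to 0 frames because
un-inserted frames are labelled `none` and therefore already excluded.
Occupancy heatmaps are plain counts over (distance to bilayer center,
folded θ) bins — the underlying ensembles are not equilibrated, so no
free-energy conversion is offered.

## Event detectors

All detectors work on per-frame masks or label series with dwell
requirements, converted from ns to frames by the trajectory stride:
anchoring 1 ns, insertion 2 ns, conformational events 1 ns, crossing
persistence 5 ns (transient crossings return within a few nanoseconds).
Interruptions up to 2 frames inside a run are bridged (`max_gap_frames`),
a hysteresis against single-frame noise. Label series are dwell-smoothed
(short runs replaced by the nearest persistent label) before transitions
are emitted, so per-frame flicker never becomes an event.

* **Anchoring**: any apolar side-chain heavy atom within 0.45 nm of a
  lipid tail atom (near the first minimum of typical heavy-atom RDFs;
  configurable) while the COM is above the upper headgroup surface.
  Residues are ranked by contact count over the event; attributes record
  the conformation at first contact and concurrent peptide–lipid
  hydrogen bonds (backbone N–H donors to phosphate/ester acceptors,
  tagged by moiety).
* **Insertion**: COM below the upper headgroup surface, persistent;
  attributes record the θ trace (perpendicular→parallel) and whether the
  final position lies at the headgroup/tail interface.
* **Conformational events**: closing (→closed), half-closing
  (open→half-closed), opening, and lock release (locked→unlocked), each
  with the orientation label and prior lock state at onset. The
  detectors do not assume closing starts in orientation B — a scripted
  closing in orientation A is reported as such; the B-preference is a
  property of data, not of the code.
* **Leaflet crossing**: sign changes of the COM z. Residence at or above
  the persistence threshold — or lasting to the end of the trajectory
  (end-truncation counts as permanent) — is permanent, otherwise
  transient; the return leg of a transient excursion is part of that
  event, not a second crossing. Attributes carry the destination-leaflet
  anchor residue (tail contacts in the new leaflet during the transit)
  and the flip result.

The timeline assembler merges all detector outputs chronologically,
counts events by type and by starting conformation, and flags
inconsistencies (e.g. a closing with no preceding insertion) without
dropping them.

Pulling-run success is defined as an anchoring event persisting to the
run's end (the operational definition is not published; it is exposed as
config). A run's starting conformation is the classification of its
first frame. Anchor probabilities pool runs across peptides sharing the
pulled residue, reporting successes/runs and the run count per cell.

## Headgroup-gap scanning

The scan reimplements grid-based packing-defect detection (no external
defect tool is wrapped). Cells are ~0.1 nm (the box is divided into an
integer number of cells so periodic tiling is exact). Looking from the
solvent side within a depth window (0.5 nm beyond the headgroup surface
down to 0.5 nm below the tail-start surface), the topmost atom whose
circular footprint covers a cell classifies it: headgroup/phosphate/ester
→ covered-polar, tail → exposed-apolar, none → empty. Footprint radii
are per role class (polar 0.62 nm, tail 0.45 nm): they represent the
union of the many real atoms a single pseudo-bead stands for, and are
sized so that an intact synthetic lattice is fully covered while one
removed headgroup opens a single connected defect. Gaps are 4-connected
exposed-apolar components with XY periodicity (components touching
across the box boundary merge); gap area is cell count × cell area —
the cell-count convention is simple and exactly matches the flood-fill
oracle used in testing. Lifetimes link gaps across consecutive frames by
≥ 1 overlapping cell; a vanished-and-reappeared gap is two tracks. The
size distribution is a normalized histogram with a least-squares fit of
log-probability vs area reporting the decay constant. Accessibility uses
the ≥ 0.23 nm² leucine-anchor threshold, boundary inclusive.

## Synthetic-data generator

The generator produces the study conditions every stage is tested under.
The bilayer is a square lattice of pseudo-lipids at 0.65 nm² per lipid
(POPC scale), 64 per leaflet by default, each with headgroup nitrogen at
|z| = 2.0 nm, phosphate 1.8 nm, ester carbon 1.5 nm and three tail beads
at 1.2/0.9/0.6 nm, with iid Gaussian thermal jitter of σ = 0.08 nm per
bead per frame. These values keep all descriptor magnitudes in the ranges
typical of real CDP/POPC trajectories. Scheduled "removed" headgroups
park their polar beads near the midplane (outside the scan's depth
window), exposing the tails beneath — the kinematics of a packing defect
without its energetics. A stiffness parameter divides the jitter to
emulate the direction of the cholesterol effect (fewer thermal gaps)
without modelling cholesterol.

The peptide is a 10-residue ring (sequence LEU-SER-LEU-SER-PHE-LEU-SER-
LEU-SER-PRO) of N/H/CA/O backbone beads plus one side-chain bead per
residue. The closed template is a flattened β-hairpin-like ring whose
four canonical cross-ring donor–acceptor contacts (1→9, 9→1, 3→7, 7→3)
sit at ~0.29 nm and near-linear angles; the open template is a splayed
ellipse (no contacts) at RMSD ≈ 0.36 nm from closed; the half-closed
template opens a wedge on one side (two bonds remain, RMSD ≈ 0.23 nm);
the register-shifted template rotates residues by one ring slot, which
both displaces the bond pattern by +1 and puts the RMSD above threshold.
The geometric margins (bond distance 0.05 nm under the cutoff, donor–H
lever arm 0.12 nm) are chosen so the default criteria classify the
intended state reliably at the default positional noise of σ = 0.015 nm;
event-level recovery is robust well beyond that (the consistency test
runs at σ = 0.05 nm), while per-frame hydrogen-bond patterns degrade
first — which is physical, and is what the dwell smoothing absorbs.

Scenarios are ordered kinematic phases (diffuse, approach, anchor,
insert, rotate-parallel, set-orientation, set-lock, half-close/close/
open/register-shift, cross, return, hold) driving the rigid ring through
pose interpolations (quaternion slerp; 180° rolls about the instantaneous
major axis). Phase order is validated (e.g. a close before an insert is
rejected with the violation listed). Ground truth (events, per-frame
conformation/orientation/lock labels) is derived from the scripted
noise-free state sequence using the same interval semantics as the
detectors. Anchored poses align the anchor residue's side-chain direction
to −z over a gap site, with the COM height set from the side-chain reach
so the contact criterion is met while the COM stays above the headgroup
surface. The default frame stride is 100 ps, so the default dwells are
10/20/10/50 frames.

What the generator does **not** emulate: forces, thermostats, realistic
diffusion or kinetics (frames are independent jitter around scripted
states), water, lipid chemistry, membrane undulations, or the absolute
event rates of production MD ensembles. Passing tests therefore show
that the descriptors and detectors recover what the geometry encodes —
not that the thresholds are optimal for any particular force field; on
real data the configurable criteria (H-bond geometry, contact cutoff,
dwells, grid radii) are the knobs to revisit.

## Problem sizes used in tests and acceptance

Scripted scenarios use 64 lipids/leaflet and 100–275 frames; the
orientation-occupancy recovery uses 10⁴ frames on a 16-lipid/leaflet
patch; pulling ensembles use 200 runs of 60 frames on 36 lipids/leaflet;
gap statistics use 200 frames at removal rate 0.04 (≈ 500 gaps). These
sizes give stable statistics (binomial and KS criteria pass with wide
margins) at about a minute of total runtime for the acceptance script.

## Known limitations

* The flat-membrane assumption (normal ≡ z) breaks on curved or
  undulating membranes; no surface fitting is provided.
* Contact detection does not apply the XY minimum-image convention; the
  peptide is assumed away from the box edge (true for the generator, and
  for centered real trajectories).
* The lock and A/B descriptors are undefined (reported `n/a`/`none`)
  outside the in-membrane parallel regime by construction.
* Gap areas use the cell-count convention; alpha-shape areas would differ
  slightly for ragged defects.
* Masses default to 1 for bead systems without topology masses, making
  the mass-weighted COM coincide with the geometric one there.
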