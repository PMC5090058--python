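# Methods

## The scanning procedure

A docking engine samples ligand poses inside a box; the score of a pose is
determined only by receptor atoms within the engine's interaction cutoff
(8 Å for AutoDock Vina). Tomographic scanning exploits this locality: a
cubic box of edge *E* (default 18 Å, always larger than the cutoff) is
advanced along the pocket depth in steps of Δ (default 1 Å), and a full,
independent docking experiment is executed at every step. Early boxes
expose only the pocket mouth; each subsequent box adds a 1 Å slab of
receptor. The series of best poses across steps is a pseudo-temporal
account of descent: it shows where a ligand first makes productive
contacts, over which depth range its pose is stationary (a *plateau*), and
at which step newly included atoms pull it into a different pose.

**Scan axis.** The box must advance along the pocket depth while staying
world-axis-aligned (the docking-engine convention). The axis is taken to be
the receptor's principal axis of inertia with the largest |cosine| to the
vector from the mouth-reference centroid to the bottom-reference centroid,
sign-oriented toward the bottom. Inertia is mass-weighted by element by
default (unit-mass optional); if two principal axes tie within 1e-6 the
code refuses and asks for an explicit `axis_override`. The whole system is
then rotated so the axis is exactly +z with the mouth centroid at the
origin; the transform is recorded so outputs can be mapped back.

**Box sequence.** Box 1 is placed with its leading (deepest) face tangent
to the deepest mouth-reference atom plus an optional `start_margin`; the
lateral center is the mouth-reference centroid (overridable). Boxes advance
by exactly Δ in z; the last box is the first whose closed interior contains
every bottom-reference atom. The number of steps is therefore emergent from
the geometry, not fixed. Box membership uses a closed boundary (an atom on
a face counts as inside); this convention changes new-atom counts by ±1 at
exact tangencies and is applied consistently everywhere.

**Repetitions.** Docking is stochastic, so each step is repeated
(production default 100, desk default 5) with derived seeds
`base + 1000·step + repetition`, making any single run reproducible in
isolation. The per-step representative is the pose with the lowest score
over all repetitions (exact ties: lowest repetition index, then lowest pose
rank). Per-step results are persisted as JSON and a rerun with an unchanged
provenance hash resumes from disk.

## Analysis

**Step metrics.** For each step's best pose: *depth* = ligand centroid z
(mouth = 0); *orientation* = angle between the ring-plane normal (the
smallest-variance direction of the least-squares plane through a named set
of ring atoms) and the scan axis, folded into [0°, 90°] — 0° means the ring
lies parallel to the pocket base, 90° means it is perpendicular (the
engagement orientation); *niche engagement* = any non-ring ("tail") atom
within a cutoff (default 4.0 Å, a typical polar-contact distance) of any
niche-residue atom.

**Change flags.** Step 1 is always flagged (pocket entry). Step k ≥ 2 is
flagged when, relative to step k−1, |Δdepth| > 0.5 Å, or in-frame RMSD (no
superposition) > 1.0 Å, or |Δ orientation| > 20°. These thresholds are
deliberate operational choices — the underlying phenomenon is qualitative
("the pose changed") — and all three are configuration keys reported in
output headers. *Plateaus* are maximal runs of unflagged steps merged with
the preceding flagged step; they partition the step range.

**Filter candidates.** The atom-inclusion table records, for every
pocket-lining atom (heavy atoms by default), the first step at which it
enters a box, aggregated to per-residue new-atom counts per step. A residue
becomes a filter candidate when it contributes at least `min_new_atoms`
(default 3) newly included atoms at an interior flagged step or within
`window` (default 1) steps before it — i.e. the pose demonstrably responded
where the residue arrived. Residues whose atoms arrive only during plateaus
are excluded on the same evidence: the pose did not respond to them.
Engagement-niche members are reported separately, never as filter members,
whatever their counts. Candidates are ranked by (number of triggering
flagged steps, new-atom count) and carry a polarity annotation and a
generated rationale.

**Classification.** A ligand is labelled *binder-like* when (a) some
plateau has the tail engaged in the niche with ring orientation ≥ 90° −
20° at every step of the plateau, and (b) the final plateau's mean depth
reaches a base-depth threshold. Both criteria are reported individually.
This is a label for the descent mechanism, not a binding-affinity
prediction — note that non-binders typically *do* dock at the base once the
box reaches it, because docking accepts any geometrically accessible pose;
it is the missing engagement step that separates them.

## The synthetic system

The toy receptor is a tube of apolar carbon (radius 7 Å, depth 14 Å, mouth
at z = 0) with three planted features:

* an **engagement niche**: a lateral channel in the +x wall (plate walls at
  ±2.9 Å, lids and a back plate enclosing it) ending in a row of three
  hydrogen-bond acceptors. The channel half-width admits a planar ligand
  edge-on (its plane clears both walls) but clashes the out-of-plane bulk
  of the blocked ligand in every rotation about its tail axis, and it caps
  the ring twist at about ±17°, so an engaged ring is necessarily within
  ~73–90° of perpendicular. Two "guard" atoms on the channel centreline pin
  the in-plane swing of the engaged pose, so the engagement plateau has one
  well-defined depth;
* a **constriction** at z = 6.7 Å: ten apolar atoms on a 5.5 Å-radius ring,
  grouped into the only two residues in the structure with ≥ 3 atoms
  (besides the niche acceptors, which the analysis reports separately).
  Every other structural residue is deliberately split into ≤ 2-atom
  pieces, so no incidental wall residue can ever reach the candidate
  threshold — recovery of exactly the planted residues is guaranteed by
  construction, not tuned. The constriction depth is chosen so it enters
  the box at the step where the basal pose first becomes reachable;
* a **basal site**: six acceptors on a small ring just above the floor,
  centred on a slightly off-axis descent lane, strong enough (score ≈ −6)
  to out-compete the niche (score ≈ −3) once the box is deep enough.

The niche assembly is mirrored at −x with inert carbon (plus a small
counterweight for the off-axis basal site), cancelling the products of
inertia so the principal-axis determination recovers the tube axis exactly.
The two ligands share a six-carbon aromatic ring and a linear tail ending
in a donor; the blocked ligand adds two out-of-plane carbons on the tail.
Coordinates carry 0.03 Å Gaussian jitter derived from the seed.

What the toy system does *not* emulate: real packing density (its walls are
sparse atom lattices), torsional ligand flexibility (the toy engine is
rigid-body; flexibility is delegated to the external engine), solvation,
and realistic energetics. Passing tests therefore demonstrate that the
*orchestration and analysis* are correct — that the scan geometry, the
trajectory reduction, the flag/inclusion crossing and the classification
recover a known mechanism — not that any particular real ligand binds.

## The built-in toy engine

The toy score is a fixture convention, not a physical claim: over
receptor–ligand atom pairs within 8 Å, a soft-sphere clash penalty
`10·max(0, 2.5 − d)²` plus a Gaussian attraction `−exp(−(d − 3)²)` between
label-matched pharmacophore pairs (donor↔acceptor, aromatic↔aromatic).
Labels come from explicit annotations or default by element (N donor,
O/S acceptor, else apolar). The score is exactly additive, continuous, and
local.

The search is rigid-body: scrambled-Halton translations × uniform random
rotations inside the box, two-thirds of them *aimed* — placed near a
receptor atom that can attract some ligand atom, approached along that
atom's open directions (rays whose probe points 2.5–5.5 Å out are
clash-free), with the ligand rotated so the matching atom faces it and the
free twist about the aiming axis pre-scanned. Aiming is what makes enclosed
sub-pockets discoverable at all: uniform sampling essentially never threads
a narrow channel. The best starts — stratified so every aimed-at receptor
atom keeps refinement slots, with near-duplicates merged — are refined by
bounded L-BFGS-B over the six rigid degrees of freedom. Sample count scales
with `exhaustiveness`; identical seeds give bit-identical pose lists.

## Full-fidelity protocol for a real receptor

For TIR1: download PDB 2P1M, strip waters, excise the ASK1 adaptor chain
(keep the chain carrying Phe-351/Arg-403; `tomodock.presets.find_tir1_chain`
identifies it), keep the InsP6 cofactor, and prepare PDBQT files with
AutoDockTools. Ligands are accepted pre-prepared (protonation and charge
assignment are upstream of this package). Then:

```bash
tomodock scan --receptor tir1.pdbqt --ligand iaa.pdbqt \
    --pocket tir1_pocket.yaml --engine vina \
    --edge 18 --step 1.0 --reps 100 --exhaustiveness 16 \
    --seed 1 --out tir1_iaa/
```

with `tir1_pocket.yaml` generated from `tomodock.presets` (seven lining
ranges 77–84, 344–354, 377–381, 403–410, 436–441, 462–465, 489–490; mouth
Phe-351; bottom Arg-403). This configuration — the package default — is the
production protocol; at roughly 1500 Vina runs per ligand it is a
multi-hour computation and is exercised by the test suite only at the level
of configuration fidelity and adapter parsing.

## Numerical choices and limitations

* Depth conventions: heavy-atom residue centroids by default, Cα–Cα as the
  alternative; both are reported side by side, since the atom pair behind a
  quoted pocket depth is rarely stated.
* Alternate locations: highest occupancy wins, first on ties. Hydrogens are
  kept on parse; the inclusion table counts heavy atoms unless configured
  otherwise.
* Never-included atoms (laterally outside every box, or deeper than the
  final leading face) carry a reserved sentinel step and export as "none".
* Desk-scale runs in this repository use 5 repetitions over ~15 steps and
  three seeds; the analysis itself is scale-free and the production default
  remains 100 repetitions.
* The change thresholds, the new-atom threshold and the engagement cutoff
  are heuristics; conclusions should be checked for stability under
  reasonable variations of them (all are exposed as parameters).
* The receptor is treated as rigid throughout; adapting the scan to
  side-chain flexibility is possible in principle but unimplemented.
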