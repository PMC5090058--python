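"""Synthetic receptors and ligands with planted ground truth.

The toy receptor is a tubular pocket along +z (mouth at z = 0, floor at
z = depth) decorated with the three features the scanning method is meant to
detect:

* an **engagement niche** — a narrow lateral channel in the +x wall holding a
  row of hydrogen-bond acceptors.  The channel is walled closely enough that
  only a planar ligand inserted edge-on (ring plane containing the tube
  axis, i.e. perpendicular to the pocket base) can bring its donor tail
  within contact distance; a ligand with out-of-plane bulk on its tail is
  kept out;
* a **constriction ring** (the planted selectivity filter) at mid depth,
  placed so it enters the search box exactly around the step at which the
  basal binding pose first becomes reachable;
* a **basal attraction site** — a ring of acceptors just above the floor
  that the donor tail binds once the search box is deep enough.

Every structural residue is split into at-most-two-atom pieces except the
planted filter residues (and the niche acceptors, which the analysis reports
separately), so no incidental wall residue can ever reach the new-atom
threshold of the filter identification — candidate recovery is guaranteed by
construction, not by tuning.

The +x niche assembly is mirrored at −x with inert carbon so the receptor's
products of inertia vanish and its principal axes coincide with the
coordinate axes; the scan-axis determination therefore recovers +z exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analysis import NicheDefinition
from .geometry import PocketDefinition
from .structures import Atom, ResidueRef, Structure

__all__ = ["ToyPocketSpec", "ToyLigand", "make_toy_pocket", "make_toy_ligands"]

CHAIN = "A"


@dataclass
class ToyPocketSpec:
    """Parameters of the planted toy pocket (all lengths in Å)."""

    depth: float = 14.0
    tube_radius: float = 7.0
    ring_spacing: float = 1.4
    atoms_per_ring: int = 14
    niche_z: float = 3.0          # depth of the engagement niche channel
    niche_x: float = 8.5          # radial position of the niche acceptors
    filter_z: float = 6.7         # depth of the planted constriction
    filter_aperture: float = 5.5  # constriction radius
    base_z: float = 12.8          # depth of the basal acceptor ring
    base_radius: float = 2.0
    base_offset: float = -1.8      # lateral x of the basal site (descent lane)
    base_depth_threshold: float = 6.0  # classification depth criterion
    jitter: float = 0.03          # coordinate noise, Å
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.niche_z < self.filter_z < self.base_z < self.depth):
            raise ValueError(
                "require 0 < niche_z < filter_z < base_z < depth "
                f"(got {self.niche_z}, {self.filter_z}, {self.base_z}, "
                f"{self.depth})"
            )
        if self.filter_aperture >= self.tube_radius:
            raise ValueError("filter aperture must be narrower than the tube")
        if self.depth < 5.0:
            raise ValueError("pocket too shallow for a multi-step scan")
        if self.ring_spacing <= 0 or self.atoms_per_ring < 6:
            raise ValueError("degenerate wall geometry")


class _Builder:
    """Accumulates atoms, assigning serials and residue numbers."""

    def __init__(self, rng: np.random.Generator, jitter: float):
        self.atoms: list[Atom] = []
        self.rng = rng
        self.jitter = jitter
        self._resseq = 0

    def residue(self, resn: str, positions: list[tuple], element: str = "C",
                label: str = "apolar") -> int:
        self._resseq += 1
        for i, pos in enumerate(positions, start=1):
            xyz = np.asarray(pos, dtype=float)
            if self.jitter > 0:
                xyz = xyz + self.rng.normal(0.0, self.jitter, size=3)
            self.atoms.append(
                Atom(
                    serial=len(self.atoms) + 1,
                    name=f"{element.upper()}{i}",
                    element=element,
                    residue_name=resn,
                    residue_seq=self._resseq,
                    chain=CHAIN,
                    coords=tuple(float(v) for v in xyz),
                    pharm_label=label,
                )
            )
        return self._resseq

    def chunked(self, resn: str, positions: list[tuple], element: str = "C",
                label: str = "apolar", size: int = 2) -> list[int]:
        """Split positions into residues of at most ``size`` atoms."""
        out = []
        for k in range(0, len(positions), size):
            out.append(self.residue(resn, positions[k : k + size], element, label))
        return out


def _ring(radius: float, z: float, n: int, skip_azimuth0: bool = False) -> list[tuple]:
    pts = []
    for j in range(n):
        az = 2 * np.pi * j / n
        if skip_azimuth0 and (j == 0 or (n % 2 == 0 and j == n // 2)):
            continue
        pts.append((radius * np.cos(az), radius * np.sin(az), z))
    return pts


def make_toy_pocket(
    spec: ToyPocketSpec | None = None,
) -> tuple[Structure, PocketDefinition, NicheDefinition, list[ResidueRef], dict]:
    """Build the toy receptor; returns structure, pocket/niche definitions,
    the planted filter residues, and a ground-truth manifest."""
    spec = spec or ToyPocketSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder(rng, spec.jitter)
    R, zn, zf = spec.tube_radius, spec.niche_z, spec.filter_z

    # mouth and bottom reference residues: the azimuth-0/180 pair of the
    # first and last wall rings (two atoms each, z exactly 0 and depth)
    mouth_seq = b.residue("MTH", [(R, 0.0, 0.0), (-R, 0.0, 0.0)])
    bottom_seq = b.residue("BTM", [(R, 0.0, spec.depth), (-R, 0.0, spec.depth)])

    # tube wall: rings of apolar carbon, split into 2-atom residues; the
    # azimuth-0/180 atoms of rings near the niche are omitted (channel mouth)
    n_rings = int(round(spec.depth / spec.ring_spacing)) + 1
    for k in range(n_rings):
        z = k * spec.ring_spacing
        near_niche = abs(z - zn) <= 1.9 and z not in (0.0,)
        skip_ref = k == 0 or k == n_rings - 1  # reference pair already placed
        pts = _ring(R, z, spec.atoms_per_ring, skip_azimuth0=near_niche or skip_ref)
        b.chunked("WAL", pts)

    # floor disc
    floor = [(0.0, 0.0, spec.depth)]
    floor += _ring(R / 3.0, spec.depth, 6)
    floor += _ring(2 * R / 3.0, spec.depth, 10)
    b.chunked("FLR", floor)

    # engagement-niche channel at +x, mirrored inertly at -x
    def channel(sign: float, acceptor: bool) -> list[int]:
        seqs: list[int] = []
        xs = np.arange(2.2, spec.niche_x + 0.35, 1.1)
        side = [(sign * x, sy * 2.9, zn + dz)
                for x in xs for sy in (1.0, -1.0)
                for dz in (-1.5, -0.75, 0.0, 0.75, 1.5)]
        seqs += b.chunked("PLT" if sign > 0 else "PLM", side)
        lidx = np.linspace(R, spec.niche_x + 2.9, 5)
        lidy = np.linspace(-3.9, 3.9, 7)
        lids = [(sign * x, y, zn + dz)
                for x in lidx for y in lidy for dz in (2.4, -2.4)]
        seqs += b.chunked("LID" if sign > 0 else "LIM", lids)
        back = [(sign * (spec.niche_x + 2.9), y, zn + dz)
                for y in lidy for dz in (-1.5, 0.0, 1.5)]
        seqs += b.chunked("BCK" if sign > 0 else "BCM", back)
        return seqs

    channel(+1.0, acceptor=True)
    channel(-1.0, acceptor=False)

    # niche acceptors: one 3-atom oxygen residue deep in the +x channel
    # (its mirror is inert carbon so the inertia products still cancel)
    niche_pts = [(spec.niche_x, -0.9, zn), (spec.niche_x, 0.0, zn),
                 (spec.niche_x, 0.9, zn)]
    niche_seq = b.residue("NIC", niche_pts, element="O", label="acceptor")
    b.chunked("NCM", [(-x, y, z) for x, y, z in niche_pts])

    # the planted constriction: a ring of apolar atoms at mid depth,
    # deliberately the only residues large enough to trigger the
    # new-atom threshold of the filter identification
    filt_pts = _ring(spec.filter_aperture, zf, 10)
    filt_seqs = [
        b.residue("FLT", filt_pts[:5]),
        b.residue("FLT", filt_pts[5:]),
    ]

    # swing guards: two apolar atoms on the niche centreline that pin the
    # engaged ligand's in-plane swing about its anchored donor, so the
    # engagement plateau has a single well-defined pose
    b.residue("GRD", [(1.5, 0.0, zn - 3.9), (1.5, 0.0, zn + 3.9)])

    # basal acceptors: ring just above the floor, centred on the descent
    # lane; a small carbon counterweight keeps the products of inertia zero
    base_pts = [(x + spec.base_offset, y, z)
                for x, y, z in _ring(spec.base_radius, spec.base_z, 6)]
    b.chunked("BSE", base_pts, element="O", label="acceptor")
    cw_x = -(16.0 * sum(p[0] for p in base_pts)) / (2 * 12.011)
    b.residue("CWT", [(cw_x, 1.0, spec.base_z), (cw_x, -1.0, spec.base_z)])

    receptor = Structure(b.atoms, id="toy_pocket")
    pocket = PocketDefinition(
        lining_ranges=[(CHAIN, 1, b._resseq)],
        mouth_ref=ResidueRef(CHAIN, mouth_seq, "MTH"),
        bottom_ref=ResidueRef(CHAIN, bottom_seq, "BTM"),
    )
    niche = NicheDefinition(
        residues=[ResidueRef(CHAIN, niche_seq, "NIC")],
        engagement_cutoff=4.0,
    )
    filter_refs = [ResidueRef(CHAIN, s, "FLT") for s in filt_seqs]

    truth = {
        "filter_residues": [
            {"chain": CHAIN, "resi": s, "resn": "FLT"} for s in filt_seqs
        ],
        "niche_residues": [{"chain": CHAIN, "resi": niche_seq, "resn": "NIC"}],
        "base_depth": spec.base_depth_threshold,
        "pocket_depth": spec.depth,
        "niche_z": zn,
        "filter_z": zf,
        "base_z": spec.base_z,
        "seed": spec.seed,
    }
    return receptor, pocket, niche, filter_refs, truth


@dataclass
class ToyLigand:
    structure: Structure
    ring_atoms: list[str]

    @property
    def tail_atoms(self) -> list[str]:
        return [a.name for a in self.structure.atoms if a.name not in self.ring_atoms]


def _ligand(atoms_spec: list[tuple], lig_id: str) -> Structure:
    atoms = [
        Atom(serial=i + 1, name=name, element=element, residue_name="LIG",
             residue_seq=1, chain="L", coords=xyz, is_hetero=True,
             pharm_label=label)
        for i, (name, element, label, xyz) in enumerate(atoms_spec)
    ]
    return Structure(atoms, id=lig_id)


def make_toy_ligands(spec: ToyPocketSpec | None = None) -> tuple[ToyLigand, ToyLigand]:
    """The passing and the blocked ligand.

    Both share a planar six-membered aromatic ring and a linear tail ending
    in a hydrogen-bond donor (tip 4.0 Å from the ring centre).  The blocked
    ligand additionally carries two out-of-plane carbon atoms on the tail,
    which keep it from inserting the tail into the niche channel in any
    orientation; the passing ligand clears both the channel and the planted
    constriction when its ring is perpendicular to the pocket base.
    """
    spec = spec or ToyPocketSpec()
    ring = [
        (f"C{i + 1}", "C", "aromatic",
         (1.4 * np.cos(np.pi * i / 3), 1.4 * np.sin(np.pi * i / 3), 0.0))
        for i in range(6)
    ]
    tail = [("CT", "C", "apolar", (2.7, 0.0, 0.0)),
            ("NT", "N", "donor", (4.0, 0.0, 0.0))]
    bulk = [("CB1", "C", "apolar", (2.7, 0.0, 1.4)),
            ("CB2", "C", "apolar", (2.7, 0.0, -1.4))]
    ring_names = [r[0] for r in ring]
    passing = ToyLigand(_ligand(ring + tail, "toy_ligand_passing"), ring_names)
    blocked = ToyLigand(_ligand(ring + tail + bulk, "toy_ligand_blocked"), ring_names)
    return passing, blocked


def write_fixture_files(out_dir: str | Path, spec: ToyPocketSpec | None = None) -> dict:
    """Emit the toy system as PDB + YAML + truth JSON files (CLI helper)."""
    from .structures import write_pose_model

    spec = spec or ToyPocketSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    receptor, pocket, niche, filter_refs, truth = make_toy_pocket(spec)
    passing, blocked = make_toy_ligands(spec)

    class _P:  # minimal pose shim for the writer
        def __init__(self, coords):
            self.coords, self.score = coords, 0.0

    write_pose_model([_P(receptor.coords)], receptor, out / "receptor.pdb")
    write_pose_model([_P(passing.structure.coords)], passing.structure,
                     out / "ligand_passing.pdb")
    write_pose_model([_P(blocked.structure.coords)], blocked.structure,
                     out / "ligand_blocked.pdb")

    import yaml

    pocket_yaml = {
        "chain": CHAIN,
        "ranges": [[lo, hi] for (_, lo, hi) in pocket.lining_ranges],
        "mouth_ref": {"resi": pocket.mouth_ref.residue_seq,
                      "resn": pocket.mouth_ref.residue_name},
        "bottom_ref": {"resi": pocket.bottom_ref.residue_seq,
                       "resn": pocket.bottom_ref.residue_name},
    }
    (out / "pocket.yaml").write_text(yaml.safe_dump(pocket_yaml))
    niche_yaml = {
        "residues": [{"chain": r.chain, "resi": r.residue_seq,
                      "resn": r.residue_name} for r in niche.residues],
        "engagement_cutoff": niche.engagement_cutoff,
    }
    (out / "niche.yaml").write_text(yaml.safe_dump(niche_yaml))
    truth = dict(truth, ring_atoms=passing.ring_atoms)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def run_toy_study(
    seed: int,
    repetitions: int = 5,
    exhaustiveness: int = 16,
    spec: ToyPocketSpec | None = None,
):
    """Run the complete planted-truth study at one seed.

    Builds the toy pocket and both ligands, scans each with the built-in
    engine (the seed drives both the fixture jitter and the docking
    searches), and returns ``(outcome_passing, outcome_blocked, truth)``
    with the analysis fields filled in.
    """
    from .engines import MockEngine
    from .scan import ScanConfig
    from .workflow import tomographic_scan

    spec = spec or ToyPocketSpec(seed=seed)
    receptor, pocket, niche, filter_refs, truth = make_toy_pocket(spec)
    passing, blocked = make_toy_ligands(spec)
    truth = dict(truth, ring_atoms=passing.ring_atoms)
    outcomes = []
    for lig in (passing, blocked):
        cfg = ScanConfig(repetitions=repetitions,
                         exhaustiveness=exhaustiveness, seed=seed)
        outcomes.append(
            tomographic_scan(
                receptor, lig.structure, pocket, cfg, MockEngine(),
                niche=niche, ring_atoms=lig.ring_atoms,
                base_depth=truth["base_depth"],
            )
        )
    return outcomes[0], outcomes[1], truth
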