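"""Molecular structures, residue selection and rigid transforms.

The atom model is deliberately flat: a :class:`Structure` is an ordered list
of :class:`Atom` records, as read from PDB or AutoDock PDBQT files.  Residue
grouping is recovered from the per-atom annotation; residue contiguity in the
file is never assumed.  All coordinates are in Ångström.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "ResidueRef",
    "RigidTransform",
    "StructureFormatError",
    "parse_structure",
    "select_residues",
    "select_chains",
    "apply_transform",
    "write_pose_model",
    "read_pose_models",
]

#: residue names treated as water by the ``strip_water`` option
WATER_RESNAMES = frozenset({"HOH", "WAT"})

#: map from AutoDock atom types to chemical elements (PDBQT files carry the
#: AutoDock type, not the element, in the trailing column)
_AUTODOCK_ELEMENTS = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N",
    "OA": "O", "OS": "O", "O": "O", "SA": "S", "S": "S",
    "H": "H", "HD": "H", "HS": "H", "P": "P", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "MG": "Mg", "MN": "Mn",
    "ZN": "Zn", "CA": "Ca", "FE": "Fe",
}


class StructureFormatError(ValueError):
    """Raised for unparseable or empty structure files."""


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record.

    ``pharm_label`` is an optional pharmacophore annotation
    (``donor``/``acceptor``/``aromatic``/``apolar``) used by the built-in
    toy scoring function; real structures leave it ``None`` and the engine
    derives a default from the element.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    coords: tuple[float, float, float]
    insertion_code: str = ""
    alt_loc: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0
    partial_charge: float | None = None
    pharm_label: str | None = None

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Structure:
    """An ordered, annotated atom collection (receptor or ligand)."""

    atoms: list[Atom]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureFormatError(f"structure {self.id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same annotation)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            dataclasses.replace(a, coords=tuple(xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, id=self.id)

    def subset(self, indices: Sequence[int], id_suffix: str = "subset") -> "Structure":
        atoms = [self.atoms[i] for i in indices]
        return Structure(atoms, id=f"{self.id}/{id_suffix}" if self.id else id_suffix)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Map residue id -> atom indices, in order of first appearance."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_id, []).append(i)
        return out

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]


@dataclass(frozen=True)
class ResidueRef:
    """Reference to a single residue, e.g. the pocket-mouth Phe or bottom Arg."""

    chain: str
    residue_seq: int
    residue_name: str | None = None

    def resolve(self, s: Structure) -> list[int]:
        """Atom indices of this residue in ``s``; validates the residue name."""
        idx = [
            i
            for i, a in enumerate(s.atoms)
            if a.chain == self.chain and a.residue_seq == self.residue_seq
        ]
        if not idx:
            raise KeyError(
                f"residue {self.chain}:{self.residue_seq} not found in "
                f"structure {s.id!r}"
            )
        if self.residue_name is not None:
            found = {s.atoms[i].residue_name for i in idx}
            if self.residue_name not in found:
                raise KeyError(
                    f"residue {self.chain}:{self.residue_seq} has name(s) "
                    f"{sorted(found)}, expected {self.residue_name}"
                )
        return idx

    def centroid(self, s: Structure, heavy_only: bool = True) -> np.ndarray:
        idx = self.resolve(s)
        if heavy_only:
            heavy = [i for i in idx if not s.atoms[i].is_hydrogen]
            idx = heavy or idx
        return s.coords[idx].mean(axis=0)


class RigidTransform:
    """A proper rigid motion x' = R x + t with R orthonormal, det(R) = +1."""

    def __init__(self, rotation: np.ndarray, translation: np.ndarray):
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float).reshape(3)
        if rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal (tol 1e-8)")
        if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-8):
            raise ValueError("rotation matrix must have determinant +1")
        self.rotation = rotation
        self.translation = translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# parsing


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".pdbqt":
        return "pdbqt"
    return "pdb"


def _parse_atom_line(line: str, lineno: int, fmt: str) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip()
        residue_seq = int(line[22:26])
        insertion_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError) as exc:
        raise StructureFormatError(
            f"line {lineno}: unparseable {fmt.upper()} atom record: {line.rstrip()!r}"
        ) from exc

    partial_charge: float | None = None
    if fmt == "pdbqt":
        tail = line[66:].split()
        if not tail:
            raise StructureFormatError(
                f"line {lineno}: PDBQT record missing charge/type columns"
            )
        try:
            partial_charge = float(tail[0])
        except ValueError as exc:
            raise StructureFormatError(
                f"line {lineno}: unparseable PDBQT partial charge {tail[0]!r}"
            ) from exc
        ad_type = tail[1].upper() if len(tail) > 1 else ""
        element = _AUTODOCK_ELEMENTS.get(ad_type, "")
        if not element:
            element = _element_from_name(name)
    else:
        element = line[76:78].strip() if len(line) >= 77 else ""
        if not element:
            element = _element_from_name(name)

    if not element:
        raise StructureFormatError(
            f"line {lineno}: cannot determine element for atom {name!r}"
        )
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise StructureFormatError(f"line {lineno}: non-finite coordinates")

    return Atom(
        serial=serial,
        name=name,
        element=element.capitalize(),
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain=chain,
        coords=(x, y, z),
        insertion_code=insertion_code,
        alt_loc=alt_loc,
        is_hetero=line.startswith("HETATM"),
        occupancy=occupancy,
        partial_charge=partial_charge,
    )


def _element_from_name(name: str) -> str:
    # PDB atom names encode the element in the leading characters; digits and
    # greek-position letters follow it (e.g. "CA", "1HB", "NE2").
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _dedupe_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom site: highest occupancy, first on ties."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain, a.residue_seq, a.insertion_code, a.residue_name, a.name)
        if key not in best:
            best[key] = i
        elif a.occupancy > atoms[best[key]].occupancy:  # first wins ties
            best[key] = i
    keep = sorted(best.values())
    return [dataclasses.replace(atoms[i], alt_loc="") for i in keep]


def parse_structure(
    path: str | Path,
    fmt: str | None = None,
    *,
    strip_water: bool = False,
    model: int = 1,
) -> Structure:
    """Read a PDB or PDBQT file into a :class:`Structure`.

    PDBQT ROOT/BRANCH torsion-tree records are tolerated and ignored (poses
    are analysed rigidly).  For multi-model files only ``model`` is read.
    ``strip_water`` drops HOH/WAT residues.  Alternate locations are reduced
    to the highest-occupancy conformer (first on ties).
    """
    path = Path(path)
    if fmt is None:
        fmt = _guess_format(path)
    if fmt not in ("pdb", "pdbqt"):
        raise ValueError(f"unknown structure format {fmt!r}")

    atoms: list[Atom] = []
    current_model = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                try:
                    current_model = int(line.split()[1])
                except (IndexError, ValueError):
                    current_model += 1
            elif rec in ("ATOM", "HETATM") and current_model == model:
                atom = _parse_atom_line(line, lineno, fmt)
                if strip_water and atom.residue_name in WATER_RESNAMES:
                    continue
                atoms.append(atom)
    if not atoms:
        raise StructureFormatError(f"no atoms parsed from {path}")
    atoms = _dedupe_alt_locs(atoms)
    return Structure(atoms, id=path.stem)


# ---------------------------------------------------------------------------
# selection


ResidueRange = tuple[str, int, int]  # (chain, first_seq, last_seq) inclusive


def _normalize_selector(
    sel: "ResidueRef | ResidueRange",
) -> tuple[str, int, int]:
    if isinstance(sel, ResidueRef):
        return (sel.chain, sel.residue_seq, sel.residue_seq)
    chain, start, end = sel
    return (chain, int(start), int(end))


def select_residues(
    s: Structure,
    selectors: Iterable["ResidueRef | ResidueRange"],
) -> Structure:
    """Subset of ``s`` whose (chain, residue_seq) fall in any selector.

    Selectors are :class:`ResidueRef` objects or inclusive ``(chain, start,
    end)`` ranges.  Atom order is preserved and atoms matched by several
    selectors appear once.  A selector matching no atoms is an error.
    """
    ranges = [_normalize_selector(sel) for sel in selectors]
    if not ranges:
        raise ValueError("no residue selectors given")
    matched: list[int] = []
    hit = [False] * len(ranges)
    for i, a in enumerate(s.atoms):
        for j, (chain, start, end) in enumerate(ranges):
            if a.chain == chain and start <= a.residue_seq <= end:
                hit[j] = True
                matched.append(i)
                break
    for j, ok in enumerate(hit):
        if not ok:
            chain, start, end = ranges[j]
            raise KeyError(
                f"residue range {chain}:{start}-{end} matches no atoms in "
                f"structure {s.id!r}"
            )
    return s.subset(matched, id_suffix="sel")


def select_chains(s: Structure, chains: Iterable[str]) -> Structure:
    """Keep only the given chains (e.g. excise a co-expressed adaptor)."""
    chains = set(chains)
    idx = [i for i, a in enumerate(s.atoms) if a.chain in chains]
    if not idx:
        raise KeyError(f"chains {sorted(chains)} match no atoms in {s.id!r}")
    return s.subset(idx, id_suffix="+".join(sorted(chains)))


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Rigidly move a structure; all annotation is unchanged."""
    return s.with_coords(t.apply(s.coords))


# ---------------------------------------------------------------------------
# pose model I/O


def write_pose_model(poses: Sequence, template: Structure, path: str | Path) -> None:
    """Write poses as a multi-model PDB file.

    ``poses`` are objects with ``coords`` (atom array matching ``template``'s
    atom order) and ``score`` attributes; one MODEL block is written per pose
    with the score in a ``REMARK TOMODOCK SCORE`` line.
    """
    n = len(template.atoms)
    for k, p in enumerate(poses):
        c = np.asarray(p.coords)
        if c.shape != (n, 3):
            raise ValueError(
                f"pose {k} has coordinate shape {c.shape}, template has {n} atoms"
            )
    path = Path(path)
    with open(path, "w") as fh:
        for k, p in enumerate(poses, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            fh.write(f"REMARK TOMODOCK SCORE {float(p.score):10.4f}\n")
            for a, (x, y, z) in zip(template.atoms, np.asarray(p.coords)):
                rec = "HETATM" if a.is_hetero else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"{rec}{a.serial:5d} {name:<4s}{a.alt_loc or ' ':1s}"
                    f"{a.residue_name:>3s} {a.chain or 'A':1s}"
                    f"{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pose_models(path: str | Path) -> list[tuple[np.ndarray, float | None]]:
    """Read a multi-model PDB back as ``(coords, score)`` pairs.

    Scores come from ``REMARK TOMODOCK SCORE`` or ``REMARK VINA RESULT``
    lines; ``None`` when absent.
    """
    path = Path(path)
    models: list[tuple[np.ndarray, float | None]] = []
    coords: list[tuple[float, float, float]] = []
    score: float | None = None
    seen_any = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                coords, score = [], None
                seen_any = True
            elif rec == "REMARK":
                fields = line.split()
                if "SCORE" in fields:  # REMARK TOMODOCK SCORE <value>
                    score = float(fields[fields.index("SCORE") + 1])
                elif (len(fields) >= 4 and fields[1] == "VINA"
                      and fields[2].startswith("RESULT")):
                    # REMARK VINA RESULT: <score> <rmsd lb> <rmsd ub>
                    score = float(fields[3])
            elif rec in ("ATOM", "HETATM"):
                try:
                    coords.append(
                        (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                    )
                except ValueError as exc:
                    raise StructureFormatError(
                        f"line {lineno}: bad coordinates in pose file"
                    ) from exc
            elif rec == "ENDMDL":
                models.append((np.array(coords, dtype=float), score))
    if not models and coords and not seen_any:
        models.append((np.array(coords, dtype=float), score))
    if not models:
        raise StructureFormatError(f"no pose models found in {path}")
    return models
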