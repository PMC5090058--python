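"""Scan planning: the ordered cubic search boxes and the atom-inclusion table.

All functions here operate in the aligned frame produced by
:func:`tomodock.geometry.align_to_axis`: the scan axis is +z, the pocket
mouth centroid is at the origin, and successive boxes advance purely in z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PocketDefinition
from .structures import Structure

__all__ = [
    "ScanConfig",
    "SearchBox",
    "ScanPlan",
    "build_scan",
    "atoms_in_box",
    "static_box",
    "inclusion_table",
    "NEVER_INCLUDED",
]

#: sentinel first-inclusion step for atoms that never enter any box
NEVER_INCLUDED = 0

#: interaction cutoff of the production docking engine, Å; boxes smaller
#: than this silently truncate interactions, hence the warning below
ENGINE_CUTOFF = 8.0


@dataclass
class ScanConfig:
    """Scan parameters.

    Defaults are the standard deep-pocket protocol: an 18 Å cube advancing
    in 1 Å steps, 100 independent repetitions per step at engine
    exhaustiveness 16.  ``heavy_atoms_only`` controls the inclusion-table
    granularity; ``start_margin`` pushes the first box's leading face past
    the deepest mouth-reference atom.
    """

    edge: float = 18.0
    step: float = 1.0
    repetitions: int = 100
    exhaustiveness: int = 16
    seed: int = 0
    heavy_atoms_only: bool = True
    start_margin: float = 0.0
    n_poses: int = 9
    lateral_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("box edge must be positive")
        if self.step <= 0:
            raise ValueError("scan step must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")
        if self.edge < ENGINE_CUTOFF:
            warnings.warn(
                f"box edge {self.edge} Å is below the engine interaction "
                f"cutoff ({ENGINE_CUTOFF} Å); scores will miss interactions",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SearchBox:
    """A world-axis-aligned cubic search space."""

    center: tuple[float, float, float]
    edge: float
    step_index: int = 1

    @property
    def leading_face_z(self) -> float:
        """z of the deepest (+z) face — the box 'bottom' in pocket terms."""
        return self.center[2] + self.edge / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-boundary membership of points (face contact counts)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        half = self.edge / 2.0
        return (np.abs(pts - np.asarray(self.center)) <= half + 1e-12).all(axis=1)


@dataclass
class ScanPlan:
    """Ordered sequence of search boxes along the +z scan axis."""

    boxes: list[SearchBox]
    config: ScanConfig

    @property
    def n_steps(self) -> int:
        return len(self.boxes)

    def __post_init__(self) -> None:
        for k, box in enumerate(self.boxes, start=1):
            if box.step_index != k:
                raise ValueError("box step indices must run 1..n contiguously")


def build_scan(
    receptor_aligned: Structure,
    pocket: PocketDefinition,
    cfg: ScanConfig,
) -> ScanPlan:
    """Plan the tomographic scan for a receptor in the aligned frame.

    Box 1 is placed with its leading (deepest) face tangent to the deepest
    mouth-reference atom (plus ``cfg.start_margin``), so the mouth residue
    sits at the bottom of the first search space.  Boxes then advance by
    ``cfg.step`` Å in z until the box interior first contains every
    bottom-reference atom; that box is the last step.  The lateral (x, y)
    center is the mouth-reference centroid unless overridden in the config.
    """
    coords = receptor_aligned.coords
    mouth_idx = pocket.mouth_ref.resolve(receptor_aligned)
    bottom_idx = pocket.bottom_ref.resolve(receptor_aligned)
    mouth_xy = coords[mouth_idx, :2].mean(axis=0)
    if cfg.lateral_center is not None:
        mouth_xy = np.asarray(cfg.lateral_center, dtype=float)

    lead0 = coords[mouth_idx, 2].max() + cfg.start_margin
    bottom_pts = coords[bottom_idx]

    depth_span = max(bottom_pts[:, 2].max() - coords[mouth_idx, 2].min(), cfg.step)
    max_steps = int(np.ceil(10.0 * depth_span / cfg.step)) + 2

    boxes: list[SearchBox] = []
    for k in range(1, max_steps + 1):
        center = (
            float(mouth_xy[0]),
            float(mouth_xy[1]),
            lead0 + (k - 1) * cfg.step - cfg.edge / 2.0,
        )
        box = SearchBox(center=center, edge=cfg.edge, step_index=k)
        boxes.append(box)
        if k >= 2 and box.contains(bottom_pts).all():
            return ScanPlan(boxes=boxes, config=cfg)
    raise ValueError(
        "bottom reference never fully enters the search box within 10x the "
        "pocket depth; the scan axis is probably misoriented"
    )


def atoms_in_box(s: Structure, box: SearchBox, heavy_only: bool = True) -> set[int]:
    """Indices of atoms inside the box (closed boundary: faces count)."""
    mask = box.contains(s.coords)
    if heavy_only:
        mask &= np.array([not a.is_hydrogen for a in s.atoms])
    return set(np.nonzero(mask)[0].tolist())


def static_box(
    receptor_aligned: Structure, pocket: PocketDefinition, edge: float = 18.0
) -> SearchBox:
    """Single box over the whole pocket: the conventional-docking baseline."""
    lining = pocket.lining(receptor_aligned)
    coords = lining.coords
    center = coords.mean(axis=0)
    box = SearchBox(center=tuple(center), edge=edge, step_index=1)
    if not box.contains(coords).all():
        warnings.warn(
            f"edge {edge} Å does not contain all pocket-lining atoms; "
            "the static baseline will truncate the pocket",
            stacklevel=2,
        )
    return box


def inclusion_table(s: Structure, plan: ScanPlan, pocket: PocketDefinition) -> pd.DataFrame:
    """First-inclusion step of every pocket-lining atom as the box descends.

    One row per lining atom with columns ``chain, resi, resn, atom_name,
    element, z, first_inclusion``; atoms that never enter any box carry the
    sentinel step ``NEVER_INCLUDED`` (0).  Aggregate per-residue counts with
    :func:`residue_inclusion`.
    """
    lining = pocket.lining(s)
    heavy = plan.config.heavy_atoms_only
    first = np.full(len(lining.atoms), NEVER_INCLUDED, dtype=int)
    remaining = set(range(len(lining.atoms)))
    if heavy:
        remaining = {i for i in remaining if not lining.atoms[i].is_hydrogen}
        skipped_h = set(range(len(lining.atoms))) - remaining
    else:
        skipped_h = set()
    for box in plan.boxes:
        if not remaining:
            break
        inside = atoms_in_box(lining, box, heavy_only=heavy)
        newly = remaining & inside
        for i in newly:
            first[i] = box.step_index
        remaining -= newly

    rows = []
    for i, a in enumerate(lining.atoms):
        if i in skipped_h:
            continue
        rows.append(
            {
                "chain": a.chain,
                "resi": a.residue_seq,
                "resn": a.residue_name,
                "atom_name": a.name,
                "element": a.element,
                "z": a.coords[2],
                "first_inclusion": int(first[i]),
            }
        )
    return pd.DataFrame(rows)


def residue_inclusion(table: pd.DataFrame) -> pd.DataFrame:
    """Per-residue newly-included atom counts per step.

    Rows: one per (step, residue) with a positive count of atoms first
    included at that step.  Never-included atoms (sentinel step) are omitted.
    """
    inc = table[table["first_inclusion"] != NEVER_INCLUDED]
    grouped = (
        inc.groupby(["first_inclusion", "chain", "resi", "resn"])
        .size()
        .reset_index(name="new_atoms")
        .rename(columns={"first_inclusion": "step"})
        .sort_values(["step", "chain", "resi"], kind="stable")
        .reset_index(drop=True)
    )
    return grouped


def export_inclusion(table: pd.DataFrame, out_dir: str | Path, prefix: str = "inclusion") -> None:
    """Write the per-atom and per-residue inclusion tables as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_atom = table.copy()
    per_atom["first_inclusion"] = per_atom["first_inclusion"].map(
        lambda k: "none" if k == NEVER_INCLUDED else str(k)
    )
    per_atom.to_csv(out_dir / f"{prefix}_atoms.tsv", sep="\t", index=False)
    residue_inclusion(table).to_csv(
        out_dir / f"{prefix}_residues.tsv", sep="\t", index=False
    )
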