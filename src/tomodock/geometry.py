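"""Pocket geometry: scan axis from principal axes of inertia, depth, alignment.

The docking search box is world-axis-aligned, so before planning a scan the
working frame is rotated to put the scan axis on +z with the pocket-mouth
centroid at the origin.  The transform is returned so every downstream result
can be mapped back into the original crystal frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .structures import (
    ResidueRef,
    ResidueRange,
    RigidTransform,
    Structure,
    apply_transform,
    select_residues,
)

__all__ = [
    "PocketDefinition",
    "ScanAxis",
    "AxisAmbiguityError",
    "principal_axes",
    "scan_axis",
    "pocket_depth",
    "align_to_axis",
    "load_pocket_definition",
]

# monoisotopic-ish masses are overkill here; standard atomic weights
try:  # biopython's element weight table
    from Bio.Data.IUPACData import atom_weights as _ATOM_WEIGHTS
except ImportError:  # pragma: no cover
    _ATOM_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                     "P": 30.974, "S": 32.06}


def _element_mass(element: str) -> float:
    return float(_ATOM_WEIGHTS.get(element.capitalize(), 12.011))


class AxisAmbiguityError(ValueError):
    """Two principal axes align equally well with the pocket depth vector."""


@dataclass
class PocketDefinition:
    """Residue ranges lining the pocket plus mouth/bottom reference residues.

    For TIR1 the lining is the seven leucine-rich-repeat loop segments and
    the references are Phe-351 (mouth) and Arg-403 (bottom).
    """

    lining_ranges: list[ResidueRange]
    mouth_ref: ResidueRef
    bottom_ref: ResidueRef
    axis_override: np.ndarray | None = None

    def lining(self, receptor: Structure) -> Structure:
        return select_residues(receptor, self.lining_ranges)

    def validate(self, receptor: Structure) -> None:
        if not self.lining_ranges:
            raise ValueError("pocket definition has no lining ranges")
        self.mouth_ref.resolve(receptor)
        self.bottom_ref.resolve(receptor)
        self.lining(receptor)


@dataclass(frozen=True)
class ScanAxis:
    """Unit scan direction (mouth -> bottom) and origin (mouth centroid)."""

    direction: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("scan axis direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def depth_of(self, points: np.ndarray) -> np.ndarray:
        """Signed depth coordinate of points along the axis, mouth = 0."""
        return (np.atleast_2d(points) - self.origin) @ self.direction


def principal_axes(
    s: Structure, mass_weighted: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal axes of inertia about the centre of mass.

    Returns ``(axes, moments, centroid)`` with ``axes[i]`` the eigenvector
    (row) of the inertia tensor belonging to ``moments[i]``, sorted by
    ascending moment.  ``mass_weighted=False`` uses unit masses (geometric
    inertia).  Degenerate (collinear) structures are rejected.
    """
    coords = s.coords
    if len(coords) < 3:
        raise ValueError("need at least 3 atoms for principal axes")
    masses = (
        np.array([_element_mass(a.element) for a in s.atoms])
        if mass_weighted
        else np.ones(len(coords))
    )
    centroid = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - centroid
    # inertia tensor I = sum_i m_i (|r_i|^2 E - r_i r_i^T)
    tensor = float(masses @ (r**2).sum(axis=1)) * np.eye(3) - np.einsum(
        "i,ij,ik->jk", masses, r, r
    )
    moments, vecs = np.linalg.eigh(tensor)
    spread = np.linalg.svd(r * np.sqrt(masses)[:, None], compute_uv=False)
    if spread[1] < 1e-8 * max(spread[0], 1.0):
        raise ValueError("structure is collinear; principal axes are degenerate")
    axes = vecs.T  # rows
    return axes, moments, centroid


def scan_axis(receptor: Structure, pocket: PocketDefinition) -> ScanAxis:
    """Scan axis: the principal inertia axis best aligned with mouth->bottom.

    The axis sign is chosen to point from the mouth reference toward the
    bottom reference; the origin is the mouth-reference heavy-atom centroid.
    An explicit ``axis_override`` in the pocket definition bypasses the
    inertia calculation (for receptors whose principal axes are ambiguous).
    """
    mouth_c = pocket.mouth_ref.centroid(receptor)
    bottom_c = pocket.bottom_ref.centroid(receptor)
    depth_vec = bottom_c - mouth_c
    norm = np.linalg.norm(depth_vec)
    if norm < 1e-9:
        raise ValueError("mouth and bottom reference centroids coincide")
    depth_hat = depth_vec / norm

    if pocket.axis_override is not None:
        d = np.asarray(pocket.axis_override, dtype=float)
        d = d / np.linalg.norm(d)
        if d @ depth_hat < 0:
            d = -d
        return ScanAxis(direction=d, origin=mouth_c)

    axes, _, _ = principal_axes(receptor)
    cosines = np.abs(axes @ depth_hat)
    order = np.argsort(cosines)[::-1]
    if cosines[order[0]] - cosines[order[1]] < 1e-6:
        raise AxisAmbiguityError(
            "two principal axes align equally with the pocket depth vector "
            f"(|cos| = {cosines[order[0]]:.6f} vs {cosines[order[1]]:.6f}); "
            "set an explicit axis_override in the pocket definition"
        )
    d = axes[order[0]]
    if d @ depth_hat < 0:
        d = -d
    return ScanAxis(direction=d, origin=mouth_c)


def pocket_depth(
    receptor: Structure, pocket: PocketDefinition, convention: str = "centroid"
) -> float:
    """Pocket depth: distance between the mouth and bottom reference residues.

    ``convention="centroid"`` uses heavy-atom residue centroids;
    ``convention="ca"`` uses the Cα–Cα distance.
    """
    if convention == "centroid":
        a = pocket.mouth_ref.centroid(receptor)
        b = pocket.bottom_ref.centroid(receptor)
    elif convention == "ca":
        a = _ca_position(receptor, pocket.mouth_ref)
        b = _ca_position(receptor, pocket.bottom_ref)
    else:
        raise ValueError(f"unknown depth convention {convention!r}")
    return float(np.linalg.norm(b - a))


def _ca_position(s: Structure, ref: ResidueRef) -> np.ndarray:
    idx = ref.resolve(s)
    ca = [i for i in idx if s.atoms[i].name == "CA"]
    if not ca:
        raise KeyError(
            f"residue {ref.chain}:{ref.residue_seq} has no CA atom "
            "(required by the 'ca' depth convention)"
        )
    return s.coords[ca[0]]


def align_to_axis(
    receptor: Structure, ligand: Structure, axis: ScanAxis
) -> tuple[Structure, Structure, RigidTransform]:
    """Rotate/translate the system so the scan axis is +z, mouth at origin.

    Returns the transformed receptor and ligand plus the applied
    :class:`RigidTransform`; its inverse maps results back to the input frame.
    """
    d = axis.direction
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(d, z)
    c = float(d @ z)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else _flip_about_x()
    else:
        # Rodrigues: minimal rotation taking d onto z
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    t = RigidTransform(rot, -rot @ axis.origin)
    aligned_dir = t.rotation @ d
    assert np.allclose(aligned_dir, z, atol=1e-9)
    return apply_transform(receptor, t), apply_transform(ligand, t), t


def _flip_about_x() -> np.ndarray:
    return np.diag([1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# configuration


def load_pocket_definition(path: str | Path) -> PocketDefinition:
    """Read a pocket definition from YAML/JSON.

    Expected keys: ``chain``, ``ranges`` (list of ``[start, end]``),
    ``mouth_ref`` and ``bottom_ref`` (``{resi: int, resn: str|null,
    chain: optional}``), optional ``axis_override`` (3-vector).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    chain = str(cfg["chain"])
    ranges = [(chain, int(lo), int(hi)) for lo, hi in cfg["ranges"]]

    def _ref(block: dict) -> ResidueRef:
        return ResidueRef(
            chain=str(block.get("chain", chain)),
            residue_seq=int(block["resi"]),
            residue_name=block.get("resn"),
        )

    override = cfg.get("axis_override")
    return PocketDefinition(
        lining_ranges=ranges,
        mouth_ref=_ref(cfg["mouth_ref"]),
        bottom_ref=_ref(cfg["bottom_ref"]),
        axis_override=np.asarray(override, dtype=float) if override else None,
    )
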