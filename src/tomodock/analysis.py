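"""Pose-series analysis: depth/orientation metrics, significant-change flags,
plateau grouping, filter-residue identification and binder classification.

The scientific picture behind these functions: a binder descends a deep
pocket in stages — it first anchors its polar tail in an engagement niche on
the pocket wall with its aromatic ring system perpendicular to the pocket
base, then pivots past a constriction (the molecular filter) whose residues
admit correctly oriented ligands, and finally binds at the base.  The
trajectory of best poses across scan steps, combined with the atom-inclusion
table, localises those events: steps where the best pose jumps mark the
entry of mechanistically relevant residues into the search space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .runner import Trajectory
from .scan import NEVER_INCLUDED, residue_inclusion
from .structures import ResidueRef, Structure

__all__ = [
    "StepMetrics",
    "ChangeFlags",
    "NicheDefinition",
    "FilterCandidate",
    "LigandClassification",
    "step_metrics",
    "flag_changes",
    "plateaus",
    "identify_filter",
    "classify_ligand",
]

POLAR_ELEMENTS = {"N", "O", "S", "P"}


@dataclass(frozen=True)
class StepMetrics:
    """Per-step descriptors of the best pose (aligned frame)."""

    step_index: int
    best_score: float
    depth: float              # ligand centroid z relative to the mouth origin, Å
    orientation_angle: float  # ring-plane normal vs. scan axis, degrees in [0, 90]
    tail_in_niche: bool


@dataclass(frozen=True)
class ChangeFlags:
    step_index: int
    depth_changed: bool
    orientation_changed: bool
    rmsd_changed: bool
    significant: bool


@dataclass
class NicheDefinition:
    """The engagement niche: wall residues a binder's tail inserts into."""

    residues: list[ResidueRef]
    engagement_cutoff: float = 4.0  # Å, typical polar-contact distance

    def atom_coords(self, receptor: Structure) -> np.ndarray:
        idx: list[int] = []
        for ref in self.residues:
            idx.extend(ref.resolve(receptor))
        return receptor.coords[idx]

    def residue_keys(self) -> set[tuple[str, int]]:
        return {(r.chain, r.residue_seq) for r in self.residues}


@dataclass
class FilterCandidate:
    """A residue implicated in the selectivity filter."""

    residue: ResidueRef
    triggering_steps: list[int]
    new_atom_count: int
    polarity: str  # polar | apolar | mixed
    rank_score: float
    rationale: str


@dataclass
class LigandClassification:
    label: str  # "binder-like" | "non-binder-like"
    engages_niche_perpendicular: bool  # criterion (a)
    reaches_base: bool                 # criterion (b)
    engagement_plateau: tuple[int, int] | None = None
    final_depth: float = float("nan")


def ring_plane_angle(ring_coords: np.ndarray) -> float:
    """Angle (degrees, [0, 90]) between the ring-plane normal and +z.

    The normal is the smallest-variance direction of the least-squares plane
    through the ring atoms.  0° means the ring lies parallel to the pocket
    base (flat); 90° means the ring plane contains the scan axis
    (perpendicular to the base — the engagement orientation).
    """
    ring = np.asarray(ring_coords, dtype=float)
    if ring.shape[0] < 3:
        raise ValueError("need at least 3 ring atoms")
    centered = ring - ring.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("ring atoms are collinear; plane normal undefined")
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    normal = vecs[:, 0]  # smallest-variance direction
    cos = abs(float(normal[2]) / np.linalg.norm(normal))
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))


def step_metrics(
    traj: Trajectory,
    ligand: Structure,
    ring_atom_names: list[str],
    niche: NicheDefinition,
    receptor: Structure,
) -> list[StepMetrics]:
    """Depth, ring orientation and niche engagement for each step's best pose.

    ``ring_atom_names`` selects the aromatic ring atoms in the ligand (by
    atom name); the remaining ligand atoms are the "tail".  The tail engages
    the niche when any tail atom lies within the niche engagement cutoff of
    any niche-residue atom.  All structures must be in the aligned frame.
    """
    names = [a.name for a in ligand.atoms]
    ring_idx = [i for i, n in enumerate(names) if n in set(ring_atom_names)]
    if len(ring_idx) < 3:
        raise ValueError(
            f"ring atom names {ring_atom_names} match only {len(ring_idx)} "
            "ligand atoms; need >= 3"
        )
    tail_idx = [i for i in range(len(names)) if i not in set(ring_idx)]
    niche_coords = niche.atom_coords(receptor)

    out: list[StepMetrics] = []
    for step, pose in zip(traj.steps, traj.best_poses):
        coords = np.asarray(pose.coords)
        depth = float(coords.mean(axis=0)[2])
        angle = ring_plane_angle(coords[ring_idx])
        if tail_idx:
            d = np.linalg.norm(
                coords[tail_idx][:, None, :] - niche_coords[None, :, :], axis=2
            )
            tail_in = bool((d <= niche.engagement_cutoff).any())
        else:
            tail_in = False
        out.append(
            StepMetrics(
                step_index=step, best_score=float(pose.score), depth=depth,
                orientation_angle=angle, tail_in_niche=tail_in,
            )
        )
    return out


def flag_changes(
    metrics: list[StepMetrics],
    traj: Trajectory,
    depth_tol: float = 0.5,
    rmsd_tol: float = 1.0,
    angle_tol: float = 20.0,
) -> list[ChangeFlags]:
    """Flag steps at which the best pose changes significantly.

    Step 1 is always flagged (pocket entry).  Step k ≥ 2 is flagged when the
    depth change, the in-frame (no superposition) RMSD to the previous best
    pose, or the ring-orientation change exceeds its tolerance.
    """
    if len(metrics) < 2:
        raise ValueError("need at least two steps to flag changes")
    flags = [
        ChangeFlags(step_index=metrics[0].step_index, depth_changed=True,
                    orientation_changed=True, rmsd_changed=True,
                    significant=True)
    ]
    for prev, cur, pose_prev, pose_cur in zip(
        metrics, metrics[1:], traj.best_poses, traj.best_poses[1:]
    ):
        d_depth = abs(cur.depth - prev.depth) > depth_tol
        d_angle = abs(cur.orientation_angle - prev.orientation_angle) > angle_tol
        rmsd = float(
            np.sqrt(
                ((np.asarray(pose_cur.coords) - np.asarray(pose_prev.coords)) ** 2)
                .sum(axis=1)
                .mean()
            )
        )
        d_rmsd = rmsd > rmsd_tol
        flags.append(
            ChangeFlags(
                step_index=cur.step_index,
                depth_changed=d_depth,
                orientation_changed=d_angle,
                rmsd_changed=d_rmsd,
                significant=d_depth or d_angle or d_rmsd,
            )
        )
    return flags


def plateaus(flags: list[ChangeFlags]) -> list[list[int]]:
    """Group steps into pose plateaus.

    Each maximal run of consecutive unflagged steps is merged with the
    flagged step that precedes it; the groups partition the step range.
    """
    groups: list[list[int]] = []
    for f in flags:
        if f.significant or not groups:
            groups.append([f.step_index])
        else:
            groups[-1].append(f.step_index)
    return groups


def _polarity(elements: list[str]) -> str:
    polar = [e for e in elements if e.capitalize().upper() in POLAR_ELEMENTS]
    if not polar:
        return "apolar"
    if len(polar) == len(elements):
        return "polar"
    return "mixed"


def identify_filter(
    inclusion: pd.DataFrame,
    flags: list[ChangeFlags],
    niche: NicheDefinition,
    min_new_atoms: int = 3,
    window: int = 1,
) -> tuple[list[FilterCandidate], list[FilterCandidate]]:
    """Rank residues likely to form the selectivity filter.

    A residue becomes a candidate when it contributes at least
    ``min_new_atoms`` newly included atoms at an interior flagged step or
    within ``window`` steps before it — i.e. its arrival coincides with a
    pose change.  Residues whose atoms arrive only during plateaus are
    excluded: the pose demonstrably did not respond to them.  Residues of
    the engagement niche are reported separately (second return value)
    rather than as filter members, whatever their counts.  Candidates are
    ranked by (number of triggering flagged steps, new-atom count).
    """
    per_res = residue_inclusion(inclusion)
    interior_flagged = [f.step_index for f in flags[1:] if f.significant]
    niche_keys = niche.residue_keys()

    atoms_by_res_step: dict[tuple[str, int], dict[int, int]] = {}
    resnames: dict[tuple[str, int], str] = {}
    for row in per_res.itertuples():
        key = (row.chain, row.resi)
        atoms_by_res_step.setdefault(key, {})[int(row.step)] = int(row.new_atoms)
        resnames[key] = row.resn

    elements_by_res: dict[tuple[str, int], dict[int, list[str]]] = {}
    for row in inclusion.itertuples():
        if row.first_inclusion == NEVER_INCLUDED:
            continue
        key = (row.chain, row.resi)
        elements_by_res.setdefault(key, {}).setdefault(
            int(row.first_inclusion), []
        ).append(row.element)

    candidates: list[FilterCandidate] = []
    niche_report: list[FilterCandidate] = []
    for key, step_counts in atoms_by_res_step.items():
        triggering: list[int] = []
        trigger_atoms = 0
        trigger_elements: list[str] = []
        for f in interior_flagged:
            in_window = {
                s: c for s, c in step_counts.items() if f - window <= s <= f
            }
            n_new = sum(in_window.values())
            if n_new >= min_new_atoms:
                triggering.append(f)
                trigger_atoms += n_new
                for s in in_window:
                    trigger_elements.extend(elements_by_res[key].get(s, []))
        if not triggering:
            continue
        chain, resi = key
        resn = resnames[key]
        pol = _polarity(trigger_elements)
        cand = FilterCandidate(
            residue=ResidueRef(chain=chain, residue_seq=resi, residue_name=resn),
            triggering_steps=triggering,
            new_atom_count=trigger_atoms,
            polarity=pol,
            rank_score=float(len(triggering)) + 1e-3 * trigger_atoms,
            rationale=(
                f"{resn}-{resi} contributes {trigger_atoms} new {pol} atom(s) "
                f"at/just before pose-change step(s) {triggering}; the best "
                "pose responds where this residue enters the search space."
            ),
        )
        if key in niche_keys:
            cand.rationale += (
                "  Reported separately: structurally part of the engagement "
                "niche, not counted as a filter member."
            )
            niche_report.append(cand)
        else:
            candidates.append(cand)

    keyfn = lambda c: (-c.rank_score, c.residue.chain, c.residue.residue_seq)
    candidates.sort(key=keyfn)
    niche_report.sort(key=keyfn)
    return candidates, niche_report


def classify_ligand(
    metrics: list[StepMetrics],
    flags: list[ChangeFlags],
    base_depth: float,
    angle_tol: float = 20.0,
) -> LigandClassification:
    """Heuristic binder / non-binder label from the scan trajectory.

    Binder-like requires (a) some plateau in which the tail engages the
    niche with the ring system perpendicular to the pocket base
    (orientation angle ≥ 90° − ``angle_tol`` at every step of the plateau),
    and (b) a final plateau at or below ``base_depth``.  This labels the
    descent mechanism, it is not a binding-affinity prediction.
    """
    by_step = {m.step_index: m for m in metrics}
    groups = plateaus(flags)

    engagement: tuple[int, int] | None = None
    for g in groups:
        ms = [by_step[s] for s in g]
        if all(m.tail_in_niche for m in ms) and all(
            m.orientation_angle >= 90.0 - angle_tol for m in ms
        ):
            engagement = (g[0], g[-1])
            break

    final_group = groups[-1]
    final_depth = float(np.mean([by_step[s].depth for s in final_group]))
    reaches_base = final_depth >= base_depth

    label = (
        "binder-like" if (engagement is not None and reaches_base)
        else "non-binder-like"
    )
    return LigandClassification(
        label=label,
        engages_niche_perpendicular=engagement is not None,
        reaches_base=reaches_base,
        engagement_plateau=engagement,
        final_depth=final_depth,
    )


def metrics_frame(metrics: list[StepMetrics], flags: list[ChangeFlags] | None = None
                  ) -> pd.DataFrame:
    """Tabulate step metrics (and flags) for TSV export."""
    df = pd.DataFrame(
        {
            "step": [m.step_index for m in metrics],
            "score": [m.best_score for m in metrics],
            "depth": [m.depth for m in metrics],
            "angle": [m.orientation_angle for m in metrics],
            "tail_in_niche": [m.tail_in_niche for m in metrics],
        }
    )
    if flags is not None:
        by_step = {f.step_index: f for f in flags}
        df["significant_change"] = [
            by_step[s].significant for s in df["step"]
        ]
    return df
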