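"""High-level orchestration: align, plan, scan, analyse in one call."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .analysis import (
    ChangeFlags,
    FilterCandidate,
    LigandClassification,
    NicheDefinition,
    StepMetrics,
    classify_ligand,
    flag_changes,
    identify_filter,
    metrics_frame,
    plateaus,
    step_metrics,
)
from .geometry import PocketDefinition, align_to_axis, scan_axis
from .runner import ScanResult, Trajectory, best_pose_per_step, run_scan
from .scan import ScanConfig, ScanPlan, build_scan, inclusion_table
from .structures import RigidTransform, Structure

__all__ = ["ScanOutcome", "tomographic_scan", "analyze_trajectory"]


@dataclass
class ScanOutcome:
    """Everything a tomographic scan produces, in the aligned frame."""

    receptor_aligned: Structure
    ligand_aligned: Structure
    transform: RigidTransform
    plan: ScanPlan
    result: ScanResult
    trajectory: Trajectory
    inclusion: pd.DataFrame
    metrics: list[StepMetrics] | None = None
    flags: list[ChangeFlags] | None = None
    plateau_groups: list[list[int]] | None = None
    filter_candidates: list[FilterCandidate] | None = None
    niche_report: list[FilterCandidate] | None = None
    classification: LigandClassification | None = None


def tomographic_scan(
    receptor: Structure,
    ligand: Structure,
    pocket: PocketDefinition,
    cfg: ScanConfig,
    engine,
    niche: NicheDefinition | None = None,
    ring_atoms: list[str] | None = None,
    base_depth: float | None = None,
    out_dir: str | Path | None = None,
    depth_tol: float = 0.5,
    rmsd_tol: float = 1.0,
    angle_tol: float = 20.0,
    min_new_atoms: int = 3,
    window: int = 1,
) -> ScanOutcome:
    """Run a full tomographic docking scan and (optionally) its analysis.

    The receptor/ligand are given in any frame; the scan axis is derived
    from the receptor's principal axes of inertia and the pocket definition,
    the system is aligned so the axis is +z, and the box sequence is built
    and executed.  When ``niche`` and ``ring_atoms`` are provided the pose
    series is analysed through to filter candidates; ``base_depth``
    additionally yields a binder / non-binder classification.
    """
    pocket.validate(receptor)
    axis = scan_axis(receptor, pocket)
    rec_a, lig_a, tf = align_to_axis(receptor, ligand, axis)
    plan = build_scan(rec_a, pocket, cfg)
    result = run_scan(rec_a, lig_a, plan, engine, cfg, out_dir=out_dir)
    traj = best_pose_per_step(result)
    incl = inclusion_table(rec_a, plan, pocket)
    outcome = ScanOutcome(
        receptor_aligned=rec_a,
        ligand_aligned=lig_a,
        transform=tf,
        plan=plan,
        result=result,
        trajectory=traj,
        inclusion=incl,
    )
    if niche is not None and ring_atoms is not None:
        analyze_trajectory(
            outcome, niche, ring_atoms, base_depth=base_depth,
            depth_tol=depth_tol, rmsd_tol=rmsd_tol, angle_tol=angle_tol,
            min_new_atoms=min_new_atoms, window=window,
        )
    return outcome


def analyze_trajectory(
    outcome: ScanOutcome,
    niche: NicheDefinition,
    ring_atoms: list[str],
    base_depth: float | None = None,
    depth_tol: float = 0.5,
    rmsd_tol: float = 1.0,
    angle_tol: float = 20.0,
    min_new_atoms: int = 3,
    window: int = 1,
) -> ScanOutcome:
    """Fill the analysis fields of an existing :class:`ScanOutcome`."""
    outcome.metrics = step_metrics(
        outcome.trajectory, outcome.ligand_aligned, ring_atoms, niche,
        outcome.receptor_aligned,
    )
    outcome.flags = flag_changes(
        outcome.metrics, outcome.trajectory,
        depth_tol=depth_tol, rmsd_tol=rmsd_tol, angle_tol=angle_tol,
    )
    outcome.plateau_groups = plateaus(outcome.flags)
    cands, niche_rep = identify_filter(
        outcome.inclusion, outcome.flags, niche,
        min_new_atoms=min_new_atoms, window=window,
    )
    outcome.filter_candidates = cands
    outcome.niche_report = niche_rep
    if base_depth is not None:
        outcome.classification = classify_ligand(
            outcome.metrics, outcome.flags, base_depth, angle_tol=angle_tol
        )
    return outcome


def summary_frame(outcome: ScanOutcome) -> pd.DataFrame:
    if outcome.metrics is None:
        raise ValueError("outcome has not been analysed")
    return metrics_frame(outcome.metrics, outcome.flags)
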