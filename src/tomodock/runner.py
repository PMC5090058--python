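"""Scan execution: repeated docking at every step, reduced to a
best-pose-per-step trajectory.

Every (step, repetition) pair is an independent engine invocation with a
derived seed (``base_seed + 1000·step_index + repetition``), so any single
run can be reproduced in isolation.  Results can be persisted incrementally
(one JSON file per step) and a rerun with the same provenance hash resumes
from what is already on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engines import EngineError, EngineParams, Pose
from .scan import ScanConfig, ScanPlan
from .structures import Structure

__all__ = ["ScanResult", "Trajectory", "run_scan", "best_pose_per_step",
           "derived_seed"]

logger = logging.getLogger(__name__)


def derived_seed(base_seed: int, step_index: int, repetition: int) -> int:
    return base_seed + 1000 * step_index + repetition


@dataclass
class ScanResult:
    """All poses of a scan, keyed by (step_index, repetition)."""

    plan: ScanPlan
    poses: dict[tuple[int, int], list[Pose]]
    failures: dict[tuple[int, int], str] = field(default_factory=dict)
    engine: str = ""
    provenance: str = ""

    def poses_at_step(self, step_index: int) -> list[Pose]:
        out: list[Pose] = []
        for rep in range(1, self.plan.config.repetitions + 1):
            out.extend(self.poses.get((step_index, rep), []))
        return out

    def scores_frame(self) -> pd.DataFrame:
        """Long-format (step, repetition, rank, score) table."""
        rows = []
        for (step, rep), plist in sorted(self.poses.items()):
            for rank, p in enumerate(plist, start=1):
                rows.append(
                    {"step": step, "repetition": rep, "rank": rank,
                     "score": p.score}
                )
        return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """Best pose and score per step, ordered by step index."""

    steps: list[int]
    best_poses: list[Pose]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.best_poses):
            raise ValueError("steps and best_poses must have equal length")

    @property
    def best_scores(self) -> np.ndarray:
        return np.array([p.score for p in self.best_poses])


def _provenance_hash(
    receptor: Structure, ligand: Structure, plan: ScanPlan, engine_name: str
) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(receptor.coords).tobytes())
    h.update(np.ascontiguousarray(ligand.coords).tobytes())
    cfg = plan.config
    h.update(
        json.dumps(
            [cfg.edge, cfg.step, cfg.repetitions, cfg.exhaustiveness,
             cfg.seed, engine_name, [list(b.center) for b in plan.boxes]],
            sort_keys=True,
        ).encode()
    )
    return h.hexdigest()[:16]


def _step_file(out_dir: Path, step: int) -> Path:
    return out_dir / f"step_{step:03d}.json"


def _save_step(path: Path, provenance: str, step: int,
               poses: dict[int, list[Pose]], failures: dict[int, str]) -> None:
    payload = {
        "provenance": provenance,
        "step": step,
        "repetitions": {
            str(rep): [
                {"score": p.score, "coords": np.asarray(p.coords).tolist()}
                for p in plist
            ]
            for rep, plist in poses.items()
        },
        "failures": {str(rep): msg for rep, msg in failures.items()},
    }
    path.write_text(json.dumps(payload))


def _load_step(path: Path, provenance: str, step: int, engine: str
               ) -> tuple[dict[int, list[Pose]], dict[int, str]] | None:
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError):
        return None
    if payload.get("provenance") != provenance:
        return None
    poses = {
        int(rep): [
            Pose(coords=np.array(p["coords"]), score=p["score"],
                 step_index=step, repetition=int(rep), engine=engine)
            for p in plist
        ]
        for rep, plist in payload["repetitions"].items()
    }
    failures = {int(rep): msg for rep, msg in payload.get("failures", {}).items()}
    return poses, failures


def run_scan(
    receptor: Structure,
    ligand: Structure,
    plan: ScanPlan,
    engine,
    cfg: ScanConfig | None = None,
    out_dir: str | Path | None = None,
    resume: bool = True,
) -> ScanResult:
    """Run ``cfg.repetitions`` independent docking experiments at every step.

    Individual engine failures are recorded, not fatal; a step where every
    repetition fails raises.  With ``out_dir`` set, per-step results are
    persisted as JSON and a rerun resumes completed steps whose provenance
    hash matches.
    """
    cfg = cfg or plan.config
    engine_name = getattr(engine, "name", engine.__class__.__name__)
    provenance = _provenance_hash(receptor, ligand, plan, engine_name)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    all_poses: dict[tuple[int, int], list[Pose]] = {}
    all_failures: dict[tuple[int, int], str] = {}
    for box in plan.boxes:
        step = box.step_index
        step_poses: dict[int, list[Pose]] = {}
        step_failures: dict[int, str] = {}
        cached = None
        if out_path is not None and resume:
            cached = _load_step(_step_file(out_path, step), provenance, step,
                                engine_name)
        if cached is not None:
            step_poses, step_failures = cached
        else:
            for rep in range(1, cfg.repetitions + 1):
                params = EngineParams(
                    exhaustiveness=cfg.exhaustiveness,
                    n_poses=cfg.n_poses,
                    seed=derived_seed(cfg.seed, step, rep),
                )
                try:
                    poses = engine.dock(receptor, ligand, box, params)
                except EngineError as exc:
                    logger.warning("step %d rep %d failed: %s", step, rep, exc)
                    step_failures[rep] = str(exc)
                    continue
                step_poses[rep] = [
                    Pose(coords=p.coords, score=p.score, step_index=step,
                         repetition=rep, engine=engine_name)
                    for p in poses
                ]
            if out_path is not None:
                _save_step(_step_file(out_path, step), provenance, step,
                           step_poses, step_failures)
        if not step_poses:
            raise EngineError(
                f"all {cfg.repetitions} repetitions failed at step {step}"
            )
        for rep, plist in step_poses.items():
            all_poses[(step, rep)] = plist
        for rep, msg in step_failures.items():
            all_failures[(step, rep)] = msg

    return ScanResult(
        plan=plan, poses=all_poses, failures=all_failures,
        engine=engine_name, provenance=provenance,
    )


def best_pose_per_step(result: ScanResult) -> Trajectory:
    """Reduce a scan to the lowest-score pose at each step.

    Exact score ties are broken by the lowest repetition index, then the
    lowest pose rank within the repetition.
    """
    steps: list[int] = []
    best: list[Pose] = []
    for box in result.plan.boxes:
        step = box.step_index
        candidates: list[tuple[float, int, int, Pose]] = []
        for rep in sorted(
            r for (s, r) in result.poses.keys() if s == step
        ):
            for rank, p in enumerate(result.poses[(step, rep)], start=1):
                candidates.append((p.score, rep, rank, p))
        if not candidates:
            raise ValueError(f"step {step} has no poses")
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        steps.append(step)
        best.append(candidates[0][3])
    return Trajectory(steps=steps, best_poses=best)
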