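"""Docking engines: the engine contract, a built-in toy engine, and an
AutoDock Vina adapter.

The scanning method itself is engine-agnostic orchestration; production runs
use AutoDock Vina through :class:`VinaEngine`, while tests and desk-scale
examples use :class:`MockEngine`, a deterministic rigid-body engine with a
simple additive pairwise score.  The toy score is a fixture convention, not
a physical claim: a soft-sphere clash penalty plus a Gaussian attraction
between label-matched pharmacophore pairs (donor/acceptor, aromatic pairs).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import qmc

from .scan import SearchBox
from .structures import Atom, Structure, read_pose_models

__all__ = [
    "Pose",
    "EngineParams",
    "EngineError",
    "MockEngine",
    "VinaEngine",
    "ToyScorer",
    "toy_score",
    "pharm_label",
    "write_vina_config",
    "parse_vina_output",
]

# toy-score constants (fixture conventions)
CLASH_WEIGHT = 10.0   # C, kcal-ish units per Å²
CLASH_RADIUS = 2.5    # r_min, Å
ATTRACT_WEIGHT = 1.0  # A
ATTRACT_DIST = 3.0    # d0, Å
ATTRACT_WIDTH = 1.0   # w, Å²
DEFAULT_CUTOFF = 8.0  # engine interaction cutoff, Å

_DEFAULT_LABELS = {"N": "donor", "O": "acceptor", "S": "acceptor"}

#: label pairs that produce the Gaussian attraction term
_MATCHED = {
    ("donor", "acceptor"),
    ("acceptor", "donor"),
    ("aromatic", "aromatic"),
}


class EngineError(RuntimeError):
    """Engine invocation or output parsing failed; carries the raw log."""

    def __init__(self, message: str, log: str = ""):
        super().__init__(message + (f"\n--- engine log ---\n{log}" if log else ""))
        self.log = log


@dataclass(frozen=True)
class Pose:
    """One docked ligand placement.

    ``coords`` uses the same atom order as the input ligand; ``score`` is in
    engine units, lower = better.
    """

    coords: np.ndarray
    score: float
    step_index: int = 0
    repetition: int = 0
    engine: str = ""

    def centroid(self) -> np.ndarray:
        return np.asarray(self.coords).mean(axis=0)


@dataclass(frozen=True)
class EngineParams:
    exhaustiveness: int = 16
    n_poses: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exhaustiveness < 1 or self.n_poses < 1:
            raise ValueError("exhaustiveness and n_poses must be positive")


def pharm_label(atom: Atom) -> str:
    """Pharmacophore label of an atom: explicit annotation, else by element."""
    if atom.pharm_label is not None:
        return atom.pharm_label
    return _DEFAULT_LABELS.get(atom.element.capitalize(), "apolar")


_LABEL_CODES = {"apolar": 0, "donor": 1, "acceptor": 2, "aromatic": 3}
_MATCH_TABLE = np.zeros((4, 4), dtype=bool)
for _a, _b in _MATCHED:
    _MATCH_TABLE[_LABEL_CODES[_a], _LABEL_CODES[_b]] = True


def _codes(labels) -> np.ndarray:
    return np.array([_LABEL_CODES[l] for l in labels], dtype=np.intp)


class ToyScorer:
    """Additive pairwise toy score against a fixed receptor.

    score = sum over receptor-ligand pairs with d <= cutoff of
    ``C·max(0, r_min − d)²  −  A·exp(−(d − d0)²/w)·[labels matched]``.
    Continuous in the ligand coordinates and exactly additive, so scores are
    local: receptor atoms farther than the cutoff from every ligand atom
    contribute nothing.
    """

    def __init__(self, receptor: Structure, cutoff: float = DEFAULT_CUTOFF):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.cutoff = float(cutoff)
        self.rec_coords = np.ascontiguousarray(receptor.coords)
        self.rec_labels = np.array([pharm_label(a) for a in receptor.atoms])
        self._rec_codes = _codes(self.rec_labels)
        self._rec_sq = (self.rec_coords**2).sum(axis=1)

    def match_matrix(self, ligand_labels) -> np.ndarray:
        """(n_receptor, n_ligand) matched-pair mask for a label assignment."""
        return _MATCH_TABLE[np.ix_(self._rec_codes, _codes(ligand_labels))]

    def score(
        self,
        ligand_coords: np.ndarray,
        ligand_labels=None,
        match: np.ndarray | None = None,
    ) -> float:
        """Score one ligand configuration.

        Either ``ligand_labels`` or a precomputed ``match`` matrix (from
        :meth:`match_matrix`, for repeated scoring of the same ligand) must
        be given.
        """
        lig = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
        if match is None:
            if ligand_labels is None:
                raise ValueError("need ligand_labels or a match matrix")
            match = self.match_matrix(ligand_labels)
        d2 = (
            self._rec_sq[:, None]
            + (lig**2).sum(axis=1)[None, :]
            - 2.0 * (self.rec_coords @ lig.T)
        )
        d = np.sqrt(np.maximum(d2, 0.0))
        total = 0.0
        cm = d < CLASH_RADIUS  # clash radius is within the cutoff
        if cm.any():
            delta = CLASH_RADIUS - d[cm]
            total += CLASH_WEIGHT * float((delta * delta).sum())
        am = match & (d <= self.cutoff)
        if am.any():
            dm = d[am]
            total -= ATTRACT_WEIGHT * float(
                np.exp(-((dm - ATTRACT_DIST) ** 2) / ATTRACT_WIDTH).sum()
            )
        return total

    def score_many(self, configs: np.ndarray, match: np.ndarray) -> np.ndarray:
        """Score a (K, n_ligand, 3) batch of configurations at once."""
        configs = np.asarray(configs, dtype=float)
        k, n, _ = configs.shape
        flat = configs.reshape(k * n, 3)
        d2 = (
            self._rec_sq[:, None]
            + (flat**2).sum(axis=1)[None, :]
            - 2.0 * (self.rec_coords @ flat.T)
        )
        d = np.sqrt(np.maximum(d2, 0.0))
        totals = np.zeros(k)
        rows, cols = np.nonzero(d < CLASH_RADIUS)
        if len(rows):
            delta = CLASH_RADIUS - d[rows, cols]
            np.add.at(totals, cols // n, CLASH_WEIGHT * delta * delta)
        match_full = np.repeat(match[:, None, :], k, axis=1).reshape(
            len(self.rec_coords), k * n
        )
        rows, cols = np.nonzero(match_full & (d <= self.cutoff))
        if len(rows):
            dm = d[rows, cols]
            np.add.at(
                totals,
                cols // n,
                -ATTRACT_WEIGHT * np.exp(-((dm - ATTRACT_DIST) ** 2) / ATTRACT_WIDTH),
            )
        return totals


def toy_score(
    receptor: Structure,
    ligand_coords: np.ndarray,
    ligand_labels: np.ndarray | list[str],
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Convenience wrapper: score one configuration (see :class:`ToyScorer`)."""
    return ToyScorer(receptor, cutoff).score(ligand_coords, ligand_labels)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _align_matrix(u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector t."""
    v = np.cross(u, t)
    c = float(u @ t)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite vectors: rotate pi about any axis perpendicular to u
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, p)
        axis /= np.linalg.norm(axis)
        return _axis_angle_matrices(axis, np.array([np.pi]))[0]
    vx = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_angle_matrices(axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Stack of rotation matrices about a fixed unit axis (Rodrigues)."""
    kx = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    kx2 = kx @ kx
    s = np.sin(angles)[:, None, None]
    c = (1.0 - np.cos(angles))[:, None, None]
    return np.eye(3)[None] + s * kx + c * kx2


def _aim_centers(pick: np.ndarray, dirs: np.ndarray, radius: float,
                 mats: np.ndarray, arm: np.ndarray, n_twist: int) -> np.ndarray:
    """Centroid placements for aimed candidates: the aimed atom sits
    ``radius`` out from the hot atom along each approach direction."""
    n_dir = len(dirs)
    d_rep = np.repeat(dirs, n_twist, axis=0)
    rot_arm = np.einsum("kij,j->ki", mats, arm)
    return pick[None, :] + d_rep * radius - rot_arm


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (Rodrigues), allocation-light."""
    theta = float(np.linalg.norm(v))
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    kx = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(theta) * kx + (1.0 - np.cos(theta)) * (kx @ kx)


class MockEngine:
    """Deterministic rigid-body toy docking engine.

    The search draws ``samples_per_exhaustiveness × exhaustiveness`` starting
    placements (scrambled-Halton translations within the box × uniform random
    rotations), scores all of them, then refines the best ``n_refine``
    candidates by bounded local minimisation over the six rigid degrees of
    freedom.  Identical seeds and inputs give bit-identical pose lists.
    """

    name = "mock"

    def __init__(
        self,
        cutoff: float = DEFAULT_CUTOFF,
        samples_per_exhaustiveness: int = 8,
        n_refine: int = 14,
    ):
        self.cutoff = cutoff
        self.samples_per_exhaustiveness = samples_per_exhaustiveness
        self.n_refine = n_refine
        self._scorer_cache: tuple[int, ToyScorer] | None = None

    def _scorer(self, receptor: Structure) -> ToyScorer:
        key = id(receptor)
        if self._scorer_cache is None or self._scorer_cache[0] != key:
            self._scorer_cache = (key, ToyScorer(receptor, self.cutoff))
        return self._scorer_cache[1]

    def dock(
        self,
        receptor: Structure,
        ligand: Structure,
        box: SearchBox,
        params: EngineParams,
    ) -> list[Pose]:
        lig0 = ligand.coords
        center0 = lig0.mean(axis=0)
        local = lig0 - center0
        radius = float(np.linalg.norm(local, axis=1).max())
        if 2 * radius > box.edge:
            raise ValueError(
                f"ligand bounding sphere ({2 * radius:.1f} Å) exceeds the "
                f"box edge ({box.edge:.1f} Å)"
            )
        labels = np.array([pharm_label(a) for a in ligand.atoms])
        scorer = self._scorer(receptor)
        match = scorer.match_matrix(labels)

        rng = np.random.default_rng(params.seed)
        n_samples = self.samples_per_exhaustiveness * params.exhaustiveness
        halton = qmc.Halton(d=3, scramble=True, seed=rng)
        lo = np.asarray(box.center) - box.edge / 2.0
        uniform_centers = lo + halton.random(n_samples) * box.edge
        uniform_mats = Rotation.random(
            n_samples,
            random_state=np.random.RandomState(rng.integers(0, 2**31 - 1)),
        ).as_matrix()

        # complementarity-biased seeding: start a share of placements near
        # receptor atoms whose label can attract some ligand atom, along
        # that atom's OPEN approach directions (rays whose probe points
        # 2.5-5.5 Å out are clash-free) — an enclosed site such as a
        # sub-pocket or channel can only be entered along the few lines
        # that exist, and uniform box sampling never finds them
        hot = scorer.rec_coords[match.any(axis=1)]
        near = np.linalg.norm(hot - np.asarray(box.center), axis=1)
        hot = hot[near <= np.sqrt(3.0) * box.edge / 2 + self.cutoff]
        lig_hot = np.nonzero(match.any(axis=0))[0]

        cand_mats: list[np.ndarray] = []
        cand_centers: list[np.ndarray] = []
        cand_scores: list[float] = []
        cand_targets: list[int] = []  # hot-atom index; -1 for uniform starts

        n_bias = (2 * n_samples) // 3 if len(hot) and len(lig_hot) else 0
        if n_bias:
            n_dir, n_twist = 4, 12
            pick_idx = rng.integers(0, len(hot), n_bias)
            aims = lig_hot[rng.integers(0, len(lig_hot), n_bias)]
            direction = rng.normal(size=(n_bias, n_dir, 3))
            direction /= np.linalg.norm(direction, axis=2, keepdims=True)
            probe = _fibonacci_sphere(32)
            probe_r = np.array([2.5, 4.0, 5.5])
            open_dirs: dict[int, np.ndarray] = {}
            for h in np.unique(pick_idx):
                pts = (hot[h][None, None, :]
                       + probe[:, None, :] * probe_r[None, :, None])
                d2p = (
                    (pts.reshape(-1, 3)[None, :, :]
                     - scorer.rec_coords[:, None, :]) ** 2
                ).sum(axis=2)
                clear = np.sqrt(d2p.min(axis=0)).reshape(len(probe), 3)
                ok = (clear > 2.2).all(axis=1)
                if ok.any():
                    open_dirs[int(h)] = probe[ok]
            for i in range(n_bias):
                od = open_dirs.get(int(pick_idx[i]))
                if od is not None and len(od):
                    for m in range(n_dir - 1):
                        base = od[rng.integers(0, len(od))]
                        wob = base + 0.25 * rng.normal(size=3)
                        direction[i, m] = wob / np.linalg.norm(wob)

            radii = rng.uniform(ATTRACT_DIST - 0.5, ATTRACT_DIST + 2.0, n_bias)
            twist0 = rng.uniform(-np.pi, np.pi, n_bias)
            twists = twist0[:, None] + 2 * np.pi * np.arange(n_twist) / n_twist
            half = box.edge / 2.0
            blo = np.asarray(box.center) - half
            bhi = np.asarray(box.center) + half
            for i in range(n_bias):
                arm = local[aims[i]]
                arm_len = np.linalg.norm(arm)
                if arm_len < 1e-9:
                    continue
                u = arm / arm_len
                mats = np.empty((n_dir, n_twist, 3, 3))
                for m in range(n_dir):
                    d_hat = direction[i, m]
                    align = _align_matrix(u, -d_hat)
                    spin = _axis_angle_matrices(-d_hat, twists[i])
                    mats[m] = spin @ align
                flat = mats.reshape(-1, 3, 3)
                ctrs = np.clip(
                    _aim_centers(hot[pick_idx[i]], direction[i], radii[i],
                                 flat, arm, n_twist),
                    blo, bhi,
                )
                cfgs = np.einsum("kij,nj->kni", flat, local) + ctrs[:, None, :]
                scs = scorer.score_many(cfgs, match)
                scs_m = scs.reshape(n_dir, n_twist)
                for m in range(n_dir):
                    j = int(np.argmin(scs_m[m]))
                    k = m * n_twist + j
                    cand_mats.append(flat[k])
                    cand_centers.append(ctrs[k])
                    cand_scores.append(float(scs_m[m, j]))
                    cand_targets.append(int(pick_idx[i]))

        n_uniform = n_samples - n_bias
        if n_uniform:
            cfgs = (
                np.einsum("kij,nj->kni", uniform_mats[n_bias:], local)
                + uniform_centers[n_bias:, None, :]
            )
            scs = scorer.score_many(cfgs, match)
            for i, s in enumerate(scs):
                cand_mats.append(uniform_mats[n_bias + i])
                cand_centers.append(uniform_centers[n_bias + i])
                cand_scores.append(float(s))
                cand_targets.append(-1)

        centers = np.array(cand_centers)
        scores = np.array(cand_scores)

        # refine a stratified, diverse subset of the best starts: every
        # aimed-at receptor atom keeps a couple of slots (so one dominant
        # attraction basin cannot crowd all others out of refinement), and
        # near-duplicate placements (close centroid, similar orientation)
        # share one slot
        targets = np.array(cand_targets)
        ranked = np.argsort(scores, kind="stable")

        def _is_dup(i: int, chosen: list[int]) -> bool:
            for j in chosen:
                if np.linalg.norm(centers[i] - centers[j]) < 1.5:
                    tr = np.trace(cand_mats[i].T @ cand_mats[j])
                    if np.arccos(np.clip((tr - 1) / 2, -1, 1)) < 1.0:
                        return True
            return False

        order: list[int] = []
        distinct = [tgt for tgt in np.unique(targets) if tgt >= 0]
        quota = 2 if 2 * len(distinct) <= self.n_refine else 1
        for tgt in distinct:
            taken = 0
            for i in ranked:
                if targets[i] != tgt or _is_dup(int(i), order):
                    continue
                order.append(int(i))
                taken += 1
                if taken >= quota:
                    break
        for i in ranked:
            if len(order) >= self.n_refine:
                break
            if int(i) in order or _is_dup(int(i), order):
                continue
            order.append(int(i))

        half = box.edge / 2.0
        bounds = [
            (box.center[0] - half, box.center[0] + half),
            (box.center[1] - half, box.center[1] + half),
            (box.center[2] - half, box.center[2] + half),
            (-np.pi, np.pi), (-np.pi, np.pi), (-np.pi, np.pi),
        ]
        refined: list[tuple[float, np.ndarray]] = []
        for i in order:
            base_mat = cand_mats[int(i)]

            def objective(x: np.ndarray) -> float:
                mat = _rotvec_matrix(x[3:]) @ base_mat
                return scorer.score(local @ mat.T + x[:3], match=match)

            x0 = np.concatenate([centers[int(i)], np.zeros(3)])
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxfun": 120},
            )
            mat = _rotvec_matrix(res.x[3:]) @ base_mat
            refined.append((float(res.fun), local @ mat.T + res.x[:3]))

        refined.sort(key=lambda t: t[0])
        poses: list[Pose] = []
        for sc, coords in refined:
            if any(np.abs(coords - p.coords).max() < 0.25 for p in poses):
                continue
            poses.append(
                Pose(coords=coords, score=sc, step_index=box.step_index,
                     repetition=0, engine=self.name)
            )
            if len(poses) >= params.n_poses:
                break
        return poses


# ---------------------------------------------------------------------------
# AutoDock Vina adapter


def write_vina_config(
    box: SearchBox,
    params: EngineParams,
    receptor_path: str | Path,
    ligand_path: str | Path,
    out_path: str | Path,
) -> str:
    """Render a Vina config file; returns the text written."""
    cx, cy, cz = box.center
    text = (
        f"receptor = {receptor_path}\n"
        f"ligand = {ligand_path}\n"
        f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
        f"size_x = {box.edge:g}\nsize_y = {box.edge:g}\nsize_z = {box.edge:g}\n"
        f"exhaustiveness = {params.exhaustiveness}\n"
        f"num_modes = {params.n_poses}\n"
        f"seed = {params.seed}\n"
        f"out = {out_path}\n"
    )
    return text


def parse_vina_output(path: str | Path, step_index: int = 0,
                      repetition: int = 0) -> list[Pose]:
    """Parse a Vina output PDBQT (MODEL blocks + REMARK VINA RESULT lines)."""
    models = read_pose_models(path)
    poses = []
    for coords, score in models:
        if score is None:
            raise EngineError(f"pose model in {path} lacks a VINA RESULT score")
        poses.append(
            Pose(coords=coords, score=score, step_index=step_index,
                 repetition=repetition, engine="vina")
        )
    return poses


class VinaEngine:
    """Adapter invoking an external AutoDock Vina binary on PDBQT inputs."""

    name = "vina"

    def __init__(
        self,
        receptor_pdbqt: str | Path,
        ligand_pdbqt: str | Path,
        executable: str = "vina",
        workdir: str | Path = ".",
    ):
        self.receptor_pdbqt = Path(receptor_pdbqt)
        self.ligand_pdbqt = Path(ligand_pdbqt)
        self.executable = executable
        self.workdir = Path(workdir)

    def dock(
        self,
        receptor: Structure,
        ligand: Structure,
        box: SearchBox,
        params: EngineParams,
    ) -> list[Pose]:
        if shutil.which(self.executable) is None:
            raise EngineError(
                f"docking engine executable {self.executable!r} not found on PATH"
            )
        self.workdir.mkdir(parents=True, exist_ok=True)
        tag = f"step{box.step_index:03d}_seed{params.seed}"
        out_path = self.workdir / f"poses_{tag}.pdbqt"
        cfg_path = self.workdir / f"config_{tag}.txt"
        cfg_path.write_text(
            write_vina_config(box, params, self.receptor_pdbqt,
                              self.ligand_pdbqt, out_path)
        )
        proc = subprocess.run(
            [self.executable, "--config", str(cfg_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise EngineError(
                f"engine exited with status {proc.returncode}",
                log=proc.stdout + proc.stderr,
            )
        try:
            return parse_vina_output(out_path, step_index=box.step_index)
        except Exception as exc:
            raise EngineError(
                f"could not parse engine output {out_path}: {exc}",
                log=proc.stdout + proc.stderr,
            ) from exc
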