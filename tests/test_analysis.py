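"""Pose-series analysis: orientation, change flags, plateaus, filter ranking,
binder classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tomodock.analysis import (
    ChangeFlags,
    NicheDefinition,
    StepMetrics,
    classify_ligand,
    flag_changes,
    identify_filter,
    plateaus,
    ring_plane_angle,
    step_metrics,
)
from tomodock.engines import Pose
from tomodock.runner import Trajectory
from tomodock.structures import ResidueRef, Structure

from conftest import make_atoms


def _hexagon(radius=1.4):
    return np.array(
        [(radius * np.cos(np.pi * k / 3), radius * np.sin(np.pi * k / 3), 0.0)
         for k in range(6)]
    )


class TestRingPlaneAngle:
    def test_flat_ring_is_zero(self):
        assert ring_plane_angle(_hexagon()) == pytest.approx(0.0, abs=1e-9)

    def test_ring_containing_axis_is_ninety(self):
        ring = _hexagon() @ Rotation.from_euler("x", 90, degrees=True).as_matrix().T
        assert ring_plane_angle(ring) == pytest.approx(90.0, abs=1e-9)

    def test_matches_full_eigendecomposition(self, rng):
        """Angle agrees with a brute-force least-squares plane fit."""
        ring = _hexagon()
        for _ in range(20):
            rot = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(0, 2**31 - 1))))
            placed = rot.apply(ring) + rng.uniform(-5, 5, 3)
            centered = placed - placed.mean(0)
            w, v = np.linalg.eigh(centered.T @ centered)
            normal = v[:, np.argmin(w)]
            expected = np.degrees(np.arccos(abs(normal[2])))
            assert ring_plane_angle(placed) == pytest.approx(expected, abs=1e-6)

    def test_collinear_ring_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ring_plane_angle(np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0)]))


def _trajectory_from_coords(coord_list):
    poses = [Pose(coords=np.asarray(c), score=-1.0 - i, step_index=i + 1)
             for i, c in enumerate(coord_list)]
    return Trajectory(steps=list(range(1, len(poses) + 1)), best_poses=poses)


def _ligand_with_ring():
    ring = _hexagon()
    tail = np.array([(2.7, 0, 0), (4.0, 0, 0)])
    coords = np.vstack([ring, tail])
    atoms = make_atoms(coords, resname="LIG", name_prefix="C", hetero=True)
    return Structure(atoms, id="lig"), [f"C{i}" for i in range(1, 7)]


class TestStepMetrics:
    def test_depth_orientation_and_niche_contact(self):
        lig, ring_names = _ligand_with_ring()
        receptor = Structure(make_atoms([(6.0, 0, 5.0)], resname="NIC"),
                             id="rec")
        niche = NicheDefinition([ResidueRef("A", 1)], engagement_cutoff=4.0)
        vertical = lig.coords @ Rotation.from_euler(
            "x", 90, degrees=True).as_matrix().T + np.array([1.0, 0, 5.0])
        flat_far = lig.coords + np.array([-8.0, 0, 1.0])
        traj = _trajectory_from_coords([flat_far, vertical])
        metrics = step_metrics(traj, lig, ring_names, niche, receptor)
        assert metrics[0].orientation_angle == pytest.approx(0.0, abs=1e-6)
        assert not metrics[0].tail_in_niche
        assert metrics[1].orientation_angle == pytest.approx(90.0, abs=1e-6)
        assert metrics[1].tail_in_niche  # tail tip at (5,0,5), 1 A from NIC
        assert metrics[1].depth == pytest.approx(
            float(vertical.mean(0)[2]), abs=1e-9
        )

    def test_too_few_ring_atoms_rejected(self):
        lig, _ = _ligand_with_ring()
        niche = NicheDefinition([], engagement_cutoff=4.0)
        traj = _trajectory_from_coords([lig.coords])
        with pytest.raises(ValueError, match="ring"):
            step_metrics(traj, lig, ["C1", "C2"], niche,
                         Structure(make_atoms([(0, 0, 0)]), id="r"))


class TestFlagChanges:
    def _metrics(self, depths, angles=None):
        angles = angles or [0.0] * len(depths)
        return [
            StepMetrics(step_index=i + 1, best_score=-1.0, depth=d,
                        orientation_angle=a, tail_in_niche=False)
            for i, (d, a) in enumerate(zip(depths, angles))
        ]

    def test_identical_poses_not_flagged(self):
        coords = np.zeros((4, 3))
        traj = _trajectory_from_coords([coords, coords, coords])
        flags = flag_changes(self._metrics([1.0, 1.0, 1.0]), traj)
        assert flags[0].significant  # entry step always flagged
        assert not flags[1].significant and not flags[2].significant

    def test_translation_flags_depth_and_rmsd(self):
        c0 = np.zeros((4, 3))
        c1 = c0 + np.array([0, 0, 2.0])
        traj = _trajectory_from_coords([c0, c1])
        flags = flag_changes(self._metrics([0.0, 2.0]), traj,
                             depth_tol=0.5, rmsd_tol=1.0, angle_tol=20.0)
        assert flags[1].depth_changed and flags[1].rmsd_changed
        assert flags[1].significant and not flags[1].orientation_changed

    def test_single_planted_jump_matches_pairwise_diff(self, rng):
        """Exactly one interior step is flagged, at the planted jump."""
        n = 10
        jump_at = 6
        coords = [np.zeros((3, 3))] * (jump_at - 1)
        coords += [np.full((3, 3), 5.0)] * (n - jump_at + 1)
        depths = [0.0] * (jump_at - 1) + [5.0] * (n - jump_at + 1)
        traj = _trajectory_from_coords(coords)
        flags = flag_changes(self._metrics(depths), traj)
        flagged = [f.step_index for f in flags if f.significant]
        assert flagged == [1, jump_at]


class TestPlateaus:
    def _flags(self, flagged, n):
        return [
            ChangeFlags(step_index=k, depth_changed=False,
                        orientation_changed=False, rmsd_changed=False,
                        significant=(k in flagged))
            for k in range(1, n + 1)
        ]

    def test_documented_grouping(self):
        groups = plateaus(self._flags({1, 3, 8, 10}, 15))
        assert groups == [[1, 2], [3, 4, 5, 6, 7], [8, 9],
                          [10, 11, 12, 13, 14, 15]]

    def test_no_interior_flags_single_group(self):
        groups = plateaus(self._flags({1}, 8))
        assert groups == [list(range(1, 9))]

    def test_round_trip_reconstructs_flags(self, rng):
        """The first step of each group recovers the flagged set exactly."""
        for _ in range(25):
            n = int(rng.integers(2, 20))
            flagged = {1} | {
                int(k) for k in rng.choice(range(2, n + 1),
                                           size=rng.integers(0, n - 1),
                                           replace=False)
            } if n > 2 else {1}
            groups = plateaus(self._flags(flagged, n))
            # partition property
            flat = [s for g in groups for s in g]
            assert flat == list(range(1, n + 1))
            assert {g[0] for g in groups} == flagged


def _inclusion_frame(rows):
    return pd.DataFrame(
        rows, columns=["chain", "resi", "resn", "atom_name", "element", "z",
                       "first_inclusion"]
    )


def _mkflags(flagged, n):
    return [
        ChangeFlags(step_index=k, depth_changed=False,
                    orientation_changed=False, rmsd_changed=False,
                    significant=(k in flagged))
        for k in range(1, n + 1)
    ]


class TestIdentifyFilter:
    def _table(self):
        rows = []
        # residue 10: 4 atoms entering at flagged step 5 -> candidate
        for i in range(4):
            rows.append(("A", 10, "FLT", f"C{i}", "C", 5.0, 5))
        # residue 20: 3 atoms entering at plateau step 3 only -> excluded
        for i in range(3):
            rows.append(("A", 20, "PLA", f"C{i}", "O", 3.0, 3))
        # residue 30: 2 atoms at flagged step 5 -> below threshold
        for i in range(2):
            rows.append(("A", 30, "SMA", f"C{i}", "N", 5.0, 5))
        # residue 40: niche member with 5 atoms at flagged step 5
        for i in range(5):
            rows.append(("A", 40, "NIC", f"O{i}", "O", 5.0, 5))
        return _inclusion_frame(rows)

    def _niche(self):
        return NicheDefinition([ResidueRef("A", 40)], engagement_cutoff=4.0)

    def test_flagged_entry_with_enough_atoms_is_candidate(self):
        cands, niche_rep = identify_filter(
            self._table(), _mkflags({1, 5}, 8), self._niche(),
            min_new_atoms=3, window=1,
        )
        assert [c.residue.residue_seq for c in cands] == [10]
        assert cands[0].triggering_steps == [5]
        assert cands[0].polarity == "apolar"
        assert [c.residue.residue_seq for c in niche_rep] == [40]

    def test_plateau_only_entries_excluded(self):
        cands, _ = identify_filter(self._table(), _mkflags({1, 6}, 8),
                                   self._niche(), min_new_atoms=3, window=0)
        assert cands == []

    def test_window_extends_backwards(self):
        cands, _ = identify_filter(self._table(), _mkflags({1, 6}, 8),
                                   self._niche(), min_new_atoms=3, window=1)
        assert [c.residue.residue_seq for c in cands] == [10]

    def test_no_interior_flags_no_candidates(self):
        cands, niche_rep = identify_filter(self._table(), _mkflags({1}, 8),
                                           self._niche())
        assert cands == [] and niche_rep == []

    def test_monotone_in_min_new_atoms(self, rng):
        """Raising the atom threshold never adds candidates."""
        for _ in range(10):
            rows = []
            for resi in range(1, 8):
                n_atoms = int(rng.integers(1, 6))
                step = int(rng.integers(1, 9))
                for i in range(n_atoms):
                    rows.append(("A", resi, "RES", f"C{i}", "C", 1.0 * step,
                                 step))
            table = _inclusion_frame(rows)
            flagged = {1} | {int(k) for k in rng.choice(range(2, 9), 3,
                                                        replace=False)}
            flags = _mkflags(flagged, 8)
            niche = NicheDefinition([], engagement_cutoff=4.0)
            prev = None
            for thresh in (1, 2, 3, 4, 5):
                cands, _ = identify_filter(table, flags, niche,
                                           min_new_atoms=thresh)
                current = {c.residue.residue_seq for c in cands}
                if prev is not None:
                    assert current <= prev
                prev = current


def _mk_metrics(specs):
    return [
        StepMetrics(step_index=i + 1, best_score=-1.0, depth=d,
                    orientation_angle=a, tail_in_niche=t)
        for i, (d, a, t) in enumerate(specs)
    ]


class TestClassifyLigand:
    def test_binder_like_both_criteria(self):
        metrics = _mk_metrics([
            (0.0, 10.0, False),
            (2.0, 85.0, True), (2.1, 88.0, True), (2.0, 86.0, True),
            (7.0, 80.0, False), (7.1, 82.0, False),
        ])
        flags = _mkflags({1, 2, 5}, 6)
        out = classify_ligand(metrics, flags, base_depth=6.0)
        assert out.label == "binder-like"
        assert out.engages_niche_perpendicular and out.reaches_base
        assert out.engagement_plateau == (2, 4)

    def test_flat_orientation_fails_criterion_a(self):
        metrics = _mk_metrics([
            (0.0, 10.0, False),
            (2.0, 30.0, True), (2.1, 35.0, True),
            (7.0, 80.0, False),
        ])
        flags = _mkflags({1, 2, 4}, 4)
        out = classify_ligand(metrics, flags, base_depth=6.0)
        assert out.label == "non-binder-like"
        assert not out.engages_niche_perpendicular and out.reaches_base

    def test_no_niche_contact_fails_criterion_a(self):
        metrics = _mk_metrics([
            (0.0, 90.0, False), (2.0, 90.0, False), (7.0, 90.0, False),
        ])
        flags = _mkflags({1, 2, 3}, 3)
        out = classify_ligand(metrics, flags, base_depth=6.0)
        assert out.label == "non-binder-like"
        assert not out.engages_niche_perpendicular

    def test_shallow_final_plateau_fails_criterion_b(self):
        metrics = _mk_metrics([
            (0.0, 10.0, False), (2.0, 85.0, True), (2.1, 86.0, True),
        ])
        flags = _mkflags({1, 2}, 3)
        out = classify_ligand(metrics, flags, base_depth=6.0)
        assert out.label == "non-binder-like"
        assert out.engages_niche_perpendicular and not out.reaches_base
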