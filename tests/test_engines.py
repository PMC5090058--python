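"""Toy scoring function, mock search engine, and the Vina adapter."""

import numpy as np
import pytest

from tomodock.engines import (
    ATTRACT_DIST,
    ATTRACT_WEIGHT,
    ATTRACT_WIDTH,
    CLASH_RADIUS,
    CLASH_WEIGHT,
    DEFAULT_CUTOFF,
    EngineError,
    EngineParams,
    MockEngine,
    Pose,
    ToyScorer,
    VinaEngine,
    _MATCHED,
    parse_vina_output,
    pharm_label,
    toy_score,
    write_vina_config,
)
from tomodock.scan import SearchBox
from tomodock.structures import Atom, Structure


def _labelled(coords, labels, elements=None):
    elements = elements or ["C"] * len(coords)
    atoms = [
        Atom(serial=i + 1, name=f"X{i + 1}", element=e, residue_name="LIG",
             residue_seq=1 + i // 4, chain="A",
             coords=tuple(float(v) for v in c), pharm_label=l)
        for i, (c, l, e) in enumerate(zip(coords, labels, elements))
    ]
    return Structure(atoms, id="lab")


def brute_force_score(receptor, lig_coords, lig_labels, cutoff=DEFAULT_CUTOFF):
    """Independent O(N*M) double loop over all atom pairs."""
    total = 0.0
    for a in receptor.atoms:
        la = pharm_label(a)
        for c, lb in zip(lig_coords, lig_labels):
            d = float(np.linalg.norm(np.asarray(a.coords) - c))
            if d <= cutoff:
                total += CLASH_WEIGHT * max(0.0, CLASH_RADIUS - d) ** 2
                if (la, lb) in _MATCHED:
                    total -= ATTRACT_WEIGHT * np.exp(
                        -((d - ATTRACT_DIST) ** 2) / ATTRACT_WIDTH
                    )
    return total


class TestToyScore:
    def test_no_pairs_within_cutoff_is_zero(self):
        rec = _labelled([(0, 0, 0)], ["acceptor"], ["O"])
        assert toy_score(rec, np.array([[20.0, 0, 0]]), ["donor"]) == 0.0

    def test_matched_pair_at_optimum_is_minus_a(self):
        rec = _labelled([(0, 0, 0)], ["acceptor"], ["O"])
        s = toy_score(rec, np.array([[ATTRACT_DIST, 0, 0]]), ["donor"])
        assert s == pytest.approx(-ATTRACT_WEIGHT, abs=1e-12)

    def test_unmatched_pair_has_no_attraction(self):
        rec = _labelled([(0, 0, 0)], ["apolar"])
        assert toy_score(rec, np.array([[3.0, 0, 0]]), ["donor"]) == 0.0

    def test_matches_brute_force_double_loop(self, rng):
        rec_coords = rng.uniform(-6, 6, (25, 3))
        rec_labels = rng.choice(["apolar", "donor", "acceptor", "aromatic"], 25)
        rec = _labelled(rec_coords, rec_labels)
        lig_labels = list(rng.choice(["apolar", "donor", "acceptor", "aromatic"], 6))
        for _ in range(100):
            lig = rng.uniform(-8, 8, (6, 3))
            assert toy_score(rec, lig, lig_labels) == pytest.approx(
                brute_force_score(rec, lig, lig_labels), abs=1e-9
            )

    def test_locality_far_atom_changes_nothing(self, rng):
        rec = _labelled(rng.uniform(-3, 3, (10, 3)),
                        ["acceptor"] * 10, ["O"] * 10)
        lig = rng.uniform(-3, 3, (4, 3))
        labels = ["donor"] * 4
        before = toy_score(rec, lig, labels)
        far = rec.atoms + _labelled([(100, 100, 100)], ["acceptor"], ["O"]).atoms
        after = toy_score(Structure(far, id="far"), lig, labels)
        assert after == before

    def test_invariant_under_joint_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        rec_coords = rng.uniform(-4, 4, (12, 3))
        rec = _labelled(rec_coords, ["acceptor"] * 12, ["O"] * 12)
        lig = rng.uniform(-4, 4, (5, 3))
        labels = ["donor"] * 5
        rot = Rotation.random(random_state=np.random.RandomState(11))
        shift = rng.uniform(-9, 9, 3)
        rec2 = rec.with_coords(rot.apply(rec_coords) + shift)
        assert toy_score(rec2, rot.apply(lig) + shift, labels) == pytest.approx(
            toy_score(rec, lig, labels), abs=1e-9
        )

    def test_score_many_consistent_with_score(self, rng):
        rec = _labelled(rng.uniform(-5, 5, (15, 3)),
                        rng.choice(["apolar", "acceptor"], 15))
        scorer = ToyScorer(rec)
        labels = ["donor", "aromatic", "apolar"]
        match = scorer.match_matrix(labels)
        cfgs = rng.uniform(-6, 6, (8, 3, 3))
        many = scorer.score_many(cfgs, match)
        singles = [scorer.score(c, match=match) for c in cfgs]
        np.testing.assert_allclose(many, singles, atol=1e-9)


def _well_receptor():
    """A single acceptor atom at the origin: one global attraction well."""
    return _labelled([(0.0, 0.0, 0.0)], ["acceptor"], ["O"])


def _probe_ligand():
    return _labelled([(0.0, 0.0, 0.0)], ["donor"], ["N"])


class TestMockEngine:
    def test_finds_planted_well_within_grid_oracle(self):
        """Best score approaches the dense-grid optimum of the single-well
        system: donor at the attraction distance from the acceptor."""
        rec, lig = _well_receptor(), _probe_ligand()
        box = SearchBox(center=(0, 0, 0), edge=12.0)
        poses = MockEngine().dock(rec, lig, box, EngineParams(seed=3))
        # dense grid oracle over translations (rotation is irrelevant for a
        # single-atom ligand)
        grid = np.mgrid[-6:6:61j, -6:6:61j, -6:6:61j].reshape(3, -1).T
        d = np.linalg.norm(grid, axis=1)
        grid_best = float(
            (CLASH_WEIGHT * np.clip(CLASH_RADIUS - d, 0, None) ** 2
             - np.exp(-((d - ATTRACT_DIST) ** 2)))[d <= 8.0].min()
        )
        assert poses[0].score <= grid_best * 0.95
        assert np.linalg.norm(np.linalg.norm(poses[0].coords)
                              - ATTRACT_DIST) < 0.5

    def test_empty_region_scores_zero(self):
        rec, lig = _well_receptor(), _probe_ligand()
        box = SearchBox(center=(100, 100, 100), edge=12.0)
        poses = MockEngine().dock(rec, lig, box, EngineParams(seed=3))
        assert poses[0].score == 0.0

    def test_same_seed_bit_identical(self):
        rec, lig = _well_receptor(), _probe_ligand()
        box = SearchBox(center=(0, 0, 0), edge=12.0)
        p1 = MockEngine().dock(rec, lig, box, EngineParams(seed=9))
        p2 = MockEngine().dock(rec, lig, box, EngineParams(seed=9))
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            assert a.score == b.score
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_output_sorted_and_centroids_in_box(self, toy_system):
        rec = toy_system["receptor"]
        lig = toy_system["passing"].structure
        box = SearchBox(center=(0, 0, -4), edge=18.0)
        poses = MockEngine().dock(rec, lig, box, EngineParams(seed=5))
        scores = [p.score for p in poses]
        assert scores == sorted(scores)
        for p in poses:
            assert box.contains(p.centroid()[None]).all()

    def test_exhaustiveness_monotone_in_expectation(self):
        """Doubling exhaustiveness cannot worsen the expected best score."""
        rec, lig = _well_receptor(), _probe_ligand()
        box = SearchBox(center=(3, 3, 3), edge=14.0)
        lo, hi = [], []
        for seed in range(20):
            lo.append(MockEngine().dock(rec, lig, box,
                                        EngineParams(exhaustiveness=1,
                                                     seed=seed))[0].score)
            hi.append(MockEngine().dock(rec, lig, box,
                                        EngineParams(exhaustiveness=2,
                                                     seed=seed))[0].score)
        assert np.mean(hi) <= np.mean(lo) + 1e-12

    def test_oversized_ligand_rejected(self):
        rec = _well_receptor()
        big = _labelled([(0, 0, 0), (20, 0, 0)], ["apolar", "apolar"])
        box = SearchBox(center=(0, 0, 0), edge=12.0)
        with pytest.raises(ValueError, match="bounding sphere"):
            MockEngine().dock(rec, big, box, EngineParams())


VINA_OUTPUT = """\
MODEL 1
REMARK VINA RESULT:    -7.1      0.000      0.000
ATOM      1  C1  LIG A   1       1.000   2.000   3.000  1.00  0.00    0.000 C
ENDMDL
MODEL 2
REMARK VINA RESULT:    -6.3      1.500      2.100
ATOM      1  C1  LIG A   1       2.000   3.000   4.000  1.00  0.00    0.000 C
ENDMDL
"""


class TestVinaAdapter:
    def test_parses_models_in_order(self, tmp_path):
        path = tmp_path / "out.pdbqt"
        path.write_text(VINA_OUTPUT)
        poses = parse_vina_output(path, step_index=4)
        assert [p.score for p in poses] == [-7.1, -6.3]
        np.testing.assert_allclose(poses[0].coords[0], (1, 2, 3))
        assert poses[0].step_index == 4 and poses[0].engine == "vina"

    def test_config_echoes_cubic_box_and_params(self, tmp_path):
        box = SearchBox(center=(1.0, 2.0, 3.0), edge=18.0)
        text = write_vina_config(box, EngineParams(exhaustiveness=16, seed=7),
                                 "r.pdbqt", "l.pdbqt", tmp_path / "o.pdbqt")
        assert "size_x = 18" in text and "size_y = 18" in text
        assert "size_z = 18" in text
        assert "center_x = 1.000" in text
        assert "exhaustiveness = 16" in text and "seed = 7" in text

    def test_missing_binary_raises_engine_error(self, toy_system, tmp_path):
        eng = VinaEngine("r.pdbqt", "l.pdbqt",
                         executable="definitely-not-a-real-engine",
                         workdir=tmp_path)
        box = SearchBox(center=(0, 0, 0), edge=18.0)
        with pytest.raises(EngineError, match="not found"):
            eng.dock(toy_system["receptor"], toy_system["passing"].structure,
                     box, EngineParams())

    def test_pose_round_trip_through_writer(self, tmp_path, rng):
        from tomodock.structures import write_pose_model, read_pose_models
        from conftest import random_structure

        s = random_structure(rng, n_atoms=7)
        poses = [Pose(coords=s.coords + k, score=-3.0 - k) for k in range(2)]
        path = tmp_path / "poses.pdb"
        write_pose_model(poses, s, path)
        back = read_pose_models(path)
        for p, (coords, score) in zip(poses, back):
            np.testing.assert_allclose(coords, p.coords, atol=1e-3)
            assert score == pytest.approx(p.score, abs=1e-4)
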