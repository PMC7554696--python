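"""Superposition, RMSD clustering, and structural descriptors."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from dnaintercal import synthetic as syn
from dnaintercal.clustering import (
    ConformerEnsemble,
    chromophore_rotation_angle,
    cluster_kcenters_kmedoids,
    kabsch_superpose,
    min_distance_series,
    pairwise_rmsd,
    read_pdb_ensemble,
    rmsd,
    superpose_ensemble,
    write_pdb_ensemble,
)
from dnaintercal.exceptions import DegenerateGeometryError, InvalidInputError
from oracles import exhaustive_medoid_cost, quaternion_superpose_rmsd


class TestKabsch:
    def test_identical_frames_have_zero_rmsd(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(0, 1, (15, 3))
        _, r = kabsch_superpose(frame, frame, np.arange(15))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_exactly(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(0, 1, (20, 3))
        rot = Rotation.from_euler("xyz", [31, -72, 115], degrees=True)
        moved = rot.apply(frame) + np.array([1.0, -2.0, 0.5])
        _, r = kabsch_superpose(moved, frame, np.arange(20))
        assert r <= 1e-10

    def test_matches_quaternion_oracle(self):
        """SVD-route Kabsch RMSD equals the quaternion-eigenvalue solution
        on random 4-point sets."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, (4, 3))
            b = rng.normal(0, 1, (4, 3))
            _, r = kabsch_superpose(a, b, np.arange(4))
            assert r == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-6)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line, np.arange(5))

    def test_transformation_applies_to_all_atoms(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(0, 1, (10, 3))
        rot = Rotation.from_euler("z", 40, degrees=True)
        moved = rot.apply(frame) + 2.0
        transformed, _ = kabsch_superpose(moved, frame, np.arange(5))
        np.testing.assert_allclose(transformed, frame, atol=1e-9)


class TestRmsdMetric:
    def test_pseudo_metric_properties(self):
        rng = np.random.default_rng(4)
        A, B, C = rng.normal(0, 1, (3, 9, 3))
        assert rmsd(A, B) == pytest.approx(rmsd(B, A), rel=1e-12)
        assert rmsd(A, C) <= rmsd(A, B) + rmsd(B, C) + 1e-12
        assert rmsd(A, A) == 0.0

    def test_pairwise_matches_direct(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (8, 6, 3))
        D = pairwise_rmsd(X)
        # the Gram-matrix route loses ~1e-7 to cancellation near zero
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(rmsd(X[i], X[j]), abs=1e-6)


class TestClustering:
    def test_identical_frames_form_one_cluster(self):
        coords = np.tile(np.arange(30.0).reshape(10, 3), (5, 1, 1))
        ens = ConformerEnsemble(coords=coords)
        res = cluster_kcenters_kmedoids(ens, np.arange(10), cutoff=0.3)
        assert res.n_clusters == 1
        assert res.populations[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_separated_blobs(self, two_blob_ensemble):
        ens, labels = two_blob_ensemble
        res = cluster_kcenters_kmedoids(ens, "ligand_heavy", cutoff=0.3)
        assert res.n_clusters == 2
        true_fracs = np.sort(np.bincount(labels) / len(labels))
        np.testing.assert_allclose(np.sort(res.populations), true_fracs, atol=1e-12)

    def test_kcenters_cutoff_guarantee(self, two_blob_ensemble):
        ens, _ = two_blob_ensemble
        for cutoff in (0.1, 0.3, 0.6):
            res = cluster_kcenters_kmedoids(ens, "ligand_heavy", cutoff=cutoff)
            assert res.max_center_distance <= cutoff

    def test_medoids_match_exhaustive_oracle(self):
        """On <= 12 frames the refined medoids attain the brute-force
        optimal within-cluster RMSD sums for the final assignment."""
        rng = np.random.default_rng(6)
        base = rng.normal(0, 0.3, (5, 3))
        coords = np.concatenate(
            [
                base + rng.normal(0, 0.05, (6, 5, 3)),
                base + 1.5 + rng.normal(0, 0.05, (6, 5, 3)),
            ]
        )
        ens = ConformerEnsemble(coords=coords)
        res = cluster_kcenters_kmedoids(ens, np.arange(5), cutoff=0.4)
        X = coords
        oracle = exhaustive_medoid_cost(X, res.assignments, rmsd)
        for ci, medoid in enumerate(res.medoid_frames):
            members = np.flatnonzero(res.assignments == ci)
            cost = sum(rmsd(X[medoid], X[j]) for j in members)
            assert cost == pytest.approx(oracle[ci], abs=1e-10)

    def test_partition_invariant_under_frame_permutation(self, two_blob_ensemble):
        ens, _ = two_blob_ensemble
        res = cluster_kcenters_kmedoids(ens, "ligand_heavy", cutoff=0.3)
        rng = np.random.default_rng(7)
        perm = rng.permutation(ens.n_frames)
        ens_p = ConformerEnsemble(
            coords=ens.coords[perm], selections=dict(ens.selections)
        )
        res_p = cluster_kcenters_kmedoids(ens_p, "ligand_heavy", cutoff=0.3)
        # same partition up to label names
        a = res.assignments[perm]
        b = res_p.assignments
        mapping = {}
        for x, y in zip(a, b):
            mapping.setdefault(x, y)
            assert mapping[x] == y

    def test_empty_cutoff_rejected(self, two_blob_ensemble):
        ens, _ = two_blob_ensemble
        with pytest.raises(InvalidInputError):
            cluster_kcenters_kmedoids(ens, "ligand_heavy", cutoff=0.0)


class TestDistances:
    def test_single_atoms_at_known_distance(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 0.62
        ens = ConformerEnsemble(coords=coords)
        series, mean = min_distance_series(ens, [0], [1])
        assert mean == pytest.approx(0.62, abs=1e-12)

    def test_subset_selection_gives_zero(self):
        rng = np.random.default_rng(8)
        ens = ConformerEnsemble(coords=rng.normal(0, 1, (3, 6, 3)))
        _, mean = min_distance_series(ens, [0, 1], [0, 1, 2])
        assert mean == 0.0

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 1, (4, 10, 3))
        ens = ConformerEnsemble(coords=coords)
        ia, ib = [0, 3, 5], [6, 7, 8, 9]
        series, _ = min_distance_series(ens, ia, ib)
        for f in range(4):
            assert series[f] == pytest.approx(
                cdist(coords[f, ia], coords[f, ib]).min(), abs=1e-12
            )


class TestRotationAngle:
    def _ring_and_site(self):
        rng = np.random.default_rng(10)
        ring = np.column_stack(
            [np.linspace(-0.5, 0.5, 8), 0.1 * np.sin(np.linspace(0, 3, 8)), np.zeros(8)]
        )
        site = rng.normal(0, 0.5, (10, 3))
        site[:, 2] *= 0.01
        return ring, site

    def test_identical_frames_give_zero(self):
        ring, site = self._ring_and_site()
        frame = np.vstack([ring, site])
        angle = chromophore_rotation_angle(frame, frame, np.arange(8), np.arange(8, 18))
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_rotation_recovered(self):
        ring, site = self._ring_and_site()
        rot = Rotation.from_euler("z", 33, degrees=True)
        fa = np.vstack([ring, site])
        fb = np.vstack([rot.apply(ring), site])
        angle = chromophore_rotation_angle(fa, fb, np.arange(8), np.arange(8, 18))
        assert angle == pytest.approx(33.0, abs=0.5)
        # symmetric in argument order
        assert chromophore_rotation_angle(
            fb, fa, np.arange(8), np.arange(8, 18)
        ) == pytest.approx(angle, abs=1e-9)

    def test_too_few_ring_atoms_rejected(self):
        ring, site = self._ring_and_site()
        frame = np.vstack([ring, site])
        with pytest.raises(DegenerateGeometryError):
            chromophore_rotation_angle(frame, frame, np.arange(3), np.arange(8, 18))


class TestEnsembleIO:
    def test_pdb_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        ens = ConformerEnsemble(coords=rng.normal(0, 0.5, (4, 7, 3)))
        path = tmp_path / "ens.pdb"
        write_pdb_ensemble(ens, path)
        back = read_pdb_ensemble(path)
        assert back.n_frames == 4
        assert back.n_atoms == 7
        # PDB stores Angstroms to 3 decimals -> 1e-4 nm resolution
        np.testing.assert_allclose(back.coords, ens.coords, atol=2e-4)

    def test_selection_spec(self, tmp_path):
        rng = np.random.default_rng(12)
        ens = ConformerEnsemble(coords=rng.normal(0, 0.5, (2, 5, 3)))
        path = tmp_path / "ens.pdb"
        write_pdb_ensemble(ens, path)
        back = read_pdb_ensemble(path, {"all_c": {"elements": ["C"]}})
        assert len(back.selections["all_c"]) == 5


def test_superpose_ensemble_aligns_rigid_copies():
    rng = np.random.default_rng(13)
    base = rng.normal(0, 1, (12, 3))
    frames = [base]
    for ang in (20, 140, 260):
        rot = Rotation.from_euler("y", ang, degrees=True)
        frames.append(rot.apply(base) + rng.normal(0, 1, 3))
    ens = ConformerEnsemble(
        coords=np.array(frames), selections={"site": np.arange(12)}
    )
    aligned = superpose_ensemble(ens, "site")
    for f in aligned.coords[1:]:
        assert rmsd(f, aligned.coords[0]) <= 1e-9


def test_population_recovery_within_binomial_ci():
    """Generator populations {0.85,0.15} and {0.74,0.26} are recovered by
    clustering within the binomial 99% interval."""
    rng = np.random.default_rng(14)
    base = rng.normal(0, 0.3, (12, 3))
    shifted = base + np.array([1.0, 0.0, 0.0])
    for p in (0.85, 0.74):
        ens, labels = syn.gen_conformer_ensemble(
            1000,
            [
                {"center_coords": base, "population_fraction": p, "jitter_sd": 0.02},
                {"center_coords": shifted, "population_fraction": 1 - p,
                 "jitter_sd": 0.02},
            ],
            seed=15,
        )
        res = cluster_kcenters_kmedoids(ens, "ligand_heavy", cutoff=0.3)
        assert res.n_clusters == 2
        margin = 2.576 * np.sqrt(p * (1 - p) / 1000)
        assert abs(max(res.populations) - p) <= margin
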