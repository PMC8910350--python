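"""Circular features, PAM clustering, silhouette k-selection, Ramachandran."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ectodyn as ed
from ectodyn.clustering import (
    PAM,
    circular_features,
    cluster_report,
    pam,
    ramachandran_region,
    select_k,
    silhouette,
)


def dihedral_table(phi, psi, res_names=None):
    """Long-format phi/psi table from (n_frames, n_res) angle arrays."""
    phi = np.atleast_2d(phi)
    psi = np.atleast_2d(psi)
    n_frames, n_res = phi.shape
    res_names = res_names or ["ALA"] * n_res
    rows = []
    for f in range(n_frames):
        for r in range(n_res):
            rows.append((f, "A", 201 + r, res_names[r], phi[f, r], psi[f, r]))
    return pd.DataFrame(rows, columns=["frame", "chain", "residue",
                                       "res_name", "phi", "psi"])


class TestCircularFeatures:
    def test_basic_transform(self):
        df = dihedral_table([[0.0]], [[90.0]])
        feats = circular_features(df)
        assert np.allclose(feats.matrix[0], [0.0, 1.0, 1.0, 0.0], atol=1e-12)

    def test_wraparound_continuity(self):
        df = dihedral_table([[179.5], [-179.5]], [[0.0], [0.0]])
        feats = circular_features(df)
        d = np.linalg.norm(feats.matrix[0] - feats.matrix[1])
        assert d < 0.02

    def test_column_count_five_residues(self):
        rng = np.random.default_rng(0)
        df = dihedral_table(rng.uniform(-180, 180, (4, 5)),
                            rng.uniform(-180, 180, (4, 5)))
        feats = circular_features(df)
        assert feats.matrix.shape == (4, 20)
        # residue-major, phi before psi
        assert feats.angle_labels[0] == (201, "phi")
        assert feats.angle_labels[1] == (201, "psi")

    def test_periodicity_invariance(self):
        rng = np.random.default_rng(1)
        ang = rng.uniform(-180, 180, (3, 2))
        f1 = circular_features(dihedral_table(ang, ang))
        f2 = circular_features(dihedral_table(ang + 360.0, ang - 360.0))
        assert np.allclose(f1.matrix, f2.matrix, atol=1e-10)

    def test_proline_excluded(self):
        rng = np.random.default_rng(2)
        df = dihedral_table(rng.uniform(size=(3, 3)), rng.uniform(size=(3, 3)),
                            res_names=["LEU", "PRO", "LYS"])
        feats = circular_features(df)
        assert all(res != 202 for res, _ in feats.angle_labels)
        assert feats.matrix.shape[1] == 8

    def test_unit_circle_invariant(self):
        rng = np.random.default_rng(3)
        feats = circular_features(dihedral_table(
            rng.uniform(-180, 180, (10, 4)), rng.uniform(-180, 180, (10, 4))))
        s2c2 = feats.matrix[:, 0::2] ** 2 + feats.matrix[:, 1::2] ** 2
        assert np.allclose(s2c2, 1.0, atol=1e-10)

    def test_frames_with_missing_angles_dropped(self):
        phi = np.array([[10.0, 20.0], [np.nan, 30.0], [40.0, 50.0]])
        psi = np.zeros((3, 2))
        feats = circular_features(dihedral_table(phi, psi))
        assert feats.n_frames == 2
        assert feats.n_dropped == 1
        assert feats.frame_ids.tolist() == [0, 2]


class TestPam:
    def test_separated_blobs_exact_partition(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(20, 3))
        b = rng.normal(0, 1, size=(20, 3)) + 10 * math.sqrt(3)
        X = np.vstack([a, b])
        model = pam(X, k=2)
        labels = model.labels_
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_objective_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            X = rng.normal(size=(8, 2)) * 3
            model = pam(X, k=2)
            D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
            best = min(
                D[:, list(pair)].min(axis=1).sum()
                for pair in itertools.combinations(range(8), 2)
            )
            assert model.inertia_ == pytest.approx(best, abs=1e-10)

    def test_k_equals_n_minus_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 2))
        model = pam(X, k=6)
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        non_medoid = set(range(7)) - set(model.medoid_indices_.tolist())
        (pt,) = non_medoid
        assert model.inertia_ == pytest.approx(
            D[pt, model.medoid_indices_].min(), abs=1e-12)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 4))
        model = pam(X, k=5)
        trace = np.asarray(model.objective_trace_)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_labels_canonicalized_by_size(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.5, (30, 2)),
                       rng.normal(20, 0.5, (10, 2))])
        model = pam(X, k=2)
        sizes = np.bincount(model.labels_)
        assert sizes[0] >= sizes[1]
        assert np.all(np.isin(model.labels_, [0, 1]))
        # medoids belong to their own clusters
        for ci, m in enumerate(model.medoid_indices_):
            assert model.labels_[m] == ci

    def test_invalid_k_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            PAM(n_clusters=1).fit(X)
        with pytest.raises(ValueError):
            PAM(n_clusters=5).fit(X)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 6))
        m1, m2 = pam(X, k=3), pam(X, k=3)
        assert np.array_equal(m1.labels_, m2.labels_)
        assert np.array_equal(m1.medoid_indices_, m2.medoid_indices_)

    def test_clara_path_reasonable(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 1, (300, 2)),
                       rng.normal(15, 1, (300, 2))])
        model = PAM(n_clusters=2, max_exact_n=100, clara_samples=3,
                    clara_sample_size=80, random_state=0).fit(X)
        truth = np.repeat([0, 1], 300)
        assert adjusted_rand_score(truth, model.labels_) == 1.0


class TestSilhouette:
    def test_tight_far_pairs(self):
        X = np.array([[0.0, 0], [0.01, 0], [100.0, 0], [100.01, 0]])
        _, mean = silhouette(X, np.array([0, 0, 1, 1]))
        assert mean > 0.99

    def test_unit_square_hand_computation(self):
        # clusters {(0,0),(1,0)} and {(0,1),(1,1)}: a = 1 for every point,
        # b = (1 + sqrt(2)) / 2, s = 1 - 2 / (1 + sqrt(2)) = 3 - 2 sqrt(2)
        X = np.array([[0.0, 0], [1.0, 0], [0.0, 1], [1.0, 1]])
        vals, mean = silhouette(X, np.array([0, 0, 1, 1]))
        expected = 3.0 - 2.0 * math.sqrt(2.0)
        assert np.allclose(vals, expected, atol=1e-12)
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(500, 3))
        _, mean = silhouette(X, rng.integers(0, 2, size=500))
        assert abs(mean) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestSelectK:
    def test_three_von_mises_states(self):
        rng = np.random.default_rng(12)
        means = [(-63.0, -43.0), (-120.0, 135.0), (60.0, 45.0)]
        phi, psi = [], []
        for mp, ms in means:
            phi.append(np.degrees(rng.vonmises(math.radians(mp), 50, 150)))
            psi.append(np.degrees(rng.vonmises(math.radians(ms), 50, 150)))
        df = dihedral_table(np.concatenate(phi)[:, None],
                            np.concatenate(psi)[:, None])
        feats = circular_features(df)
        result = select_k(feats, range(2, 7))
        assert result.best_k == 3

    def test_two_blobs(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(0, 0.5, (40, 2)),
                       rng.normal(8, 0.5, (40, 2))])
        result = select_k(X, range(2, 7))
        assert result.best_k == 2

    def test_table_has_one_row_per_k(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 2))
        result = select_k(X, range(2, 6))
        assert result.table.k.tolist() == [2, 3, 4, 5]

    def test_linker_state_recovery_ari(self, three_state_run, domain_map):
        traj, truth = three_state_run
        dihedrals = ed.backbone_dihedrals(traj, domain_map["linker"])
        feats = circular_features(dihedrals)
        result = select_k(feats, range(2, 6))
        assert result.best_k == 3
        code = {n: i for i, n in enumerate(["closed", "open", "twisted"])}
        true_labels = np.array([code[s] for s in truth.state_labels()])
        ari = adjusted_rand_score(true_labels[feats.frame_ids],
                                  result.model.labels_)
        assert ari >= 0.9


class TestClusterReport:
    def test_fraction_ranking(self):
        X = np.array([[0.0], [0.1], [-0.1], [10.0]])
        model = pam(X, k=2)
        table, _ = cluster_report(model, min_fraction=0.05)
        assert np.allclose(table.fraction, [0.75, 0.25])
        assert table.cluster.tolist() == [1, 2]

    def test_min_fraction_retains_all(self):
        # populations 62 / 16.5 / 11.8 / 10.2 percent heavy-tailed split
        rng = np.random.default_rng(15)
        sizes = [620, 165, 118, 102]
        centers = [0.0, 30.0, 60.0, 90.0]
        X = np.concatenate([
            rng.normal(c, 0.5, size=(s, 1)) for c, s in zip(centers, sizes)
        ])
        model = pam(X, k=4)
        table, _ = cluster_report(model, min_fraction=0.05)
        assert len(table) == 4
        assert not table.below_min_fraction.any()
        assert np.all(np.diff(table.n_frames) <= 0)

    def test_medoid_structures_exported(self, three_state_run, domain_map):
        traj, _ = three_state_run
        dihedrals = ed.backbone_dihedrals(traj, domain_map["linker"])
        feats = circular_features(dihedrals)
        model = pam(feats, k=3)
        table, medoids = cluster_report(model, feats, traj=traj)
        assert len(medoids) == 3
        # medoid structure reproduces the dihedral row of its frame
        frame_id = int(table.medoid_frame.iloc[0])
        ref_rows = dihedrals[dihedrals.frame == frame_id]
        got = ed.backbone_dihedrals(medoids[0], domain_map["linker"])
        merged = ref_rows.merge(got, on="residue", suffixes=("_ref", "_got"))
        defined = merged.dropna()
        assert np.allclose(defined.phi_ref, defined.phi_got, atol=0.01)
        assert np.allclose(defined.psi_ref, defined.psi_got, atol=0.01)


class TestRamachandran:
    @pytest.mark.parametrize("phi,psi,region", [
        (-57.0, -47.0, "favored"),   # ideal right-handed alpha
        (-120.0, 130.0, "favored"),  # beta
        (60.0, 45.0, "allowed"),     # left-handed alpha
        (60.0, -120.0, "outlier"),
        (0.0, 0.0, "outlier"),
    ])
    def test_region_assignment(self, phi, psi, region):
        assert ramachandran_region(phi, psi) == region

    def test_boundary_is_more_permissive(self):
        # exactly on the favored beta edge -> favored, not allowed
        assert ramachandran_region(-45.0, 90.0) == "favored"

    def test_undefined_angles_rejected(self):
        with pytest.raises(ValueError):
            ramachandran_region(float("nan"), 10.0)

    def test_periodic_input(self):
        assert ramachandran_region(-57.0 + 360.0, -47.0 - 360.0) == "favored"
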