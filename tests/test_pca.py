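"""PCA eigen-solutions, free-energy landscapes and density clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA as SKPCA

from amdreweigh import (
    ClusterAssignment,
    DihedralSeries,
    FrameWeights,
    PCModel,
    TrajectorySet,
    cluster_timeline,
    cpca,
    density_cluster,
    dpca,
    fel,
    kabsch_rotation,
    kt,
    superpose,
)


def random_series(n_frames, n_res, seed):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180, 180, size=(n_frames, n_res))
    psi = rng.uniform(-180, 180, size=(n_frames, n_res))
    return DihedralSeries(np.arange(1, n_res + 1), phi, psi)


def make_model(projections, seed=0):
    """Wrap raw projections as a PCModel (identity eigenbasis)."""
    projections = np.asarray(projections, dtype=float)
    n, k = projections.shape
    var = projections.var(axis=0, ddof=1)
    return PCModel(
        "dihedral_sincos",
        np.zeros(k),
        var,
        np.eye(k),
        projections - projections.mean(axis=0),
        np.zeros(n, dtype=int),
    )


class TestDpca:
    def test_two_state_series_loads_everything_on_pc1(self):
        a = np.tile([[-63.0, -43.0]], (4, 1))
        b = np.tile([[-157.0, 161.0]], (4, 1))
        pp = np.array([a if i % 2 == 0 else b for i in range(40)])
        series = DihedralSeries(np.arange(1, 5), pp[:, :, 0], pp[:, :, 1])
        model = dpca(series)
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        # PC1 separates the two states with opposite signs
        proj = model.projections[:, 0]
        assert np.all(np.sign(proj[::2]) != np.sign(proj[1::2]))

    def test_matches_sklearn_eigendecomposition(self):
        series = random_series(50, 4, seed=1)
        model = dpca(series)
        phi = np.radians(series.phi)
        psi = np.radians(series.psi)
        data = np.concatenate(
            [np.cos(phi), np.sin(phi), np.cos(psi), np.sin(psi)], axis=1
        )
        sk = SKPCA().fit(data)
        n_keep = min(model.eigenvalues.size, sk.explained_variance_.size)
        assert np.allclose(
            model.eigenvalues[:n_keep], sk.explained_variance_[:n_keep], atol=1e-8
        )
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_frames_get_identical_projections(self):
        series = random_series(10, 3, seed=2)
        doubled = DihedralSeries(
            series.res_ids,
            np.vstack([series.phi, series.phi]),
            np.vstack([series.psi, series.psi]),
        )
        model = dpca(doubled)
        assert np.allclose(model.projections[:10], model.projections[10:])

    def test_constant_series_rejected(self):
        pp = np.tile([[-63.0, -43.0]], (10, 3, 1))
        series = DihedralSeries(np.arange(1, 4), pp[:, :, 0], pp[:, :, 1])
        with pytest.raises(ValueError, match="constant"):
            dpca(series)

    def test_projection_covariance_is_diagonal_eigenvalues(self):
        model = dpca(random_series(60, 3, seed=3))
        cov = np.cov(model.projections.T)
        assert np.allclose(cov, np.diag(model.eigenvalues), atol=1e-10)


class TestCpca:
    @staticmethod
    def _random_traj(n_frames, n_atoms, seed, rigid=False, base=None):
        rng = np.random.default_rng(seed)
        if base is None:
            base = rng.normal(size=(n_atoms, 3)) * 3.0
        coords = np.empty((n_frames, n_atoms, 3))
        for f in range(n_frames):
            frame = base if rigid else base + rng.normal(0, 0.4, size=base.shape)
            rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            coords[f] = frame @ rot.T + rng.normal(0, 5.0, size=3)
        names = np.array(["CA"] * n_atoms)
        ids = np.arange(1, n_atoms + 1)
        return TrajectorySet(coords, names, ids, np.array(["ALA"] * n_atoms))

    def test_rigid_body_motion_gives_zero_eigenvalues(self):
        traj = self._random_traj(12, 6, seed=4, rigid=True)
        model = cpca(traj, atom_selection=np.arange(6))
        assert np.max(model.eigenvalues) < 1e-10

    def test_kabsch_matches_quaternion_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ref = rng.normal(size=(5, 3))
            rot_true = Rotation.random(random_state=rng.integers(2**31))
            mobile = ref @ rot_true.as_matrix().T
            ref0 = ref - ref.mean(axis=0)
            mob0 = mobile - mobile.mean(axis=0)
            rot = kabsch_rotation(mob0, ref0)
            oracle, _ = Rotation.align_vectors(ref0, mob0)
            rmsd_ours = np.sqrt(np.mean(np.sum((mob0 @ rot - ref0) ** 2, axis=1)))
            rmsd_oracle = np.sqrt(
                np.mean(np.sum((oracle.apply(mob0) - ref0) ** 2, axis=1))
            )
            assert abs(rmsd_ours - rmsd_oracle) < 1e-9

    def test_two_conformer_trajectory_is_rank_one(self):
        rng = np.random.default_rng(6)
        conf_a = rng.normal(size=(5, 3)) * 2
        conf_b = conf_a + rng.normal(size=(5, 3))
        coords = np.array([conf_a if i % 2 == 0 else conf_b for i in range(20)])
        traj = TrajectorySet(
            coords, np.array(["CA"] * 5), np.arange(1, 6), np.array(["ALA"] * 5)
        )
        model = cpca(traj, atom_selection=np.arange(5))
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_global_rototranslation(self):
        traj = self._random_traj(8, 5, seed=7)
        model_a = cpca(traj, atom_selection=np.arange(5))
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = TrajectorySet(
            traj.coords @ rot.T + np.array([4.0, -2.0, 9.0]),
            traj.atom_names, traj.res_ids, traj.res_names,
        )
        model_b = cpca(moved, atom_selection=np.arange(5))
        assert np.allclose(model_a.eigenvalues, model_b.eigenvalues, atol=1e-9)

    def test_small_selection_rejected(self, helix_traj):
        with pytest.raises(ValueError, match="3 atoms"):
            cpca(helix_traj, atom_selection=np.array([0, 1]))


class TestFel:
    def test_gaussian_projections_give_harmonic_pmf(self):
        rng = np.random.default_rng(8)
        proj = rng.normal(0, 1.0, size=(200_000, 2)) * np.array([2.0, 1.0])
        model = make_model(proj)
        grid = fel(model, FrameWeights.uniform(proj.shape[0]), bins=60)
        lam1 = model.eigenvalues[0]
        q = grid.centers[0]
        # PMF along PC1 at the PC2 minimum row: quadratic with curvature kT/lam1
        j0 = grid.min_bin()[1]
        sel = grid.mask[:, j0] & (np.abs(q) < 2 * np.sqrt(lam1))
        coeff = np.polyfit(q[sel], grid.pmf[sel, j0], 2)[0]
        assert coeff == pytest.approx(0.5 * kt() / lam1, rel=0.10)
        assert np.nanmin(grid.pmf) == 0.0

    def test_missing_component_rejected(self):
        model = make_model(np.random.default_rng(0).normal(size=(100, 2)))
        with pytest.raises(ValueError):
            fel(model, FrameWeights.uniform(100), components=(1, 5))


class TestDensityCluster:
    def test_single_blob_one_cluster(self):
        rng = np.random.default_rng(9)
        proj = rng.normal(size=(20_000, 3))
        assign = density_cluster(make_model(proj), n_components=3, bins=12,
                                 threshold=0.1)
        assert assign.n_clusters == 1
        assert (assign.labels == 1).mean() >= 0.99

    @pytest.mark.parametrize("seed", range(3))
    def test_two_blob_mixture_recovers_occupancies(self, seed):
        rng = np.random.default_rng(seed)
        n = 20_000
        a = rng.normal(0.0, 0.5, size=(int(0.6 * n), 3))
        b = rng.normal(5.0, 0.5, size=(n - int(0.6 * n), 3))
        proj = np.vstack([a, b])
        assign = density_cluster(make_model(proj), n_components=3, bins=30,
                                 threshold=0.1)
        assert assign.n_clusters == 2
        assert assign.occupancies[0] == pytest.approx(0.6, abs=0.03)
        assert assign.occupancies[1] == pytest.approx(0.4, abs=0.03)

    def test_threshold_one_keeps_only_global_maximum(self):
        rng = np.random.default_rng(10)
        proj = np.vstack(
            [rng.normal(0, 0.5, size=(5000, 2)), rng.normal(6, 0.5, size=(3000, 2))]
        )
        assign = density_cluster(make_model(proj), n_components=2, bins=30,
                                 threshold=1.0)
        assert assign.n_clusters == 1

    def test_representative_frame_belongs_to_cluster(self):
        rng = np.random.default_rng(11)
        proj = rng.normal(size=(5000, 3))
        assign = density_cluster(make_model(proj), n_components=3, bins=15)
        for k, rep in enumerate(assign.representative_frames, start=1):
            assert assign.labels[rep] == k

    def test_bad_threshold_rejected(self):
        model = make_model(np.random.default_rng(0).normal(size=(100, 3)))
        with pytest.raises(ValueError):
            density_cluster(model, threshold=0.0)


class TestClusterTimeline:
    @staticmethod
    def _assign(labels, n_clusters):
        labels = np.asarray(labels)
        return ClusterAssignment(
            labels,
            np.array([(labels == k + 1).mean() for k in range(n_clusters)]),
            np.zeros(n_clusters, dtype=int),
            np.zeros((n_clusters, 1)),
        )

    def test_transition_counting(self):
        assign = self._assign([1, 1, 2, 2, 1], 2)
        _, _, trans = cluster_timeline(assign, np.arange(5.0))
        assert trans[0, 1] == 1 and trans[1, 0] == 1

    def test_single_cluster_has_no_transitions(self):
        assign = self._assign([1, 1, 1, 1], 1)
        _, _, trans = cluster_timeline(assign, np.arange(4.0))
        assert trans.sum() == 0

    def test_scripted_switch_points(self):
        labels = [1] * 10 + [2] * 5 + [1] * 5 + [2] * 10
        assign = self._assign(labels, 2)
        _, _, trans = cluster_timeline(assign, np.arange(30.0))
        assert trans[0, 1] == 2 and trans[1, 0] == 1

    def test_nonmonotone_times_rejected(self):
        assign = self._assign([1, 1], 1)
        with pytest.raises(ValueError):
            cluster_timeline(assign, np.array([1.0, 0.5]))
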