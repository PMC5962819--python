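import numpy as np
import pytest

from eegunmix import (
    Parcellation,
    build_q_directional,
    build_q_general,
    check_identifiability,
    mne_operator,
    naive_roi_average,
    resolution_matrix,
    sloreta_operator,
    unmix_directional,
    unmix_general,
)
from eegunmix.experiments import electrode_cap_parcellation
from eegunmix.inverse import ResolutionMatrix
from _oracles import q_directional_bruteforce, q_general_bruteforce


def _azimuth_partition(src, L):
    az = np.arctan2(src.positions[:, 1], src.positions[:, 0])
    lab = np.minimum(((az + np.pi) / (2 * np.pi) * L).astype(int), L - 1)
    return Parcellation.from_labels(lab)


class TestParcellation:
    def test_overlap_rejected_naming_voxels(self):
        with pytest.raises(ValueError, match="overlap.*\\[3\\]"):
            Parcellation((np.array([1, 3]), np.array([3, 5])))

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Parcellation((np.array([1]), np.array([], dtype=int)))

    def test_from_labels_ignores_unassigned(self):
        p = Parcellation.from_labels(np.array([0, -1, 1, 0, -1]))
        assert p.n_regions == 2
        assert p.regions[0].tolist() == [0, 3]
        assert p.regions[1].tolist() == [2]


class TestIdentifiability:
    @pytest.mark.parametrize(
        "L,d,variant,expected",
        [
            (6, 19, "general", True),
            (7, 19, "general", False),
            (18, 19, "directional", True),
            (19, 19, "directional", False),
            (1, 2, "general", False),  # 3 unknowns > m = 1
            (1, 2, "directional", True),
        ],
    )
    def test_bounds(self, L, d, variant, expected):
        ok, msg = check_identifiability(L, d, variant)
        assert ok is expected
        assert "maximum admissible" in msg


class TestBuildQGeneral:
    def test_identity_resolution_gives_region_sizes(self, grid200):
        N = grid200.n_voxels
        R = ResolutionMatrix(np.eye(3 * N), "free", grid200)
        parc = _azimuth_partition(grid200, 4)
        sys_ = build_q_general(R, parc)
        for l in range(4):
            for s in range(4):
                blk = sys_.Q[3 * l : 3 * l + 3, 3 * s : 3 * s + 3]
                expected = (
                    len(parc.regions[l]) * np.eye(3) if l == s else np.zeros((3, 3))
                )
                assert np.allclose(blk, expected)

    def test_singleton_regions_pick_out_resolution_blocks(self, rng):
        N = 6
        Rm = rng.standard_normal((3 * N, 3 * N))
        R = ResolutionMatrix(Rm, "free")
        parc = Parcellation.singletons([1, 4], n_voxels=N)
        sys_ = build_q_general(R, parc, cond_threshold=1e12)
        assert np.allclose(sys_.Q[:3, :3], Rm[3:6, 3:6])
        assert np.allclose(sys_.Q[:3, 3:], Rm[3:6, 12:15])
        assert np.allclose(sys_.Q[3:, :3], Rm[12:15, 3:6])

    def test_matches_bruteforce_double_sum(self, rng):
        N = 40
        Rm = rng.standard_normal((3 * N, 3 * N))
        R = ResolutionMatrix(Rm, "free")
        regions = (np.arange(0, 13), np.arange(13, 26), np.arange(26, 40))
        parc = Parcellation(regions, n_voxels=N)
        sys_ = build_q_general(R, parc, cond_threshold=1e12)
        assert np.allclose(sys_.Q, q_general_bruteforce(Rm, regions))

    def test_ill_conditioned_parcellation_raises(self, grid200):
        N = grid200.n_voxels
        R = ResolutionMatrix(np.zeros((3 * N, 3 * N)), "free", grid200)
        with pytest.raises(ArithmeticError, match="unidentifiable"):
            build_q_general(R, _azimuth_partition(grid200, 3))


class TestUnmixGeneral:
    def test_exact_recovery_of_piecewise_constant_source(self, R_free, grid200, rng):
        """The headline guarantee: noiseless model-satisfying sources are
        recovered exactly, while the naive ROI average is not."""
        parc = _azimuth_partition(grid200, 6)
        sys_ = build_q_general(R_free, parc)
        b_true = rng.standard_normal((6, 3))
        J = np.zeros((grid200.n_voxels, 3))
        for l, r in enumerate(parc.regions):
            J[r] = b_true[l]
        jhat = R_free.R @ J.reshape(-1)
        est = unmix_general(jhat, sys_)
        scale = np.abs(b_true).max()
        assert np.abs(est.coefficients - b_true).max() < 1e-6 * scale
        naive = naive_roi_average(jhat, parc)
        assert np.abs(naive - b_true).max() > 1e-2 * scale
        # the reconstructed field is piecewise constant and matches truth
        assert np.allclose(
            est.source_field(), J.reshape(-1), atol=1e-6 * scale
        )

    def test_identity_resolution_equals_naive_average(self, grid200, rng):
        N = grid200.n_voxels
        R = ResolutionMatrix(np.eye(3 * N), "free", grid200)
        parc = _azimuth_partition(grid200, 5)
        jhat = rng.standard_normal(3 * N)
        est = unmix_general(jhat, build_q_general(R, parc))
        assert np.allclose(est.coefficients, naive_roi_average(jhat, parc))

    def test_solve_residual_consistency_for_arbitrary_fields(self, R_free, grid200, rng):
        """Even for non-model sources the solved coefficients reproduce the
        ROI sums of the inverse solution."""
        parc = _azimuth_partition(grid200, 6)
        sys_ = build_q_general(R_free, parc)
        jhat = rng.standard_normal(3 * grid200.n_voxels)
        est = unmix_general(jhat, sys_)
        y = sys_.rhs(jhat)
        back = sys_.Q @ est.coefficients.reshape(-1)
        assert np.abs(back - y).max() < 1e-8 * max(np.abs(y).max(), 1.0)

    def test_dimension_mismatch_rejected(self, R_free, grid200):
        sys_ = build_q_general(R_free, _azimuth_partition(grid200, 4))
        with pytest.raises(ValueError, match="dimension"):
            unmix_general(np.zeros(17), sys_)


class TestBuildQDirectional:
    def test_identity_fixed_resolution_gives_region_sizes(self, grid200):
        N = grid200.n_voxels
        R = ResolutionMatrix(np.eye(N), "fixed", grid200)
        parc = _azimuth_partition(grid200, 5)
        sys_ = build_q_directional(R, parc)
        assert np.allclose(sys_.Q, np.diag([len(r) for r in parc.regions]))

    def test_free_and_collapsed_paths_agree(self, R_free, grid200):
        parc = _azimuth_partition(grid200, 6)
        dirs = grid200.normals
        sys_free = build_q_directional(R_free, parc, dirs)
        sys_fixed = build_q_directional(R_free.collapse(dirs), parc)
        assert np.allclose(sys_free.Q, sys_fixed.Q)

    def test_matches_bruteforce_double_sum(self, rng):
        N = 15
        Rm = rng.standard_normal((3 * N, 3 * N))
        dirs = rng.standard_normal((N, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        regions = (np.arange(0, 5), np.arange(5, 9), np.arange(9, 15))
        parc = Parcellation(regions, n_voxels=N)
        sys_ = build_q_directional(
            ResolutionMatrix(Rm, "free"), parc, dirs, cond_threshold=1e12
        )
        assert np.allclose(sys_.Q, q_directional_bruteforce(Rm, regions, dirs))

    def test_18_surface_regions_well_conditioned(self, R_fixed, grid200, montage):
        parc = electrode_cap_parcellation(grid200, montage)
        assert parc.n_regions == 18
        sys_ = build_q_directional(R_fixed, parc, grid200.normals)
        assert np.isfinite(sys_.condition_number)
        assert sys_.condition_number < 1e3


class TestUnmixDirectional:
    def test_exact_recovery_on_surface_regions(self, R_fixed, grid200, montage, rng):
        parc = electrode_cap_parcellation(grid200, montage)
        sys_ = build_q_directional(R_fixed, parc, grid200.normals)
        a_true = rng.standard_normal(parc.n_regions)
        X = np.zeros(grid200.n_voxels)
        for l, r in enumerate(parc.regions):
            X[r] = a_true[l]
        xhat = R_fixed.R @ X
        est = unmix_directional(xhat, sys_)
        assert np.abs(est.coefficients - a_true).max() < 1e-6 * np.abs(a_true).max()
        assert np.allclose(est.scalar_field(), X, atol=1e-6 * np.abs(a_true).max())

    def test_single_point_roi_identity_resolution_projects(self, grid200, rng):
        N = grid200.n_voxels
        R = ResolutionMatrix(np.eye(3 * N), "free", grid200)
        parc = Parcellation.singletons([17], n_voxels=N)
        dirs = grid200.normals
        sys_ = build_q_directional(R, parc, dirs)
        jhat = rng.standard_normal(3 * N)
        est = unmix_directional(jhat, sys_)
        assert np.allclose(est.coefficients[0], dirs[17] @ jhat[3 * 17 : 3 * 17 + 3])

    def test_samplewise_equals_matrix_solve(self, R_fixed, grid200, rng):
        parc = _azimuth_partition(grid200, 8)
        sys_ = build_q_directional(R_fixed, parc)
        J = rng.standard_normal((grid200.n_voxels, 7))
        est_mat = unmix_directional(J, sys_).coefficients
        for t in range(7):
            est_t = unmix_directional(J[:, t], sys_).coefficients
            assert np.allclose(est_t, est_mat[:, t])

    def test_added_silent_region_leaves_estimates_unchanged(
        self, R_fixed, grid200, montage, rng
    ):
        """Extending the parcellation by a region whose true source is zero
        does not perturb the other regions' noiseless estimates."""
        full = electrode_cap_parcellation(grid200, montage)
        small = Parcellation(full.regions[:10], n_voxels=grid200.n_voxels)
        bigger = Parcellation(full.regions[:11], n_voxels=grid200.n_voxels)
        a_true = rng.standard_normal(10)
        X = np.zeros(grid200.n_voxels)
        for l, r in enumerate(small.regions):
            X[r] = a_true[l]
        xhat = R_fixed.R @ X
        est_small = unmix_directional(xhat, build_q_directional(R_fixed, small))
        est_big = unmix_directional(xhat, build_q_directional(R_fixed, bigger))
        tol = 1e-8 * np.abs(a_true).max()
        assert np.abs(est_small.coefficients - a_true).max() < tol
        assert np.abs(est_big.coefficients[:10] - a_true).max() < tol
        assert abs(est_big.coefficients[10]) < tol

    def test_method_agnostic_recovery(self, K_fixed, grid200, montage, rng):
        """Unmixing depends on the inverse solution only through R: both
        operators recover the same (true) parameters from their own
        noiseless solutions."""
        parc = electrode_cap_parcellation(grid200, montage)
        a_true = rng.standard_normal(parc.n_regions)
        X = np.zeros(grid200.n_voxels)
        for l, r in enumerate(parc.regions):
            X[r] = a_true[l]
        v = K_fixed.gain @ X
        for build in (mne_operator, sloreta_operator):
            op = build(K_fixed, 0.0)
            R = resolution_matrix(op, K_fixed)
            est = unmix_directional(op.apply(v), build_q_directional(R, parc))
            assert np.abs(est.coefficients - a_true).max() < 1e-6 * np.abs(a_true).max()
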