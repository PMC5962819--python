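import numpy as np
import pytest

from eegunmix import (
    MARModel,
    extended_17node_model,
    five_node_mar_model,
    forward,
    mar_simulate,
    nearest_voxels_to_electrodes,
    scenario_point_sources,
    scenario_surface_regions,
    three_node_mar_model,
    true_edge_set,
)
from eegunmix.simulate import _SEVENTEEN_EDGES, region_spatial_profile
from eegunmix.experiments import electrode_cap_parcellation
from _oracles import mar_autocovariance


class TestThreeNodeModel:
    def test_reference_coefficients(self):
        m = three_node_mar_model()
        A1, A2 = m.coeffs
        assert A1[0, 0] == 1.5 and A1[0, 1] == -0.25
        assert A1[1, 0] == -0.25 and A1[1, 1] == 1.8
        assert A1[2, 1] == 0.5 and A1[2, 2] == 1.3
        assert np.allclose(A2, np.diag([-0.95, -0.96, -0.95]))
        assert np.allclose(m.cov, np.eye(3))

    def test_stable(self):
        assert three_node_mar_model().spectral_radius < 1


class TestLargerModels:
    @pytest.mark.parametrize("builder,n", [(five_node_mar_model, 5), (extended_17node_model, 17)])
    def test_size_stability_and_determinism(self, builder, n):
        a, b = builder(3), builder(3)
        assert a.n_vars == n
        assert a.spectral_radius < 1
        assert np.array_equal(a.coeffs, b.coeffs)
        assert not np.array_equal(a.coeffs, builder(4).coeffs)

    def test_zero_coefficients_match_declared_non_edges(self):
        m = extended_17node_model(0)
        declared = {(s, t) for s, t in _SEVENTEEN_EDGES}
        assert true_edge_set(m) == declared
        idx = {lab: i for i, lab in enumerate(m.labels)}
        for s in m.labels:
            for t in m.labels:
                if s != t and (s, t) not in declared:
                    assert np.all(m.coeffs[:, idx[t], idx[s]] == 0.0)

    def test_bidirectional_pair_and_pure_senders(self):
        m = extended_17node_model(1)
        edges = true_edge_set(m)
        assert ("Fp1", "Fp2") in edges and ("Fp2", "Fp1") in edges
        for sender in ("O1", "O2"):
            assert not any(t == sender for _, t in edges)


class TestMarSimulate:
    def test_zero_innovations_give_zero_output(self):
        m = three_node_mar_model()
        m0 = MARModel(m.coeffs, np.zeros((3, 3)), m.labels)
        ts = mar_simulate(m0, 100, seed=0)
        assert np.allclose(ts.values, 0.0)

    def test_deterministic_per_seed(self):
        m = three_node_mar_model()
        a = mar_simulate(m, 200, seed=5)
        b = mar_simulate(m, 200, seed=5)
        c = mar_simulate(m, 200, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.allclose(a.values, c.values)

    def test_unstable_model_refused_with_radius(self):
        bad = MARModel(np.array([[[1.01]]]), np.eye(1))
        with pytest.raises(ValueError, match="1.01"):
            mar_simulate(bad, 10)

    def test_autocovariances_match_yule_walker(self):
        """Sample lag-0/1/2 autocovariances agree with the stationary
        solution of the companion Lyapunov equation within 3 SE."""
        m = three_node_mar_model()
        T = 20000
        X = mar_simulate(m, T, seed=2).values
        gammas = mar_autocovariance(m, 2)
        for lag in range(3):
            emp = X[:, lag:] @ X[:, : T - lag].T / (T - lag)
            expected = gammas[lag]
            # AR(2) near unit root: autocovariance estimates have large
            # variance; a generous 3-SE style bound via batch-means scale
            se = 3 * np.abs(expected).max() / np.sqrt(T / 600)
            assert np.abs(emp - expected).max() < se


class TestPointSourceScenario:
    def test_zero_background_puts_sources_only_at_targets(self, grid200, montage):
        m = three_node_mar_model()
        ts = mar_simulate(m, 50, seed=0)
        labels = ("Fp1", "O1", "P3")
        X = scenario_point_sources(ts, grid200, montage, labels, 0.0, seed=0)
        vox = nearest_voxels_to_electrodes(grid200, montage, labels)
        assert np.allclose(X[vox], ts.values)
        mask = np.ones(grid200.n_voxels, bool)
        mask[vox] = False
        assert np.allclose(X[mask], 0.0)

    def test_background_sd_calibration(self, grid200, montage):
        ts = mar_simulate(three_node_mar_model(), 10000, seed=1)
        X = scenario_point_sources(
            ts, grid200, montage, ("Fp1", "O1", "P3"), 0.1, seed=3
        )
        vox = set(
            nearest_voxels_to_electrodes(grid200, montage, ("Fp1", "O1", "P3"))
        )
        quiet = [u for u in range(grid200.n_voxels) if u not in vox][0]
        assert 0.08 <= X[quiet].std() <= 0.12

    def test_duplicate_target_voxel_rejected(self, montage):
        from eegunmix import spherical_cortex_grid

        tiny = spherical_cortex_grid(3, 0.8, seed=0)
        ts = mar_simulate(three_node_mar_model(), 10, seed=0)
        with pytest.raises(ValueError, match="same nearest voxel"):
            scenario_point_sources(ts, tiny, montage, ("Fp1", "Fp2", "F3"), 0.0)


class TestSurfaceRegionScenario:
    def test_profile_is_one_at_centroid_voxel(self, grid200, montage):
        parc = electrode_cap_parcellation(grid200, montage)
        w = region_spatial_profile(grid200, parc.regions[0])
        assert np.isclose(w.max(), 1.0)

    def test_source_not_constant_within_region(self, grid200, montage):
        parc = electrode_cap_parcellation(grid200, montage)
        ts = mar_simulate(three_node_mar_model(), 20, seed=0)
        X = scenario_surface_regions(ts, grid200, parc, (0, 5, 9), sd_within=0.1, seed=0)
        r = parc.regions[0]
        assert X[r].std(axis=0).max() > 0

    def test_flat_profile_no_noise_reduces_to_exact_model(self, grid200, montage):
        parc = electrode_cap_parcellation(grid200, montage)
        ts = mar_simulate(three_node_mar_model(), 20, seed=0)
        X = scenario_surface_regions(
            ts, grid200, parc, (0, 5, 9), sd_within=0.0, seed=0, profile_width=1e9
        )
        for ch, l in enumerate((0, 5, 9)):
            assert np.allclose(X[parc.regions[l]], ts.values[ch][None, :])
        outside = np.setdiff1d(
            np.arange(grid200.n_voxels),
            np.concatenate([parc.regions[l] for l in (0, 5, 9)]),
        )
        assert np.allclose(X[outside], 0.0)

    def test_unknown_region_id_rejected(self, grid200, montage):
        parc = electrode_cap_parcellation(grid200, montage)
        ts = mar_simulate(three_node_mar_model(), 10, seed=0)
        with pytest.raises(ValueError, match="unknown region"):
            scenario_surface_regions(ts, grid200, parc, (0, 5, 99), 0.1)


class TestForward:
    def test_noiseless_projection_is_exact(self, K_fixed, rng):
        J = rng.standard_normal((K_fixed.n_voxels, 4))
        v = forward(K_fixed, J)
        assert np.allclose(v.values, K_fixed.gain @ J, atol=1e-12)

    def test_output_is_average_referenced(self, K_fixed, rng):
        J = rng.standard_normal((K_fixed.n_voxels, 10))
        v = forward(K_fixed, J, measurement_sd=0.5, seed=1)
        assert np.abs(v.values.sum(axis=0)).max() < 1e-9 * np.abs(v.values).max()

    def test_linearity(self, K_fixed, rng):
        J = rng.standard_normal(K_fixed.n_voxels)
        v1 = forward(K_fixed, J).values
        v2 = forward(K_fixed, 2 * J).values
        assert np.allclose(v2, 2 * v1)

    def test_raw_leadfield_rejected(self, montage, head):
        from eegunmix import spherical_cortex_grid, three_sphere_leadfield

        src = spherical_cortex_grid(5, 0.7, seed=0, head=head)
        K = three_sphere_leadfield(montage, head, src)
        with pytest.raises(ValueError, match="average"):
            forward(K, np.zeros(15))
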