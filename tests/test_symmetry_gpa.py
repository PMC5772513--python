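import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from symmorph.landmark_io import LandmarkConfiguration, SymmetryMap
from symmorph.symmetry_gpa import (
    centroid_size,
    decompose_symmetry,
    gpa,
    procrustes_anova,
    procrustes_distance,
    reflect_relabel,
    reflect_relabel_array,
    shape_space_dims,
)
from symmorph.synthetic_data import SyntheticParams, generate
from symmorph.modularity import component_covariance


class TestReflectRelabel:
    def test_definition_on_midline_and_pair(self):
        # midline landmark stays put; pair rows are reflected and swapped
        smap = SymmetryMap(pairs=[(1, 2)], midline=[0], reflection_axis=0)
        config = LandmarkConfiguration(
            "t", np.array([[0.0, 1.0], [-1.0, 0.0], [1.2, 0.0]]))
        out = reflect_relabel(config, smap)
        np.testing.assert_allclose(out.coords,
                                   [[0.0, 1.0], [-1.2, 0.0], [1.0, 0.0]])

    def test_symmetric_configuration_is_fixed_point(self, toy_smap):
        coords = np.array([[1.0, 2.0], [-1.0, 2.0],
                           [0.5, -1.0], [-0.5, -1.0], [0.0, 0.3]])
        np.testing.assert_array_equal(
            reflect_relabel_array(coords, toy_smap), coords)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_involution(self, seed):
        smap = SymmetryMap(pairs=[(0, 1), (2, 3)], midline=[4],
                           reflection_axis=0)
        coords = np.random.default_rng(seed).normal(size=(5, 2))
        twice = reflect_relabel_array(
            reflect_relabel_array(coords, smap), smap)
        np.testing.assert_array_equal(twice, coords)


class TestGPA:
    def test_identical_shapes_have_zero_distance(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        sample = gpa([tri, tri.copy()])
        assert np.abs(sample.aligned[0] - sample.aligned[1]).max() < 1e-12

    def test_similarity_invariance(self):
        rng = np.random.default_rng(4)
        tri = rng.normal(size=(5, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        other = 2.5 * tri @ rot + np.array([3.0, -1.0])
        sample = gpa([tri, other])
        assert np.abs(sample.aligned[0] - sample.aligned[1]).max() < 1e-9

    def test_distance_matches_rotation_grid_oracle(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        b = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])

        ac = a - a.mean(0)
        bc = b - b.mean(0)
        ac /= centroid_size(ac)
        bc /= centroid_size(bc)

        def objective(theta):
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            return np.sqrt(((bc @ rot - ac) ** 2).sum())

        grid = np.linspace(-np.pi, np.pi, 3600)
        best = grid[np.argmin([objective(t) for t in grid])]
        res = minimize_scalar(objective, bounds=(best - 0.01, best + 0.01),
                              method="bounded",
                              options={"xatol": 1e-12})
        assert procrustes_distance(a, b) == pytest.approx(res.fun, abs=1e-6)

    def test_aligned_configurations_centered_unit_size(self, small_dataset):
        _, reps, coords = (lambda ds: __import__("symmorph").stack_dataset(
            ds.configurations))(small_dataset)
        sample = gpa(coords)
        centroids = sample.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        np.testing.assert_allclose(centroid_size(sample.aligned), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(sample.consensus,
                                   sample.aligned.mean(axis=0), atol=1e-9)

    def test_consensus_invariant_to_specimen_order(self, small_dataset):
        coords = np.stack([c.coords for c in small_dataset.configurations])
        sample1 = gpa(coords)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(coords))
        sample2 = gpa(coords[perm])
        assert np.abs(sample1.consensus - sample2.consensus).max() < 1e-9

    def test_degenerate_configuration_named_in_error(self):
        good = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        bad = np.ones((3, 2))
        with pytest.raises(ValueError, match="degenerate.*spec_b"):
            gpa([good, bad], names=["spec_a", "spec_b"])


class TestDecomposition:
    def test_prealigned_toy_reflection_average(self):
        # single pair at x = -1 and +1.2: symmetric positions -/+1.1,
        # asymmetric x-offsets of magnitude 0.1 (hand arithmetic)
        smap = SymmetryMap(pairs=[(0, 1)], midline=[], reflection_axis=0)
        config = LandmarkConfiguration(
            "t", np.array([[-1.0, 0.5], [1.2, 0.5]]))
        _, dec = decompose_symmetry([config], smap, align=False)
        np.testing.assert_allclose(dec.symmetric[0, :, 0], [-1.1, 1.1])
        np.testing.assert_allclose(dec.asymmetric[0, :, 0], [0.1, 0.1])
        np.testing.assert_allclose(
            dec.symmetric[0] + dec.asymmetric[0], config.coords)

    def test_exactly_symmetric_inputs_have_no_asymmetry(self):
        ds = generate(SyntheticParams(n_specimens=20, seed=2, sigma_fa=0.0,
                                      da_magnitude=0.0, sigma_err=0.0))
        _, dec = decompose_symmetry(ds.configurations, ds.smap)
        assert np.abs(dec.asymmetric).max() < 1e-9

    def test_reconstruction_identity(self, small_dataset):
        sample, dec = decompose_symmetry(small_dataset.configurations,
                                         small_dataset.smap)
        recon = dec.symmetric + dec.asymmetric
        assert np.abs(recon - sample.aligned[:dec.n]).max() < 1e-9

    def test_symmetric_component_invariant_under_reflect_relabel(
            self, small_dataset):
        _, dec = decompose_symmetry(small_dataset.configurations,
                                    small_dataset.smap)
        reflected = reflect_relabel_array(dec.symmetric, small_dataset.smap)
        assert np.abs(reflected - dec.symmetric).max() < 1e-9

    def test_doubled_consensus_is_reflection_symmetric(self, small_dataset):
        sample, dec = decompose_symmetry(small_dataset.configurations,
                                         small_dataset.smap)
        reflected = reflect_relabel_array(sample.consensus, small_dataset.smap)
        assert np.abs(reflected - sample.consensus).max() < 1e-9

    def test_da_mean_is_mean_of_asymmetric_components(self, small_dataset):
        _, dec = decompose_symmetry(small_dataset.configurations,
                                    small_dataset.smap)
        assert np.abs(dec.asymmetric.mean(axis=0) - dec.da_mean).max() < 1e-12

    def test_fa_covariance_invariant_to_constant_asymmetry_shift(
            self, small_dataset):
        # DA removal: a constant added to every asymmetric component moves
        # da_mean but leaves the FA deviations, hence their covariance, alone
        _, dec = decompose_symmetry(small_dataset.configurations,
                                    small_dataset.smap)
        cov0 = component_covariance(dec.flat("fa"))
        shift = np.full_like(dec.asymmetric, 0.37)
        shifted = dec.asymmetric + shift
        fa_shifted = shifted - shifted.mean(axis=0)
        cov1 = component_covariance(fa_shifted.reshape(dec.n, -1))
        assert np.abs(cov1 - cov0).max() < 1e-12


class TestProcrustesANOVA:
    def test_no_variation_means_zero_ss(self):
        ds = generate(SyntheticParams(n_specimens=10, seed=5, sigma_ind=0.0,
                                      sigma_fa=0.0, da_magnitude=0.0,
                                      sigma_err=0.0))
        _, dec = decompose_symmetry(ds.configurations, ds.smap)
        tab = procrustes_anova(dec)
        assert all(abs(tab.ss[e]) < 1e-18 for e in tab.effects)

    def test_pure_directional_asymmetry_loads_on_side_effect(self):
        # no individual variation, no FA: all doubled-sample variation is DA
        ds = generate(SyntheticParams(n_specimens=15, seed=6, sigma_ind=0.0,
                                      sigma_fa=0.0, da_magnitude=0.5,
                                      sigma_err=0.0))
        sample, dec = decompose_symmetry(ds.configurations, ds.smap)
        tab = procrustes_anova(dec)
        total = ((sample.aligned - dec.symmetric.mean(axis=0)) ** 2).sum()
        assert tab.ss["side"] == pytest.approx(
            2 * dec.n * (dec.da_mean ** 2).sum(), rel=1e-12)
        assert tab.ss["side"] == pytest.approx(total, rel=1e-9)
        assert tab.ss["individual"] < 1e-12 * total
        assert tab.ss["individual_x_side"] < 1e-12 * total

    @pytest.mark.parametrize("fixture", ["small_dataset", "replicate_dataset"])
    def test_ss_additivity(self, request, fixture):
        ds = request.getfixturevalue(fixture)
        sample, dec = decompose_symmetry(ds.configurations, ds.smap)
        tab = procrustes_anova(dec)
        total = ((sample.aligned - dec.symmetric.mean(axis=0)) ** 2).sum()
        assert tab.total_ss == pytest.approx(total, rel=1e-9)

    def test_error_row_present_only_with_replicates(self, small_dataset,
                                                    replicate_dataset):
        _, dec1 = decompose_symmetry(small_dataset.configurations,
                                     small_dataset.smap)
        tab1 = procrustes_anova(dec1)
        assert "error" not in tab1.effects
        _, dec2 = decompose_symmetry(replicate_dataset.configurations,
                                     replicate_dataset.smap)
        tab2 = procrustes_anova(dec2)
        assert "error" in tab2.effects
        assert tab2.ss["error"] > 0

    def test_duplicated_replicates_have_zero_error_ss(self):
        ds = generate(SyntheticParams(n_specimens=8, seed=9, sigma_err=0.0,
                                      n_replicates=2))
        _, dec = decompose_symmetry(ds.configurations, ds.smap)
        tab = procrustes_anova(dec)
        assert tab.ss["error"] == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("p,q,d", [(15, 4, 3), (3, 2, 3), (2, 1, 2)])
    def test_subspace_dims_sum_to_full_shape_dim(self, p, q, d):
        s_sym, s_asym = shape_space_dims(p, q, d)
        k = 2 * p + q
        full = d * k - d * (d + 1) // 2 - 1
        assert s_sym + s_asym == full
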