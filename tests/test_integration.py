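import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from symmorph.integration import (
    build_covariance_set,
    integration_metrics,
    integration_regressions,
    integration_table,
    landmark_subblock,
    matrix_correlation,
    matrix_permutation_test,
    regress,
)
from symmorph.symmetry_gpa import decompose_symmetry
from symmorph.synthetic_data import SyntheticParams, face_partitions, generate


def random_psd(rng, p):
    a = rng.standard_normal((p, p + 3))
    return a @ a.T / (p + 3)


class TestMatrixCorrelation:
    def test_self_correlation_is_exactly_one(self):
        S = random_psd(np.random.default_rng(0), 6)
        assert matrix_correlation(S, S) == 1.0

    def test_negated_matrix_gives_minus_one(self):
        S = random_psd(np.random.default_rng(1), 6)
        assert matrix_correlation(S, -S) == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        S1, S2 = random_psd(rng, 6), random_psd(rng, 6)
        assert matrix_correlation(S1, S2) == pytest.approx(
            matrix_correlation(S2, S1), abs=1e-15)

    @pytest.mark.parametrize("include_diagonal", [True, False])
    def test_matches_flatten_and_correlate_oracle(self, include_diagonal):
        S1 = np.array([[2.0, 0.5, -0.3], [0.5, 1.0, 0.2], [-0.3, 0.2, 3.0]])
        S2 = np.array([[1.0, 0.8, 0.1], [0.8, 2.0, -0.4], [0.1, -0.4, 0.5]])
        idx = np.tril_indices(3, k=0 if include_diagonal else -1)
        a, b = S1[idx], S2[idx]
        # explicit Pearson formula
        expected = (((a - a.mean()) * (b - b.mean())).sum()
                    / np.sqrt(((a - a.mean()) ** 2).sum()
                              * ((b - b.mean()) ** 2).sum()))
        assert matrix_correlation(S1, S2, include_diagonal) == pytest.approx(
            expected, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="correlation undefined"):
            matrix_correlation(np.ones((3, 3)), np.eye(3))


class TestMatrixPermutationTest:
    def test_self_similarity_reaches_floor(self):
        S = random_psd(np.random.default_rng(3), 20)   # k=10 landmarks, d=2
        res = matrix_permutation_test(S, S, d=2, n_perm=199, seed=0)
        assert res.r == 1.0
        # ties (identity-like permutations) are astronomically unlikely at k=10
        assert res.p_value == pytest.approx(1 / 200)

    def test_exchangeable_blocks_leave_r_unchanged(self):
        # all landmark blocks identical: every block permutation is a no-op
        block = np.array([[1.0, 0.3], [0.3, 2.0]])
        S2 = np.tile(block, (5, 5))
        S1 = random_psd(np.random.default_rng(4), 10)
        res = matrix_permutation_test(S1, S2, d=2, n_perm=50, seed=1)
        np.testing.assert_allclose(res.perm_values, res.r, atol=1e-12)

    def test_p_value_counting_rule(self):
        rng = np.random.default_rng(5)
        S1, S2 = random_psd(rng, 12), random_psd(rng, 12)
        res = matrix_permutation_test(S1, S2, d=3, n_perm=99, seed=2)
        expected = (1 + (res.perm_values >= res.r).sum()) / 100.0
        assert res.p_value == expected

    def test_too_few_landmarks_rejected(self):
        S = random_psd(np.random.default_rng(6), 4)
        with pytest.raises(ValueError, match="at least 3 landmarks"):
            matrix_permutation_test(S, S, d=2, n_perm=10)


class TestCovarianceSet:
    def test_zero_fa_generation_gives_zero_fa_matrix(self):
        ds = generate(SyntheticParams(n_specimens=20, seed=21, sigma_fa=0.0,
                                      da_magnitude=0.0, sigma_err=0.0))
        _, dec = decompose_symmetry(ds.configurations, ds.smap)
        covset = build_covariance_set(dec)
        assert np.abs(covset.fa).max() < 1e-9
        assert covset.error is None

    def test_identical_replicates_give_zero_error_matrix(self):
        ds = generate(SyntheticParams(n_specimens=10, seed=22, sigma_err=0.0,
                                      n_replicates=2))
        _, dec = decompose_symmetry(ds.configurations, ds.smap)
        covset = build_covariance_set(dec)
        assert covset.error is not None
        assert np.abs(covset.error).max() < 1e-18

    def test_proportional_fa_recovered_on_one_side_subblock(self):
        # ground-truth covariances are exactly proportional on the
        # paired-left sub-block under the proportional FA structure
        ds = generate(SyntheticParams(n_specimens=10, seed=23,
                                      sigma_fa=0.5, fa_structure="proportional"))
        left = [l for l, _ in ds.smap.pairs]
        ti = landmark_subblock(ds.sigma_ind_full, left, 3)
        tf = landmark_subblock(ds.sigma_fa_full, left, 3)
        assert matrix_correlation(ti, tf) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(tf, 0.25 * ti, atol=1e-12)


class TestIntegrationMetrics:
    def test_identity_covariance_has_zero_integration(self):
        m = integration_metrics(np.eye(3))
        assert m["ev_var"] == 0.0
        assert m["evstv"] == 0.0
        assert m["evstvnv"] == 0.0

    def test_rank_one_module_is_maximally_integrated(self):
        m = integration_metrics(np.diag([1.0, 0.0, 0.0]))
        assert m["tvc"] == pytest.approx(1.0)
        assert m["ev_var"] == pytest.approx(2 / 9, abs=1e-12)
        assert m["evstv"] == pytest.approx(2 / 9, abs=1e-12)
        assert m["evstvnv"] == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([0.1, 10.0]))
    def test_scaling_behaviour(self, seed, c):
        # both ratios have numerator and denominator quadratic in the scale
        S = random_psd(np.random.default_rng(seed), 5)
        base = integration_metrics(S)
        scaled = integration_metrics(c * S)
        assert scaled["evstvnv"] == pytest.approx(base["evstvnv"], rel=1e-9)
        assert scaled["evstv"] == pytest.approx(base["evstv"], rel=1e-9)
        assert scaled["ev_var"] == pytest.approx(c ** 2 * base["ev_var"],
                                                 rel=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_relative_eigenvalue_variance_bounded(self, seed):
        S = random_psd(np.random.default_rng(seed), 6)
        m = integration_metrics(S)
        assert 0.0 <= m["evstvnv"] <= 1.0 + 1e-12

    def test_degenerate_module_rejected(self):
        with pytest.raises(ValueError, match="degenerate module"):
            integration_metrics(np.zeros((3, 3)))


class TestRegress:
    def test_collinear_points(self):
        res = regress([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_ols(self):
        res = regress([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert res.slope == pytest.approx(1.5, abs=1e-12)
        assert res.r2 == pytest.approx(27 / 28, abs=1e-12)
        assert res.f == pytest.approx(27.0, abs=1e-9)
        # closed form for F(1,1): P(F > f) = 1 - 2 atan(sqrt(f)) / pi
        assert res.p_value == pytest.approx(
            1 - 2 * np.arctan(np.sqrt(27)) / np.pi, abs=1e-9)
        assert res.rmse == pytest.approx(np.sqrt(1 / 6), abs=1e-12)
        assert res.ss_model + res.ss_error == pytest.approx(res.ss_total,
                                                            rel=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="zero variance in x"):
            regress([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3 points"):
            regress([0.0, 1.0], [0.0, 1.0])


class TestIntegrationRegressions:
    @staticmethod
    def _table(tvc, evstv, fa=None):
        n = len(tvc)
        return pd.DataFrame({
            "hypothesis": ["h"] * n,
            "module": [f"m{i}" for i in range(n)],
            "component": ["symmetric"] * n,
            "tvc": tvc, "ev_var": np.zeros(n), "evstv": evstv,
            "evstvnv": np.zeros(n),
            "fa_magnitude": fa if fa is not None else np.zeros(n),
        })

    def test_proportional_integration_gives_r2_one(self):
        tvc = np.linspace(1.0, 4.0, 8)
        table = self._table(tvc, 0.5 * tvc, fa=np.linspace(0.1, 0.9, 8))
        reg_int, _, flags = integration_regressions(table, "symmetric")
        assert reg_int.r2 == pytest.approx(1.0, abs=1e-12)
        assert not flags["below_band"].any()

    def test_point_far_below_band_is_flagged(self):
        rng = np.random.default_rng(31)
        tvc = np.linspace(1.0, 4.0, 12)
        evstv = 0.5 * tvc + 0.01 * rng.standard_normal(12)
        evstv[5] -= 5.0   # constructed outlier far below the band
        table = self._table(tvc, evstv, fa=rng.random(12))
        reg_int, _, flags = integration_regressions(table, "symmetric")
        assert bool(flags.loc[flags["module"] == "m5", "below_band"].iloc[0])

    def test_shuffled_integration_loses_association(self):
        rng = np.random.default_rng(32)
        tvc = np.linspace(1.0, 4.0, 12)
        r2s = []
        for _ in range(50):
            table = self._table(tvc, rng.permutation(0.5 * tvc))
            reg_int, _, _ = integration_regressions(table, "symmetric")
            r2s.append(reg_int.r2)
        assert np.mean(r2s) < 0.3

    def test_full_table_from_synthetic_pipeline(self, small_dataset):
        _, dec = decompose_symmetry(small_dataset.configurations,
                                    small_dataset.smap)
        covset = build_covariance_set(dec)
        parts = list(face_partitions().values())
        table = integration_table(covset, parts, d=3)
        # 1 total-face row + 11 hypothesis modules, both components
        assert len(table) == 2 * 12
        assert (table["tvc"] > 0).all()
        assert table["evstvnv"].between(0, 1).all()
        reg_int, reg_fa, flags = integration_regressions(table, "asymmetric")
        assert reg_int.df_error == 10
        assert len(flags) == 12
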