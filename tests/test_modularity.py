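import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symmorph.landmark_io import ModulePartition
from symmorph.modularity import (
    component_covariance,
    cr_pairwise,
    cr_statistic,
    cr_test,
)


def cr_brute_force(S, vars_a, vars_b):
    """Independent elementwise CR oracle (explicit loops)."""
    import math
    between = 0.0
    for i in vars_a:
        for j in vars_b:
            between += S[i, j] ** 2
    within_a = 0.0
    for i in vars_a:
        for j in vars_a:
            if i != j:
                within_a += S[i, j] ** 2
    within_b = 0.0
    for i in vars_b:
        for j in vars_b:
            if i != j:
                within_b += S[i, j] ** 2
    return math.sqrt(between) / math.sqrt(
        math.sqrt(within_a) * math.sqrt(within_b))


def random_covariance(rng, p):
    a = rng.standard_normal((p, p + 2))
    return a @ a.T / (p + 2)


class TestComponentCovariance:
    def test_identical_rows_give_zero_matrix(self):
        rows = np.tile([1.0, -2.0, 3.0], (5, 1))
        np.testing.assert_array_equal(component_covariance(rows), 0.0)

    def test_fewer_than_three_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            component_covariance(np.array([[-1.0, -1.0], [1.0, 1.0]]))

    def test_hand_computed_covariance(self):
        rows = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_allclose(component_covariance(rows),
                                   [[1.0, 1.0], [1.0, 1.0]])


class TestCRPairwise:
    def test_zero_between_module_covariation(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.5
        S[2, 3] = S[3, 2] = 0.5
        assert cr_pairwise(S, [0, 1], [2, 3]) == 0.0

    def test_uniform_offdiagonal_gives_sqrt2(self):
        # all off-diagonal covariances c: ||S_AB|| = 2c, within norms c*sqrt2
        c = 0.3
        S = np.full((4, 4), c)
        np.fill_diagonal(S, 1.0)
        assert cr_pairwise(S, [0, 1], [2, 3]) == pytest.approx(np.sqrt(2.0),
                                                               abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = int(rng.integers(6, 9))
            S = random_covariance(rng, p)
            split = int(rng.integers(2, p - 1))
            idx = rng.permutation(p)
            a, b = idx[:split], idx[split:]
            assert cr_pairwise(S, a, b) == pytest.approx(
                cr_brute_force(S, a, b), abs=1e-12)

    def test_zero_within_module_covariation_rejected(self):
        S = np.eye(4)
        S[0, 2] = S[2, 0] = 0.5
        with pytest.raises(ValueError, match="CR undefined"):
            cr_pairwise(S, [0, 1], [2, 3])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.01, 100.0, allow_nan=False))
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        S = random_covariance(rng, 6)
        base = cr_pairwise(S, [0, 1, 2], [3, 4, 5])
        assert cr_pairwise(c * S, [0, 1, 2], [3, 4, 5]) == pytest.approx(
            base, rel=1e-9)

    def test_invariant_to_reordering_within_modules(self):
        rng = np.random.default_rng(3)
        S = random_covariance(rng, 6)
        a = cr_pairwise(S, [0, 1, 2], [3, 4, 5])
        b = cr_pairwise(S, [2, 0, 1], [5, 3, 4])
        assert a == pytest.approx(b, abs=1e-15)
        assert cr_pairwise(S, [3, 4, 5], [0, 1, 2]) == pytest.approx(
            a, abs=1e-15)


class TestCRStatistic:
    def test_two_modules_equal_pairwise(self):
        rng = np.random.default_rng(1)
        S = random_covariance(rng, 6)
        labels = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        overall, pairwise = cr_statistic(S, labels, d=1)
        assert overall == cr_pairwise(S, [0, 1, 2], [3, 4, 5])
        assert set(pairwise) == {("a", "b")}

    def test_three_modules_mean_of_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        S = random_covariance(rng, 6)
        labels = np.array(["a", "a", "b", "b", "c", "c"], dtype=object)
        overall, pairwise = cr_statistic(S, labels, d=1)
        expected = np.mean([
            cr_brute_force(S, [0, 1], [2, 3]),
            cr_brute_force(S, [0, 1], [4, 5]),
            cr_brute_force(S, [2, 3], [4, 5]),
        ])
        assert overall == pytest.approx(expected, abs=1e-12)
        assert len(pairwise) == 3

    def test_landmarks_carry_d_variables(self):
        # with d=2, landmark l owns variables 2l, 2l+1
        rng = np.random.default_rng(5)
        S = random_covariance(rng, 8)
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        overall, _ = cr_statistic(S, labels, d=2)
        assert overall == pytest.approx(
            cr_brute_force(S, [0, 1, 2, 3], [4, 5, 6, 7]), abs=1e-12)


class TestCRTest:
    @pytest.fixture(scope="class")
    def modular_rows(self):
        """Strongly modular 30-variable data (two 15-variable modules)."""
        rng = np.random.default_rng(7)
        n, half = 300, 15
        f1 = rng.standard_normal((n, 1))
        f2 = rng.standard_normal((n, 1))
        noise = 0.4 * rng.standard_normal((n, 2 * half))
        return np.hstack([f1 + noise[:, :half], f2 + noise[:, half:]])

    def test_p_value_counting_rule(self, modular_rows):
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        res = cr_test(modular_rows, labels, d=1, n_perm=199, seed=0)
        expected = (1 + (res.perm_values <= res.cr_observed).sum()) / 200.0
        assert res.p_value == expected

    def test_strong_modularity_reaches_floor(self, modular_rows):
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        res = cr_test(modular_rows, labels, d=1, n_perm=999, seed=1)
        assert res.cr_observed < 1.0
        assert res.p_value == pytest.approx(0.001)

    def test_antimodular_data_gives_p_one(self):
        # covariation only BETWEEN modules: observed CR above all permutations
        rng = np.random.default_rng(9)
        n = 400
        z = rng.standard_normal((n, 4))
        # module a = (z0, z1) uncorrelated within; module b mirrors module a
        # variable-by-variable with correlation 0.9: all strong covariation
        # crosses the module boundary
        rows = np.hstack([z[:, :2], 0.9 * z[:, :2] +
                          np.sqrt(1 - 0.81) * z[:, 2:]])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        res = cr_test(rows, labels, d=1, n_perm=199, seed=2)
        assert res.cr_observed > 1.0
        assert res.p_value == 1.0

    def test_deterministic_under_seed(self, modular_rows):
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        r1 = cr_test(modular_rows, labels, d=1, n_perm=99, seed=5)
        r2 = cr_test(modular_rows, labels, d=1, n_perm=99, seed=5)
        np.testing.assert_array_equal(r1.perm_values, r2.perm_values)
        assert r1.p_value == r2.p_value

    def test_accepts_module_partition_objects(self, modular_rows):
        part = ModulePartition(
            "halves", {i: ("a" if i < 15 else "b") for i in range(30)})
        res = cr_test(modular_rows, part, d=1, n_perm=99, seed=3)
        assert res.cr_observed < 1.0

    def test_invalid_n_perm_rejected(self, modular_rows):
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        with pytest.raises(ValueError, match="n_perm"):
            cr_test(modular_rows, labels, d=1, n_perm=0)

    def test_null_mean_cr_near_one(self):
        rng = np.random.default_rng(11)
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        crs = [cr_statistic(component_covariance(
            rng.standard_normal((200, 30))), labels, d=1)[0]
            for _ in range(60)]
        assert 0.9 < np.mean(crs) < 1.1
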