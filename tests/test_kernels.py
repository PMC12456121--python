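"""Marker QC, VanRaden K, EC kernel and kinship imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from menvgp import (
    BLUETable,
    EnvCovariateTable,
    GRM,
    GenotypeMatrix,
    center_standardize,
    ec_kernel,
    grm_vanraden,
    impute_phenotypes_by_kin,
    qc_markers,
)

# the three environmental covariates of a four-environment maize trial
# (seasonal max temp in deg C, min temp in deg C, total precipitation in mm)
EC_TABLE = pd.DataFrame(
    {
        "max_temp": [35.55, 33.33, 33.89, 33.33],
        "min_temp": [-1.11, -3.89, -3.89, -1.11],
        "precip": [906.78, 547.12, 760.98, 667.77],
    },
    index=["C20", "K20", "C21", "K21"],
)


class TestQC:
    def test_toy_matrix_exactly_two_survivors(self, qc_toy):
        filtered, report = qc_markers(qc_toy)
        assert report.n_removed_maf == 2
        assert report.n_removed_missing == 1
        assert report.n_removed_corr == 1
        assert filtered.n_markers == 2
        assert set(report.retained_marker_ids) == {"dupA", "good"}

    def test_clean_matrix_fully_retained(self):
        rng = np.random.default_rng(0)
        dos = 2.0 * (rng.random((80, 5)) < 0.5)
        G = GenotypeMatrix(np.arange(80), np.arange(5), dos)
        filtered, report = qc_markers(G)
        assert filtered.n_markers == 5
        assert (report.n_removed_maf, report.n_removed_missing,
                report.n_removed_corr) == (0, 0, 0)

    def test_maf_threshold_is_inclusive(self):
        # MAF exactly 0.05 must be removed (threshold "<= 5%")
        n = 40
        boundary = np.zeros(n)
        boundary[:2] = 2.0  # p = 4/80 = 0.05
        good = np.tile([0.0, 2.0], n // 2)
        G = GenotypeMatrix(np.arange(n), ["b", "g"], np.column_stack([boundary, good]))
        _, report = qc_markers(G)
        assert report.n_removed_maf == 1
        assert list(report.retained_marker_ids) == ["g"]

    def test_counts_partition_input(self, qc_toy):
        _, r = qc_markers(qc_toy)
        assert (r.n_removed_maf + r.n_removed_missing + r.n_removed_corr
                + r.n_retained) == qc_toy.n_markers

    @settings(deadline=None, max_examples=20)
    @given(perm_seed=st.integers(0, 10_000))
    def test_line_permutation_never_changes_retained_set(self, perm_seed):
        G = __import__("tests.conftest", fromlist=["toy_qc_matrix"]).toy_qc_matrix()
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(G.n_lines)
        Gp = GenotypeMatrix(G.line_ids[perm], G.marker_ids, G.dosages[perm])
        _, r0 = qc_markers(G)
        _, rp = qc_markers(Gp)
        assert list(r0.retained_marker_ids) == list(rp.retained_marker_ids)

    def test_everything_filtered_is_an_error(self):
        dos = np.zeros((10, 2))
        dos[0, :] = 2.0  # MAF 0.1 > 0.05... make them rare instead
        dos = np.zeros((30, 2))
        G = GenotypeMatrix(np.arange(30), ["a", "b"], dos)
        with pytest.raises(ValueError, match="no markers"):
            qc_markers(G)


class TestCenterStandardize:
    def test_two_point_column(self):
        W = center_standardize(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(W[:, 0], [-1.0, 1.0])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        X = (X - X.mean(0)) / X.std(0)
        # already standardized dosage-like input passes through unchanged
        from menvgp.kernels import _MISSING_TOL  # noqa: F401

        W = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(W, X, atol=1e-12)

    def test_columns_centered(self):
        rng = np.random.default_rng(2)
        dos = 2.0 * (rng.random((60, 10)) < 0.4)
        W = center_standardize(dos)
        assert np.abs(W.mean(axis=0)).max() <= 1e-12
        np.testing.assert_allclose(W.std(axis=0), 1.0)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            center_standardize(np.zeros((5, 1)))

    def test_missing_values_mean_imputed(self):
        dos = np.array([[0.0], [2.0], [np.nan], [2.0]])
        W = center_standardize(dos)
        assert not np.isnan(W).any()
        assert abs(W.mean()) < 1e-12


class TestGRM:
    def test_two_by_two_hand_computation(self):
        K = grm_vanraden(np.array([[-1.0], [1.0]]), p=1).K
        np.testing.assert_allclose(K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_grand_sum_vanishes_for_centered_input(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((20, 15))
        W -= W.mean(axis=0)
        K = grm_vanraden(W).K
        assert abs(K.sum()) <= 1e-8

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_inner_products(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((5, 8))
        K = grm_vanraden(W).K
        brute = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                brute[i, j] = sum(W[i, k] * W[j, k] for k in range(8)) / 8
        np.testing.assert_allclose(K, brute, atol=1e-12)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            grm_vanraden(np.empty((3, 0)), p=0)


class TestECKernel:
    def test_matches_hand_calculation_on_weather_table(self):
        ec = EnvCovariateTable(
            env_ids=EC_TABLE.index.to_numpy(),
            covariate_names=EC_TABLE.columns.to_numpy(),
            values=EC_TABLE.to_numpy(),
        )
        Omega = ec_kernel(ec).Omega
        # independent oracle: standardize each column, average outer products
        X = EC_TABLE.to_numpy()
        C = np.empty_like(X)
        for q in range(X.shape[1]):
            col = X[:, q]
            C[:, q] = (col - col.mean()) / col.std()
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                expected[i, j] = sum(C[i, q] * C[j, q] for q in range(3)) / 3
        np.testing.assert_allclose(Omega, expected, atol=1e-12)
        assert abs(Omega.sum()) <= 1e-8
        assert np.linalg.eigvalsh(Omega).min() >= -1e-8

    def test_identical_environments_share_diagonal(self):
        vals = np.array([[1.0, 5.0], [1.0, 5.0], [3.0, 2.0], [0.0, 1.0]])
        ec = EnvCovariateTable(np.array(list("abcd")), np.array(["x", "y"]), vals)
        Om = ec_kernel(ec).Omega
        assert Om[0, 1] == pytest.approx(Om[0, 0])
        assert Om[0, 1] == pytest.approx(Om[1, 1])

    def test_single_environment_rejected(self):
        ec = EnvCovariateTable(np.array(["only"]), np.array(["x"]), np.array([[1.0]]))
        with pytest.raises(ValueError):
            ec_kernel(ec)


class TestImputation:
    @staticmethod
    def _grm(ids, K):
        return GRM(line_ids=np.asarray(ids), K=np.asarray(K, dtype=float))

    def test_mean_of_two_equally_related_neighbours(self):
        K = self._grm(["l1", "l2", "l3"],
                      [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        values = pd.DataFrame(
            {"A": [np.nan, 10.0, 20.0], "B": [1.0, 2.0, 3.0]},
            index=["l1", "l2", "l3"],
        )
        out = impute_phenotypes_by_kin(BLUETable(values=values), K, k=2)
        assert out.values.loc["l1", "A"] == pytest.approx(15.0)
        assert out.imputed.loc["l1", "A"]

    def test_lines_missing_in_two_environments_are_dropped(self):
        K = self._grm(["l1", "l2", "l3"], np.eye(3) * 0.5 + 0.5)
        values = pd.DataFrame(
            {"A": [np.nan, 1.0, 2.0], "B": [np.nan, 2.0, 3.0],
             "C": [0.0, 1.0, 2.0], "D": [0.0, 1.0, 2.0]},
            index=["l1", "l2", "l3"],
        )
        out = impute_phenotypes_by_kin(BLUETable(values=values), K, k=1)
        assert "l1" not in out.values.index
        assert list(out.values.index) == ["l2", "l3"]

    def test_ties_broken_by_line_order(self):
        ids = ["l1", "l2", "l3", "l4"]
        K = self._grm(ids, np.eye(4) * 0.4 + 0.6)  # all off-diagonals equal
        values = pd.DataFrame(
            {"A": [np.nan, 4.0, 8.0, 100.0], "B": [1.0, 1.0, 1.0, 1.0]},
            index=ids,
        )
        out1 = impute_phenotypes_by_kin(BLUETable(values=values.copy()), K, k=2)
        out2 = impute_phenotypes_by_kin(BLUETable(values=values.copy()), K, k=2)
        # deterministic and using the first two observed lines in table order
        assert out1.values.loc["l1", "A"] == pytest.approx(6.0)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_observed_cells_never_modified(self, small_grm):
        ids = small_grm.line_ids[:5]
        values = pd.DataFrame(
            np.arange(10, dtype=float).reshape(5, 2), index=ids, columns=["A", "B"]
        )
        values.iloc[0, 0] = np.nan
        before = values.copy()
        out = impute_phenotypes_by_kin(
            BLUETable(values=values), GRM(ids, small_grm.K[:5, :5]), k=3
        )
        observed_mask = before.notna()
        pd.testing.assert_frame_equal(
            out.values[observed_mask], before[observed_mask]
        )

    def test_too_few_neighbours_warns(self):
        K = self._grm(["l1", "l2"], [[1.0, 0.3], [0.3, 1.0]])
        values = pd.DataFrame({"A": [np.nan, 5.0], "B": [1.0, 2.0]},
                              index=["l1", "l2"])
        with pytest.warns(UserWarning, match="neighbours"):
            out = impute_phenotypes_by_kin(BLUETable(values=values), K, k=20)
        assert out.values.loc["l1", "A"] == pytest.approx(5.0)
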