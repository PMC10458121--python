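import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression

from adulterspec.chemometrics_core import (compute_metrics,
                                           correlation_strength_label,
                                           kennard_stone_split, kfold_indices,
                                           pearson_with_significance, pls_fit,
                                           pls_predict, rmsecv, rmsecv_pls)


class TestPls:
    def test_exact_linear_relationship_fits_to_machine_precision(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + 2.0
        m = pls_fit(X, y, 8)
        assert np.sqrt(np.mean((pls_predict(m, X) - y) ** 2)) < 1e-8

    def test_full_rank_components_equal_ordinary_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=40)
        m = pls_fit(X, y, 6)
        A = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(pls_predict(m, X), A @ beta, atol=1e-8)

    def test_single_feature_slope_is_cov_over_var(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = 3 * x + rng.normal(size=25)
        m = pls_fit(x[:, None], y, 1)
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert m.coef_[0] == pytest.approx(expected, rel=1e-10)

    def test_matches_sklearn_pls_predictions(self):
        """Independent cross-check: NIPALS (sklearn) and SIMPLS agree for a
        univariate response."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 25))
        y = X[:, :5] @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        for ncomp in (1, 3, 5, 10):
            ours = pls_predict(pls_fit(X, y, ncomp), X)
            sk = PLSRegression(n_components=ncomp, scale=False).fit(X, y[:, None])
            np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-8)

    def test_rank_deficiency_warns_and_reduces(self):
        X = np.zeros((10, 4))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * np.arange(10)  # collinear
        y = np.arange(10, dtype=float)
        with pytest.warns(UserWarning, match="rank deficiency"):
            m = pls_fit(X, y, 3)
        assert m.n_components < 3

    def test_invalid_component_count_rejected(self):
        with pytest.raises(ValueError):
            pls_fit(np.zeros((5, 3)), np.zeros(5), 5)


class TestRmsecv:
    def test_perfect_linear_data_gives_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + 1
        assert rmsecv(X, y, LinearRegression, k=10, seed=0) < 1e-8
        assert rmsecv_pls(X, y, max_components=3, k=10, seed=0) < 1e-8

    def test_matches_explicit_leave_one_out_enumeration(self):
        """n=5, k=5: every fold is a singleton, so RMSECV must equal the
        hand-enumerated leave-one-out RMSE of the same model family."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.1, 1.2, 1.9, 3.3, 3.8])
        resid = []
        for i in range(5):
            keep = np.delete(np.arange(5), i)
            slope, icept = np.polyfit(x[keep], y[keep], 1)
            resid.append(y[i] - (slope * x[i] + icept))
        expected = np.sqrt(np.mean(np.square(resid)))
        got = rmsecv(x[:, None], y, LinearRegression, k=5, seed=0)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        a = rmsecv_pls(X, y, 5, k=10, seed=3)
        b = rmsecv_pls(X, y, 5, k=10, seed=3)
        assert a == b
        assert a != rmsecv_pls(X, y, 5, k=10, seed=4)

    def test_more_folds_than_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 6, 0)


class TestKennardStone:
    def test_64_samples_split_43_21(self, soybean_set):
        split = kennard_stone_split(soybean_set.X)
        assert len(split.calibration_indices) == 43
        assert len(split.prediction_indices) == 21
        union = np.union1d(split.calibration_indices, split.prediction_indices)
        np.testing.assert_array_equal(union, np.arange(64))

    def test_collinear_points_seed_with_extreme_pair(self):
        X = np.array([[0.0], [1.0], [10.0]])
        split = kennard_stone_split(X, calibration_ratio=2 / 3)
        assert set(split.calibration_indices) == {0, 2}

    def test_matches_exhaustive_max_min_oracle(self):
        """Greedy max-min selection re-derived with explicit python loops."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        n_cal = 8

        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        best = (-1.0, None)
        for i in range(12):
            for j in range(i + 1, 12):
                if d[i, j] > best[0]:
                    best = (d[i, j], (i, j))
        sel = list(best[1])
        while len(sel) < n_cal:
            cand, cand_d = None, -1.0
            for i in range(12):
                if i in sel:
                    continue
                mind = min(d[i, s] for s in sel)
                if mind > cand_d:
                    cand, cand_d = i, mind
            sel.append(cand)
        split = kennard_stone_split(X, calibration_ratio=n_cal / 12)
        assert set(split.calibration_indices) == set(sel)

    def test_permutation_covariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 4))
        perm = rng.permutation(15)
        orig = set(kennard_stone_split(X).calibration_indices)
        permuted = set(kennard_stone_split(X[perm]).calibration_indices)
        assert {perm[i] for i in permuted} == orig


class TestMetrics:
    def test_identity_prediction(self):
        m = compute_metrics([0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)

    def test_hand_arithmetic_oracle(self):
        # y=(0,1,2), yhat=(0,1,1): SS_res=1, SS_tot=2, n=3
        m = compute_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert m.r2 == pytest.approx(1 - 1 / 2)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.mae == pytest.approx(1 / 3)

    def test_mean_prediction_scores_zero_r2(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_rmse_at_least_mae(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=10)
        y_hat = rng.normal(size=10)
        m = compute_metrics(y, y_hat)
        assert m.rmse >= m.mae >= 0.0
        assert m.r2 <= 1.0


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_with_significance(x, 2 * x + 1).pearson_r == \
            pytest.approx(1.0)
        assert pearson_with_significance(x, -x).pearson_r == pytest.approx(-1.0)

    def test_hand_arithmetic_oracle(self):
        # x=(1,2,3,4), y=(2,1,4,3): Σ(x−x̄)(y−ȳ)=3, Σ(x−x̄)²=Σ(y−ȳ)²=5 → R=0.6
        rep = pearson_with_significance([1, 2, 3, 4], [2, 1, 4, 3])
        assert rep.pearson_r == pytest.approx(3 / 5)

    def test_p_value_matches_t_distribution(self):
        from scipy import stats
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rep = pearson_with_significance(x, y)
        t = rep.pearson_r * np.sqrt(18 / (1 - rep.pearson_r ** 2))
        assert rep.p_value == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_affine_invariance_with_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r = pearson_with_significance(x, y).pearson_r
        assert pearson_with_significance(3.2 * x + 1, y).pearson_r == \
            pytest.approx(r, abs=1e-10)
        assert pearson_with_significance(x, -0.5 * y + 4).pearson_r == \
            pytest.approx(-r, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_significance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("r,label", [
        (0.989, "very strong"), (-0.82, "very strong"),
        (-0.759, "strong"), (0.754, "strong"),
        (-0.671, "moderate"), (0.535, "moderate"),
        (0.3, "weak"),
    ])
    def test_strength_labels_match_reported_usage(self, r, label):
        assert correlation_strength_label(r) == label
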