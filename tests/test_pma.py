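import numpy as np
import pytest

from gaitstab.errors import GaitStabError, RankExhaustedError
from gaitstab.pelvis_features import apply_stats, fit_stats
from gaitstab.pma import (
    CVResult,
    cross_validate,
    fit,
    fitted_values,
    load_model,
    predict,
    regression_equation,
    save_model,
)
from gaitstab.pma import test_scores as pma_test_scores
from gaitstab.synthetic_data import LatentSpec, make_latent_dataset
from oracles import pma_brute, pma_brute_predict


def _zscore(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def _rel(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-30)


class TestFitOracle:
    def test_small_integer_instance(self):
        X = np.array([[1.0, 2.0, 0.0],
                      [0.0, 1.0, 3.0],
                      [2.0, 0.0, 1.0],
                      [1.0, 1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        S, P, q, ym = pma_brute(X, y, 2)
        m = fit(X, y, 2)
        assert _rel(m.train_scores, S) < 1e-10
        assert _rel(m.loadings, P) < 1e-10
        assert _rel(m.coeffs, q) < 1e-10
        assert m.y_mean == ym

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        S, P, q, ym = pma_brute(X, y, 5)
        m = fit(X, y, 5)
        assert _rel(m.train_scores, S) < 1e-10
        assert _rel(m.loadings, P) < 1e-10
        assert _rel(m.coeffs, q) < 1e-10
        # paper-projection predictions agree with the loop-level oracle
        Xn = _zscore(rng.normal(size=(6, 8)))
        np.testing.assert_allclose(predict(m, Xn), pma_brute_predict(P, q, ym, Xn),
                                   atol=1e-10)

    def test_single_feature_exact(self):
        rng = np.random.default_rng(3)
        X = _zscore(rng.normal(size=(15, 1)))
        y = 2.0 * X[:, 0]
        m = fit(X, y, 1)
        resid = y - fitted_values(m)
        assert np.abs(resid).max() < 1e-12
        np.testing.assert_allclose(m.coeffs[0] * m.train_scores[:, 0], y - y.mean(),
                                   atol=1e-12)

    def test_score_orthogonality(self, rng):
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        S = fit(X, y, 5).train_scores
        norms = np.linalg.norm(S, axis=0)
        for i in range(5):
            for j in range(i):
                assert abs(S[:, i] @ S[:, j]) < 1e-8 * norms[i] * norms[j]

    def test_undeflated_vs_deflated_target_equivalent(self, rng):
        # with orthogonal scores, q from the original centred target equals
        # q from the deflated target
        X = _zscore(rng.normal(size=(25, 10)))
        y = rng.normal(size=25)
        m = fit(X, y, 6)
        yc = y - y.mean()
        yn = yc.copy()
        for n in range(6):
            s = m.train_scores[:, n]
            q_defl = (yn @ s) / (s @ s)
            assert abs(q_defl - m.coeffs[n]) < 1e-10
            yn = yn - m.coeffs[n] * s


class TestAgainstNipals:
    def test_training_predictions_match_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        m = fit(X, y, 4)
        pls = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(fitted_values(m), pls.predict(X).ravel(), atol=1e-8)

    def test_rotation_projection_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = _zscore(rng.normal(size=(30, 8)))
        y = rng.normal(size=30)
        Xn = rng.normal(size=(9, 8))
        m = fit(X, y, 4)
        pls = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(predict(m, Xn, projection="pls_rotation"),
                                   pls.predict(Xn).ravel(), atol=1e-8)


class TestDeflationStructure:
    def test_exact_rank_reconstruction(self, rng):
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        m = fit(X, y, 8)
        recon = m.train_scores @ m.loadings
        assert np.linalg.norm(X - recon) < 1e-8

    def test_residual_norm_non_increasing(self, rng):
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        m = fit(X, y, 8)
        Xn = X.copy()
        norms = [np.linalg.norm(Xn)]
        for n in range(8):
            Xn = Xn - np.outer(m.train_scores[:, n], m.loadings[n])
            norms.append(np.linalg.norm(Xn))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_rank_exhausted_reports_achievable(self, rng):
        base = rng.normal(size=(12, 2))
        X = base @ rng.normal(size=(2, 6))    # rank 2
        y = X @ rng.normal(size=6)
        with pytest.raises(RankExhaustedError) as exc:
            fit(X, y, 5)
        assert exc.value.achieved == 2


class TestPredict:
    def test_zero_row_predicts_mean(self, rng):
        X = _zscore(rng.normal(size=(15, 6)))
        y = rng.normal(size=15) + 3.0
        m = fit(X, y, 3)
        np.testing.assert_allclose(predict(m, np.zeros((1, 6))), [m.y_mean], atol=1e-12)

    def test_single_component_closed_form(self, rng):
        X = _zscore(rng.normal(size=(15, 6)))
        y = rng.normal(size=15)
        m = fit(X, y, 1)
        p1 = m.loadings[0]
        t = 0.7
        got = predict(m, t * p1[None, :])
        expected = m.y_mean + m.coeffs[0] * t * (p1 @ p1)
        np.testing.assert_allclose(got, [expected], atol=1e-12)

    def test_paper_and_rotation_differ_in_general(self, rng):
        # the single-projection rule is not the exact PLS test map; on a
        # random instance the two predictors disagree measurably
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        Xn = rng.normal(size=(10, 8))
        m = fit(X, y, 3)
        d = np.abs(predict(m, Xn) - predict(m, Xn, projection="pls_rotation")).max()
        assert d > 1e-6

    def test_paper_on_training_vs_training_reconstruction(self, rng):
        # projecting the undeflated training rows does not reproduce the
        # stored training scores (the single-projection rule skips the
        # deflation), so paper-rule predictions on the training set differ
        # from the training reconstruction
        X = _zscore(rng.normal(size=(20, 8)))
        y = rng.normal(size=20)
        m = fit(X, y, 3)
        s_proj = pma_test_scores(m, X, projection="paper")
        assert np.abs(s_proj - m.train_scores).max() > 1e-6
        assert np.abs(predict(m, X) - fitted_values(m)).max() > 1e-6
        # whereas the weight-rotation projection recovers them exactly
        s_rot = pma_test_scores(m, X, projection="pls_rotation")
        np.testing.assert_allclose(s_rot, m.train_scores, atol=1e-8)

    def test_column_mismatch_errors(self, rng):
        X = _zscore(rng.normal(size=(10, 6)))
        m = fit(X, rng.normal(size=10), 2)
        with pytest.raises(GaitStabError, match="mismatch"):
            predict(m, np.zeros((2, 5)))

    def test_zero_target_guarded(self):
        X = _zscore(np.random.default_rng(0).normal(size=(10, 4)))
        m = fit(X, np.full(10, 1.5), 3)
        assert np.all(m.coeffs == 0.0)
        np.testing.assert_allclose(predict(m, X), 1.5)


class TestRegressionEquation:
    def test_decreasing_covariance_orders_coeffs(self):
        spec = LatentSpec(seed=5, factor_score_sd=(1.0, 1.0, 1.0),
                          coeffs=(0.11, 0.050, 0.030), x_noise_sd=0.02,
                          y_noise_sd=0.01)
        X, y, _ = make_latent_dataset(spec)
        stats = fit_stats(X, labels=[str(i) for i in range(X.shape[1])])
        m = fit(apply_stats(X, stats), y, 3)
        q = np.abs(regression_equation(m))
        assert q[0] >= q[1] >= q[2]

    def test_single_component_definition(self, rng):
        X = _zscore(rng.normal(size=(15, 6)))
        y = rng.normal(size=15)
        m = fit(X, y, 1)
        s1 = m.train_scores[:, 0]
        yc = y - y.mean()
        np.testing.assert_allclose(regression_equation(m), [(yc @ s1) / (s1 @ s1)],
                                   atol=1e-12)


class TestCrossValidate:
    def test_noiseless_identifiable(self):
        X, y, _ = make_latent_dataset(LatentSpec(seed=2, x_noise_sd=0.0, y_noise_sd=0.0,
                                                 n_samples=200))
        cv = cross_validate(X, y, a_max=4, n_repeats=2, seed=0, projection="pls_rotation")
        assert cv.rmse[2] < 1e-8   # a = 3 recovers exactly
        assert cv.r_mean[2] > 1 - 1e-9
        # the literal single-projection rule carries a scale bias (loadings
        # are not unit vectors), so it is only approximately exact here
        cvp = cross_validate(X, y, a_max=4, n_repeats=2, seed=0)
        assert cvp.r_mean[2] > 0.95
        assert cvp.rmse[2] < 0.5 * np.std(y)

    def test_pure_noise_calibration(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 20))
        y = rng.normal(size=300)
        cv = cross_validate(X, y, a_max=3, n_repeats=5, seed=1)
        # r should hover near zero and RMSE near SD(y)
        assert np.abs(cv.r_mean).max() < 0.25
        assert np.abs(cv.rmse - np.std(y)).max() < 0.15 * np.std(y)

    def test_perfect_predictor(self):
        # a feature that IS the target: held-out RMSE collapses to zero
        rng = np.random.default_rng(9)
        y = rng.normal(size=60)
        X = y[:, None]
        cv = cross_validate(X, y, a_max=1, n_repeats=2, seed=0)
        assert cv.rmse[0] < 1e-6
        assert cv.chosen_a == 1

    def test_selects_three_factors(self):
        X, y, _ = make_latent_dataset(LatentSpec(seed=11))
        cv = cross_validate(X, y, a_max=5, seed=11)
        assert cv.chosen_a == 3
        assert cv.r_mean[cv.chosen_a - 1] > 0.6

    def test_folds_partition_samples(self):
        X, y, _ = make_latent_dataset(LatentSpec(seed=0, n_samples=50))
        cv = cross_validate(X, y, a_max=2, n_repeats=3, seed=4)
        for fold_of in cv.folds:
            assert fold_of.shape == (50,)
            assert set(fold_of) == set(range(5))

    def test_groups_kept_together(self):
        X, y, _ = make_latent_dataset(LatentSpec(seed=0, n_samples=60))
        groups = np.repeat(np.arange(10), 6)
        cv = cross_validate(X, y, a_max=2, n_repeats=2, seed=4, groups=groups)
        for fold_of in cv.folds:
            for g in range(10):
                assert len(set(fold_of[groups == g])) == 1

    def test_deterministic_given_seed(self):
        X, y, _ = make_latent_dataset(LatentSpec(seed=0, n_samples=80))
        a = cross_validate(X, y, a_max=3, n_repeats=2, seed=13)
        b = cross_validate(X, y, a_max=3, n_repeats=2, seed=13)
        np.testing.assert_array_equal(a.rmse, b.rmse)
        np.testing.assert_array_equal(a.r_per_repeat, b.r_per_repeat)

    def test_too_few_samples(self):
        with pytest.raises(GaitStabError):
            cross_validate(np.zeros((3, 4)), np.zeros(3), a_max=1)

    def test_report_shape(self):
        X, y, _ = make_latent_dataset(LatentSpec(seed=0, n_samples=60))
        cv = cross_validate(X, y, a_max=4, n_repeats=2, seed=0)
        rep = cv.report()
        assert list(rep["a"]) == [1, 2, 3, 4]
        assert {"r_mean", "r_sd", "rmse", "rmse_cm"} <= set(rep.columns)


def test_model_round_trip(tmp_path, rng):
    X = _zscore(rng.normal(size=(15, 6)))
    y = rng.normal(size=15)
    stats = fit_stats(X, labels=[str(i) for i in range(6)])
    m = fit(X, y, 2, feature_stats=stats)
    path = tmp_path / "model.npz"
    save_model(m, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.loadings, m.loadings)
    np.testing.assert_array_equal(back.coeffs, m.coeffs)
    assert back.y_mean == m.y_mean
    np.testing.assert_array_equal(back.feature_stats.mean, stats.mean)
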