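import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from citrusauth.chemometrics import (
    Autoscaler,
    ChemometricsError,
    PCAModel,
    PLS1Regression,
    autoscale,
    cross_validate,
    martens_uncertainty,
    reduce_variables,
)


def _random_xy(seed, n=24, p=7, informative=3, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:informative] = rng.uniform(1.0, 3.0, informative) * rng.choice(
        [-1, 1], informative
    )
    y = X @ beta + rng.normal(0, noise, n)
    return X, y, beta


class TestAutoscaler:
    def test_zero_mean_unit_variance(self):
        scaled, scaler = autoscale(np.array([[1.0, 5.0], [2.0, 7.0], [3.0, 9.0]]))
        assert np.all(np.abs(scaled.mean(axis=0)) < 1e-10)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1.0)

    def test_constant_column_dropped(self):
        X = np.array([[1.0, 4.0], [2.0, 4.0], [3.0, 4.0]])
        scaled, scaler = autoscale(X)
        assert scaled.shape == (3, 1)
        assert scaler.dropped_columns_.tolist() == [1]

    def test_all_constant_errors(self):
        with pytest.raises(ChemometricsError):
            autoscale(np.ones((4, 2)))

    def test_inverse_transform_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4)) * [1, 10, 100, 0.1] + [5, -3, 0, 2]
        scaled, scaler = autoscale(X)
        assert np.allclose(scaler.inverse_transform(scaled), X, atol=1e-12)


class TestPCA:
    def test_collinear_data_one_component(self):
        x = np.linspace(0, 1, 10)
        X = np.c_[x, 2 * x]
        model = PCAModel(n_components=1).fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        scores, loadings, evr = (
            PCAModel(n_components=3).fit(X).scores_,
            PCAModel(n_components=3).fit(X).components_,
            PCAModel(n_components=3).fit(X).explained_variance_ratio_,
        )
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        assert np.allclose(np.abs(loadings), np.abs(vt), atol=1e-10)
        assert np.allclose(np.abs(scores), np.abs(u * s), atol=1e-10)
        assert np.allclose(evr, s**2 / (s**2).sum())

    def test_rank_deficiency_reduces_components(self):
        x = np.linspace(0, 1, 6)
        X = np.c_[x, 2 * x, -x]
        model = PCAModel(n_components=3).fit(X)
        assert model.n_components_ == 1
        assert model.rank_deficient_

    def test_excess_components_rejected(self):
        with pytest.raises(ChemometricsError):
            PCAModel(n_components=5).fit(np.random.default_rng(2).normal(size=(4, 3)))


class TestPLS1:
    def test_single_column_equals_univariate_regression(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 1))
        y = 2.5 * x.ravel() + rng.normal(0, 0.1, 15)
        model = PLS1Regression(n_components=1).fit(x, y)
        slope, intercept = np.polyfit(x.ravel(), y, 1)
        assert model.predict(x) == pytest.approx(slope * x.ravel() + intercept,
                                                 abs=1e-10)

    def test_full_rank_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(0, 0.2, 20)
        model = PLS1Regression(n_components=4).fit(X, y)
        X1 = np.c_[np.ones(20), X]
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
        assert np.allclose(model.predict(X), X1 @ beta, atol=1e-8)

    def test_orthogonal_response_gives_null_coefficients(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 1.0], [-1.0, 1.0],
                      [1.0, -1.0], [-1.0, -1.0]])
        y = X[:, 0].copy()
        # second column has zero covariance with y
        model = PLS1Regression(n_components=2, scale=False).fit(X, y)
        assert abs(model.coef_[1]) < 1e-10

    def test_scores_are_orthogonal(self):
        X, y, _ = _random_xy(5)
        model = PLS1Regression(n_components=5).fit(X, y)
        gram = model.x_scores_.T @ model.x_scores_
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() < 1e-8

    def test_predictions_invariant_under_column_affine_transform(self):
        X, y, _ = _random_xy(6)
        base = PLS1Regression(n_components=3).fit(X, y).predict(X)
        X2 = X * np.array([10.0, 0.5, 3.0, 100.0, 1.0, 0.01, 2.0]) + np.arange(7)
        transformed = PLS1Regression(n_components=3).fit(X2, y).predict(X2)
        assert np.allclose(base, transformed, atol=1e-8)

    def test_zero_variance_response_errors(self):
        X = np.random.default_rng(7).normal(size=(10, 3))
        with pytest.raises(ChemometricsError):
            PLS1Regression(n_components=1).fit(X, np.ones(10))


class TestCrossValidation:
    def test_noiseless_linear_response_reaches_zero_rmsecv(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, 2.0, -1.0]
        cv = cross_validate(X, y, max_components=3)
        assert cv.rmsecv[2] < 1e-10

    def test_pure_noise_suggests_one_component(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 5))
        y = rng.normal(size=25)
        cv = cross_validate(X, y, max_components=4)
        assert cv.suggested_components == 1

    def test_matches_brute_force_leave_one_out(self):
        X, y, _ = _random_xy(10, n=20, p=5)
        cv = cross_validate(X, y, max_components=3)
        for a in (1, 2, 3):
            errors = []
            for i in range(20):
                train = np.delete(np.arange(20), i)
                model = PLS1Regression(n_components=a).fit(X[train], y[train])
                errors.append(y[i] - model.predict(X[i][None, :])[0])
            assert cv.rmsecv[a - 1] == pytest.approx(
                np.sqrt(np.mean(np.square(errors))), abs=1e-10
            )

    def test_segmented_mode_is_seeded(self):
        X, y, _ = _random_xy(11, n=30)
        a = cross_validate(X, y, 2, segmentation=5, seed=3)
        b = cross_validate(X, y, 2, segmentation=5, seed=3)
        assert np.allclose(a.rmsecv, b.rmsecv)
        assert a.segments == b.segments


class TestMartensUncertainty:
    def test_identical_submodels_have_zero_variance(self):
        b = np.array([1.0, 0.0, -2.0])
        submodels = np.tile(b, (10, 1))
        result = martens_uncertainty(b, submodels)
        assert np.all(result.jackknife_variance == 0.0)
        assert result.significant.tolist() == [True, False, True]

    def test_too_few_submodels_error(self):
        with pytest.raises(ChemometricsError):
            martens_uncertainty(np.array([1.0]), np.array([[1.0], [1.0]]))

    def test_variance_grows_with_injected_perturbation(self):
        rng = np.random.default_rng(12)
        b = np.array([1.0, 1.0])
        previous = -1.0
        for magnitude in (0.01, 0.1, 1.0):
            submodels = b + rng.normal(0, magnitude, size=(20, 2))
            s2 = martens_uncertainty(b, submodels).jackknife_variance.sum()
            assert s2 > previous
            previous = s2

    def test_noise_variable_in_marker_fixture_not_significant(self):
        # 7-variable two-species fixture: three discriminating methoxyflavone
        # analogues plus pure-noise columns
        rng = np.random.default_rng(13)
        n = 40
        species = np.repeat([0.0, 100.0], n // 2)
        X = rng.normal(0, 1, size=(n, 7))
        X[:, 0] += species / 25.0  # marker up in the 100 group
        X[:, 1] -= species / 25.0  # marker down
        X[:, 2] += species / 30.0
        cv = cross_validate(X, species, max_components=3)
        a = cv.suggested_components
        full = PLS1Regression(n_components=a).fit(X, species)
        result = martens_uncertainty(full.coef_, cv.submodel_coefs[:, a - 1, :])
        assert result.significant[:3].all()
        assert not result.significant[3:].any()


class TestReduceVariables:
    def test_informative_variables_survive(self):
        X, y, beta = _random_xy(14, n=30, p=7, informative=3)
        names = [f"v{i}" for i in range(7)]
        result = reduce_variables(X, y, names, max_components=4)
        assert set(result.survivors) >= {"v0", "v1", "v2"}
        for name in result.survivors:
            idx = names.index(name)
            if idx < 3:
                assert np.sign(result.coefficients[name]) == np.sign(beta[idx])

    def test_all_noise_errors(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        with pytest.raises(ChemometricsError, match="significant"):
            reduce_variables(X, y, ["a", "b", "c", "d"], max_components=2)

    def test_single_perfect_predictor_survives_with_sign(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(20, 3))
        y = -3.0 * X[:, 1]
        result = reduce_variables(X, y, ["a", "b", "c"], max_components=2)
        assert result.survivors[0] == "b"
        assert result.coefficients["b"] < 0


@given(seed=st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_pls_matches_reference_implementation(seed):
    """Property: our NIPALS PLS1 equals the reference PLS on random data."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(seed)
    n, p = rng.integers(8, 16), rng.integers(2, 6)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    a = int(rng.integers(1, min(n - 1, p) + 1))
    ours = PLS1Regression(n_components=a).fit(X, y).predict(X)
    ref = PLSRegression(n_components=a, scale=True).fit(X, y[:, None])
    assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-8)
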