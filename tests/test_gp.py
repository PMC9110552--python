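"""Exact GP regression: standardization contracts, closed-form and
dense-inverse oracles, likelihood identities and posterior properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scangp import KernelSpec, gp_predict, log_marginal_likelihood, standardize
from scangp.gp import _standardized_system
from scangp.kernels import kernel_matrix


def spec_with(**kw):
    base = dict(
        family="matern",
        nu=1.5,
        signal_variance=1.0,
        length_scale_r=1.5,
        length_scale_alpha=1.0,
        noise_variance=1e-2,
    )
    base.update(kw)
    return KernelSpec(**base)


def naive_posterior(X, y, Xt, spec):
    """Explicit-inverse evaluation of the posterior formulas, performed in
    the same standardized space — the brute-force oracle."""
    y = np.asarray(y, float)
    ys, Xs, params = standardize(y, X)
    s = spec.replace(
        length_scale_r=spec.length_scale_r / params.coord_scale[0],
        length_scale_alpha=spec.length_scale_alpha / params.coord_scale[1],
    )
    Ts = params.transform_coords(Xt)
    K = kernel_matrix(Xs, Xs, s) + (s.noise_variance + 1e-10 * s.signal_variance) * np.eye(len(ys))
    Ks = kernel_matrix(Xs, Ts, s)
    Kinv = np.linalg.inv(K)
    mean = params.inverse_values(Ks.T @ Kinv @ ys)
    var = (s.signal_variance - np.diag(Ks.T @ Kinv @ Ks)) * params.value_scale**2
    return mean, var


class TestStandardize:
    def test_two_point_case(self):
        v, c, p = standardize([0.0, 1.0], [[0.0, 0.0], [1.0, 1.0]])
        assert p.value_shift == pytest.approx(0.5)
        np.testing.assert_allclose(v, [-1.0, 1.0])
        assert abs(v.mean()) < 1e-12 and v.std() == pytest.approx(1.0)

    def test_round_trip_identity(self, rng):
        vals = rng.uniform(0, 1, 40)
        coords = rng.normal(3.0, 2.0, size=(40, 2))
        v, c, p = standardize(vals, coords)
        np.testing.assert_allclose(p.inverse_values(v), vals, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(p.inverse_coords(c), coords, rtol=1e-12, atol=1e-14)
        assert np.abs(c.mean(axis=0)).max() < 1e-12

    def test_constant_vector_flagged_not_error(self):
        v, _, p = standardize([0.3, 0.3, 0.3], np.zeros((3, 2)))
        assert p.degenerate
        np.testing.assert_allclose(v, 0.0)
        np.testing.assert_allclose(p.inverse_values(v), 0.3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_standardize_round_trip_property(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=17) * rng.uniform(0.1, 50)
    coords = rng.normal(size=(17, 2)) * rng.uniform(0.1, 100, size=2)
    v, c, p = standardize(vals, coords)
    assert np.abs(p.inverse_values(v) - vals).max() < 1e-9 * max(1, np.abs(vals).max())
    assert np.abs(p.inverse_coords(c) - coords).max() < 1e-9 * max(1, np.abs(coords).max())


class TestGPPredict:
    def test_exact_interpolation_limit(self, rng):
        X = rng.uniform(0, 8, size=(30, 2))
        y = rng.uniform(0, 1, 30)
        spec = spec_with(noise_variance=0.0)
        post = gp_predict(X, y, X, spec)
        assert np.abs(post.mean - y).max() < 1e-8
        assert post.variance.max() <= 1e-8 * spec.signal_variance

    def test_single_observation_closed_form(self):
        # 1x1 system: standardized correlation rho = k(d) / (sigma^2 + noise)
        spec = KernelSpec(
            family="squared_exponential",
            signal_variance=1.0,
            length_scale_r=2.0,
            length_scale_alpha=2.0,
            noise_variance=0.5,
        )
        X = np.array([[0.0, 0.0], [4.0, 0.0]])
        y = np.array([1.0, 0.0])
        post = gp_predict(X, y, np.array([[0.0, 0.0]]), spec)
        # by symmetry mu = 0.5; standardized y = (+1, -1); solve 2x2 exactly
        ys, Xs, p = standardize(y, X)
        s = spec.replace(
            length_scale_r=2.0 / p.coord_scale[0], length_scale_alpha=2.0 / p.coord_scale[1]
        )
        K = kernel_matrix(Xs, Xs, s) + spec.noise_variance * np.eye(2)
        Ks = kernel_matrix(Xs, Xs[:1], s)
        expect = p.inverse_values(Ks.T @ np.linalg.solve(K, ys))
        assert post.mean[0] == pytest.approx(float(expect[0]), abs=1e-9)

    def test_matches_dense_inverse_oracle(self, rng):
        X = rng.uniform(0, 5, size=(25, 2))
        y = rng.uniform(0, 1, 25)
        Xt = rng.uniform(0, 5, size=(10, 2))
        spec = spec_with()
        post = gp_predict(X, y, Xt, spec)
        mean, var = naive_posterior(X, y, Xt, spec)
        assert np.abs(post.mean - mean).max() < 1e-8
        assert np.abs(post.variance - var).max() < 1e-8

    def test_variance_never_exceeds_prior(self, rng):
        X = rng.uniform(0, 5, size=(40, 2))
        y = rng.uniform(0, 1, 40)
        Xt = rng.uniform(-2, 7, size=(60, 2))
        spec = spec_with(signal_variance=0.8)
        post = gp_predict(X, y, Xt, spec)
        prior = spec.signal_variance * np.var(y) / np.var(y)  # standardized prior is sigma^2
        assert np.all(post.variance <= spec.signal_variance * np.var(y) + 1e-8)
        del prior

    def test_adding_observation_never_raises_variance(self, rng):
        spec = spec_with()
        X = rng.uniform(0, 4, size=(10, 2))
        y = rng.uniform(0, 1, 10)
        Xt = rng.uniform(0, 4, size=(8, 2))
        base = gp_predict(X, y, Xt, spec).variance
        x_new = rng.uniform(0, 4, size=(1, 2))
        y_new = rng.uniform(0, 1, 1)
        grown = gp_predict(np.vstack([X, x_new]), np.append(y, y_new), Xt, spec).variance
        # variance is standardization-dependent through the value scale;
        # compare in standardized units of each fit
        assert np.all(grown / np.var(np.append(y, y_new)) <= base / np.var(y) + 1e-7)

    def test_mean_linear_in_observations(self, rng):
        # in standardized space the predictor is linear in y; check through
        # the de-standardized map with fixed standardization
        X = rng.uniform(0, 5, size=(20, 2))
        Xt = rng.uniform(0, 5, size=(7, 2))
        spec = spec_with(noise_variance=5e-2)
        y1 = rng.uniform(0, 1, 20)
        y2 = rng.uniform(0, 1, 20)
        a, b = 0.3, 0.6
        combo = gp_predict(X, a * y1 + b * y2, Xt, spec).mean
        m1 = gp_predict(X, y1, Xt, spec).mean
        m2 = gp_predict(X, y2, Xt, spec).mean
        # de-standardized GP mean is affine in y with weights independent of
        # y only through the (linear) standardization: a*m1 + b*m2 matches
        np.testing.assert_allclose(combo, a * m1 + b * m2, atol=1e-9)

    def test_frame_mismatch_rejected(self, rng):
        from scangp import PointSet

        X = PointSet(rng.uniform(0, 1, (5, 2)), frame="beam_native")
        T = PointSet(rng.uniform(0, 1, (3, 2)), frame="cartesian")
        with pytest.raises(ValueError):
            gp_predict(X, rng.uniform(0, 1, 5), T, spec_with())


class TestLogMarginalLikelihood:
    def test_unit_scalar_case(self):
        # N=1: standardized y = 0, K + noise = 1 => -(1/2) log 2 pi
        spec = KernelSpec(
            family="matern",
            nu=1.5,
            signal_variance=1.0,
            length_scale_r=1.0,
            length_scale_alpha=1.0,
            noise_variance=0.0,
        )
        lml = log_marginal_likelihood(np.array([[0.0, 0.0]]), [0.42], spec)
        assert lml == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-9)

    def test_matches_dense_determinant_oracle(self, rng):
        X = rng.uniform(0, 3, size=(3, 2))
        y = rng.uniform(0, 1, 3)
        spec = spec_with(noise_variance=0.1)
        lml = log_marginal_likelihood(X, y, spec)
        ys, Xs, p = standardize(y, X)
        s = spec.replace(
            length_scale_r=spec.length_scale_r / p.coord_scale[0],
            length_scale_alpha=spec.length_scale_alpha / p.coord_scale[1],
        )
        K = kernel_matrix(Xs, Xs, s) + (0.1 + 1e-10) * np.eye(3)
        expect = (
            -0.5 * ys @ np.linalg.inv(K) @ ys
            - 0.5 * math.log(np.linalg.det(K))
            - 1.5 * math.log(2 * math.pi)
        )
        assert lml == pytest.approx(float(expect), abs=1e-9)

    def test_quadratic_term_scaling(self, rng):
        # scaling the standardized data by c scales the quadratic term by c^2;
        # verified on the raw formula since standardization undoes scaling
        X = rng.uniform(0, 3, size=(6, 2))
        y = rng.normal(size=6)
        spec = spec_with(noise_variance=0.2)
        ys, Xs, p = standardize(y, X)
        s = spec.replace(
            length_scale_r=spec.length_scale_r / p.coord_scale[0],
            length_scale_alpha=spec.length_scale_alpha / p.coord_scale[1],
        )
        K = kernel_matrix(Xs, Xs, s) + (0.2 + 1e-10) * np.eye(6)
        Kinv = np.linalg.inv(K)
        q1 = ys @ Kinv @ ys
        c = 3.0
        q2 = (c * ys) @ Kinv @ (c * ys)
        assert q2 == pytest.approx(c**2 * q1, rel=1e-12)


def test_cross_check_against_sklearn():
    """Independent library cross-check: the posterior mean/std of an
    anisotropic Matérn GP agrees with scikit-learn's implementation."""
    sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    rng = np.random.default_rng(7)
    X = rng.uniform(0, 6, size=(40, 2))
    y = rng.uniform(0, 1, 40)
    Xt = rng.uniform(0, 6, size=(12, 2))
    noise = 1e-2
    spec = spec_with(noise_variance=noise, length_scale_r=2.0, length_scale_alpha=1.2)

    post = gp_predict(X, y, Xt, spec)

    # sklearn fits in raw coordinates with y-normalization, matching the
    # standardization-invariance of the model
    k = ConstantKernel(1.0, constant_value_bounds="fixed") * Matern(
        length_scale=[2.0, 1.2], length_scale_bounds="fixed", nu=1.5
    )
    g = GaussianProcessRegressor(kernel=k, alpha=noise, optimizer=None, normalize_y=True)
    g.fit(X, y)
    mean, std = g.predict(Xt, return_std=True)
    np.testing.assert_allclose(post.mean, mean, atol=1e-7)
    np.testing.assert_allclose(np.sqrt(post.variance), std, atol=1e-5)
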