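"""Model densities and the unconstrained parameterization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal

from shapetaste.model import (
    ModelParams,
    N_FREE_PARAMS,
    PriorSpec,
    build_covariance,
    lkj_log_density,
    log_posterior,
    log_prior,
    make_taste_target,
    mvn_log_likelihood,
    to_constrained,
    to_unconstrained,
)
from shapetaste.synthetic import exchangeable_corr

finite_vectors = st.lists(
    st.floats(-4, 4, allow_nan=False), min_size=N_FREE_PARAMS, max_size=N_FREE_PARAMS
).map(np.array)


def _interior_params(rho=0.3):
    return ModelParams(
        mu=np.array([38.0, 29.0, 41.0, 31.0]),
        sigma=np.array([15.0, 18.0, 20.0, 12.0]),
        corr=exchangeable_corr(rho),
    )


class TestBuildCovariance:
    def test_unit_sigma_identity_corr(self):
        assert np.array_equal(build_covariance(np.ones(4), np.eye(4)), np.eye(4))

    def test_two_dimensional_arithmetic(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        cov = build_covariance(np.array([2.0, 3.0]), corr)
        assert np.allclose(cov, [[4.0, 3.0], [3.0, 9.0]])

    @given(st.integers(0, 10_000))
    def test_correlation_reconstruction_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        sigma = rng.uniform(0.5, 30.0, 4)
        y = rng.normal(0, 1, N_FREE_PARAMS)
        corr = to_constrained(y)[0].corr
        cov = build_covariance(sigma, corr)
        d = np.sqrt(np.diag(cov))
        assert np.allclose(cov / np.outer(d, d), corr, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            build_covariance(np.ones(3), np.eye(4))


class TestLkjLogDensity:
    def test_identity_matrix_gives_zero(self):
        assert lkj_log_density(np.eye(4), eta=7.3) == 0.0

    def test_eta_one_gives_zero(self):
        assert lkj_log_density(exchangeable_corr(0.4), eta=1.0) == 0.0

    def test_two_by_two_closed_form(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        # det = 1 - 0.6^2 = 0.64; (eta - 1) log det = 2 log 0.64
        assert lkj_log_density(corr, eta=3.0) == pytest.approx(2 * np.log(0.64))

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            lkj_log_density(bad, eta=2.0)


class TestLogPrior:
    def test_interior_eta_one_value(self):
        lp = log_prior(_interior_params(), PriorSpec())
        assert lp == pytest.approx(-4 * np.log(100) - 4 * np.log(50))

    def test_out_of_support_mu(self):
        params = ModelParams(
            mu=np.array([-1.0, 50.0, 50.0, 50.0]),
            sigma=np.full(4, 10.0),
            corr=np.eye(4),
        )
        assert log_prior(params, PriorSpec()) == -np.inf

    def test_eta_two_adds_log_determinant(self):
        params = _interior_params(rho=0.5)
        base = log_prior(params, PriorSpec(lkj_eta=1.0))
        with_lkj = log_prior(params, PriorSpec(lkj_eta=2.0))
        assert with_lkj - base == pytest.approx(lkj_log_density(params.corr, 2.0))

    @pytest.mark.parametrize(
        "eta, expected",
        [(1.0, 2.0), (2.0, 4.0 / 3.0)],  # int_{-1}^{1} (1 - r^2)^(eta-1) dr
    )
    def test_prior_mass_in_two_condition_reduction(self, eta, expected):
        """Quadrature of exp(log_prior) over the 2-condition support equals
        the width product times the unnormalized LKJ mass (the reciprocal of
        the omitted normalizing constant)."""
        priors = PriorSpec(lkj_eta=eta)
        n_mu, n_sig, n_r = 4, 4, 400
        mus = np.linspace(0, 100, n_mu + 1)[:-1] + 50.0 / n_mu
        sigs = np.linspace(0, 50, n_sig + 1)[:-1] + 25.0 / n_sig
        rs = np.linspace(-1, 1, n_r + 1)[:-1] + 1.0 / n_r
        total = 0.0
        # uniform factors are flat, so fix one grid point per mu/sigma axis
        # and scale by the cell volume; integrate the r axis densely
        cell = (100.0 / n_mu) ** 2 * (50.0 / n_sig) ** 2 * (2.0 / n_r)
        for r in rs:
            corr = np.array([[1.0, r], [r, 1.0]])
            params = ModelParams(
                mu=np.array([mus[0], mus[1]]),
                sigma=np.array([sigs[0], sigs[1]]),
                corr=corr,
            )
            total += np.exp(log_prior(params, priors)) * cell * n_mu**2 * n_sig**2
        # integral of the uniform part is 1; LKJ part integrates to `expected`
        assert total == pytest.approx(expected, rel=0.01)


class TestMvnLogLikelihood:
    def test_row_at_mean_identity_covariance(self):
        params = ModelParams(mu=np.full(4, 50.0), sigma=np.ones(4), corr=np.eye(4))
        ll = mvn_log_likelihood(np.full((1, 4), 50.0), params)
        assert ll == pytest.approx(-2 * np.log(2 * np.pi))

    def test_additivity_over_identical_rows(self):
        params = _interior_params()
        row = np.array([[40.0, 30.0, 45.0, 28.0]])
        single = mvn_log_likelihood(row, params)
        assert mvn_log_likelihood(np.repeat(row, 7, axis=0), params) == pytest.approx(
            7 * single
        )

    @given(st.integers(0, 10_000))
    def test_matches_explicit_quadratic_form(self, seed):
        rng = np.random.default_rng(seed)
        params = _interior_params(rho=float(rng.uniform(-0.2, 0.7)))
        data = rng.normal(40, 15, (6, 4))
        cov = build_covariance(params.sigma, params.corr)
        inv = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        expected = 0.0
        for row in data:
            d = row - params.mu
            expected += -0.5 * (4 * np.log(2 * np.pi) + logdet + d @ inv @ d)
        assert mvn_log_likelihood(data, params) == pytest.approx(expected)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        params = _interior_params(0.4)
        data = rng.normal(40, 15, (10, 4))
        cov = build_covariance(params.sigma, params.corr)
        ref = multivariate_normal(params.mu, cov).logpdf(data).sum()
        assert mvn_log_likelihood(data, params) == pytest.approx(ref)


class TestLogPosterior:
    def test_out_of_support_is_minus_inf(self):
        params = ModelParams(
            mu=np.full(4, 50.0), sigma=np.full(4, 60.0), corr=np.eye(4)
        )
        data = np.full((3, 4), 50.0)
        assert log_posterior(data, params) == -np.inf

    def test_additivity_of_components(self):
        params = _interior_params()
        data = np.random.default_rng(1).normal(40, 10, (8, 4))
        assert log_posterior(data, params) == pytest.approx(
            log_prior(params) + mvn_log_likelihood(data, params)
        )

    def test_differences_reduce_to_likelihood_plus_lkj(self):
        priors = PriorSpec(lkj_eta=2.0)
        data = np.random.default_rng(2).normal(40, 10, (8, 4))
        a, b = _interior_params(0.1), _interior_params(0.5)
        delta_post = log_posterior(data, a, priors) - log_posterior(data, b, priors)
        delta_ref = (
            mvn_log_likelihood(data, a)
            - mvn_log_likelihood(data, b)
            + lkj_log_density(a.corr, 2.0)
            - lkj_log_density(b.corr, 2.0)
        )
        assert delta_post == pytest.approx(delta_ref)


class TestTransforms:
    @given(finite_vectors)
    def test_round_trip_from_unconstrained(self, y):
        params, _ = to_constrained(y)
        assert np.allclose(to_unconstrained(params), y, atol=1e-8)

    def test_round_trip_from_params(self):
        params = _interior_params(0.35)
        back, _ = to_constrained(to_unconstrained(params))
        assert np.allclose(back.mu, params.mu, atol=1e-10)
        assert np.allclose(back.sigma, params.sigma, atol=1e-10)
        assert np.allclose(back.corr, params.corr, atol=1e-10)

    def test_zero_vector_maps_to_center(self):
        params, _ = to_constrained(np.zeros(N_FREE_PARAMS))
        assert np.allclose(params.mu, 50.0)
        assert np.allclose(params.sigma, 25.0)
        assert np.allclose(params.corr, np.eye(4))

    @given(finite_vectors)
    def test_constrained_correlation_always_positive_definite(self, y):
        params, _ = to_constrained(y)
        assert np.all(np.linalg.eigvalsh(params.corr) > 0)

    @given(st.integers(0, 10_000))
    def test_log_jacobian_matches_finite_differences(self, seed):
        from shapetaste.model import _TRIL_COLS, _TRIL_ROWS

        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1.0, N_FREE_PARAMS)
        _, log_jac = to_constrained(y)

        def forward(v):
            p, _ = to_constrained(v)
            return np.concatenate([p.mu, p.sigma, p.corr[_TRIL_ROWS, _TRIL_COLS]])

        h = 1e-6
        J = np.empty((N_FREE_PARAMS, N_FREE_PARAMS))
        for i in range(N_FREE_PARAMS):
            e = np.zeros(N_FREE_PARAMS)
            e[i] = h
            J[:, i] = (forward(y + e) - forward(y - e)) / (2 * h)
        _, fd = np.linalg.slogdet(J)
        assert log_jac == pytest.approx(fd, abs=1e-5)

    def test_boundary_params_rejected(self):
        on_boundary = ModelParams(
            mu=np.full(4, 50.0), sigma=np.full(4, 50.0), corr=np.eye(4)
        )  # sigma exactly at the upper prior bound
        with pytest.raises(ValueError):
            to_unconstrained(on_boundary)

    def test_target_finite_on_interior_for_complete_data(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 100, (24, 4))
        target = make_taste_target(data)
        Y = rng.normal(0, 2, (50, N_FREE_PARAMS))
        assert np.all(np.isfinite(target.log_density(Y)))
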