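import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from auxsel.errors import DataError, FitDegenerateError, InvalidParameterError
from auxsel.models import (
    Dataset,
    EMSettings,
    GMM2Params,
    fit_complete,
    fit_em,
    logdensity_joint,
    logdensity_x,
    logdensity_y,
    posterior_z,
)
from conftest import PHI0, THETA0

CASE1 = GMM2Params(*THETA0, *PHI0)


@st.composite
def gmm_params(draw, with_aux=True):
    pi1 = draw(st.floats(0.05, 0.95))
    mu1y = draw(st.floats(-5, 5))
    mu2y = draw(st.floats(-5, 5))
    sy = draw(st.floats(0.1, 5.0))
    if not with_aux:
        return GMM2Params(pi1, mu1y, mu2y, sy)
    mu1a = draw(st.floats(-5, 5))
    mu2a = draw(st.floats(-5, 5))
    sa = draw(st.floats(0.1, 5.0))
    rho = draw(st.floats(-0.9, 0.9))
    return GMM2Params(pi1, mu1y, mu2y, sy, mu1a, mu2a, sa, rho * np.sqrt(sy * sa))


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

class TestDataset:
    def test_length_mismatch(self):
        with pytest.raises(DataError):
            Dataset(y=[1.0, 2.0], a=[1.0])

    def test_bad_latent(self):
        with pytest.raises(DataError):
            Dataset(y=[1.0, 2.0], z=[0, 2])

    def test_drop(self):
        d = Dataset(y=[1.0, 2.0, 3.0], a=[4.0, 5.0, 6.0], z=[0, 1, 0])
        d2 = d.drop(1)
        assert d2.n == 2
        assert list(d2.y) == [1.0, 3.0]
        assert list(d2.a) == [4.0, 6.0]
        assert list(d2.z) == [0, 0]


# ---------------------------------------------------------------------------
# Parameter container
# ---------------------------------------------------------------------------

class TestGMM2Params:
    def test_vector_roundtrip(self):
        vec = CASE1.to_vector()
        assert vec.tolist() == [0.6, -1.2, 1.2, 0.7, 1.8, -1.8, 0.49, 0.0]
        assert GMM2Params.from_vector(vec) == CASE1

    def test_partial_aux_rejected(self):
        with pytest.raises(InvalidParameterError):
            GMM2Params(0.5, 0, 1, 1.0, mu1a=0.0)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(InvalidParameterError):
            GMM2Params(0.5, 0, 1, 1.0, 0.0, 1.0, 1.0, 1.5)

    def test_dims(self):
        assert CASE1.d == 4 and CASE1.f == 4
        assert CASE1.theta().f == 0


# ---------------------------------------------------------------------------
# Log-densities
# ---------------------------------------------------------------------------

class TestLogDensities:
    def test_joint_matches_scipy_oracle_at_case1_mean(self):
        # independent two-term oracle via scipy multivariate normal densities
        y, a = -1.2, 1.8
        cov = np.array([[0.7, 0.0], [0.0, 0.49]])
        dens = 0.6 * stats.multivariate_normal.pdf([y, a], [-1.2, 1.8], cov) + \
               0.4 * stats.multivariate_normal.pdf([y, a], [1.2, -1.8], cov)
        assert logdensity_joint(CASE1, y, a) == pytest.approx(np.log(dens), abs=1e-12)

    def test_joint_collapses_for_identical_components(self):
        p = GMM2Params(0.5, 0.3, 0.3, 1.1, -0.2, -0.2, 0.8, 0.1)
        val = logdensity_joint(p, 0.5, 0.7)
        ref = stats.multivariate_normal.logpdf(
            [0.5, 0.7], [0.3, -0.2], [[1.1, 0.1], [0.1, 0.8]]
        )
        assert val == pytest.approx(ref, abs=1e-12)

    def test_joint_label_swap_symmetry(self):
        assert logdensity_joint(CASE1, 0.0, 0.0) == pytest.approx(
            logdensity_joint(CASE1.swapped(), 0.0, 0.0), abs=1e-12
        )

    def test_joint_integrates_to_one(self):
        val, _ = integrate.dblquad(
            lambda a, y: np.exp(logdensity_joint(CASE1, y, a)),
            -8, 8, -8, 8,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_joint_requires_pd(self):
        with pytest.raises(InvalidParameterError):
            logdensity_joint(CASE1.theta(), 0.0, 0.0)

    def test_y_matches_two_term_oracle(self):
        y = 0.0
        dens = 0.6 * stats.norm.pdf(y, -1.2, np.sqrt(0.7)) + \
               0.4 * stats.norm.pdf(y, 1.2, np.sqrt(0.7))
        assert logdensity_y(CASE1, y) == pytest.approx(np.log(dens), abs=1e-12)

    def test_y_symmetric_mixture_at_zero(self):
        p = GMM2Params(0.5, -1.3, 1.3, 0.9)
        # both mixture terms coincide at y=0
        assert logdensity_y(p, 0.0) == pytest.approx(
            np.log(stats.norm.pdf(0.0, 1.3, np.sqrt(0.9))), abs=1e-12
        )

    def test_y_ignores_phi(self):
        other = GMM2Params(*THETA0, 5.0, -3.0, 2.0, 0.3)
        ys = np.linspace(-3, 3, 7)
        np.testing.assert_allclose(
            logdensity_y(CASE1, ys), logdensity_y(other, ys), atol=1e-14
        )

    def test_marginalization_over_a(self):
        for y in (-1.0, 0.0, 2.3):
            val, _ = integrate.quad(
                lambda a: np.exp(logdensity_joint(CASE1, y, a)), -10, 10
            )
            assert np.log(val) == pytest.approx(logdensity_y(CASE1, y), abs=1e-8)

    def test_x_closed_form(self):
        # log 0.6 + log N(-1.2; -1.2, 0.7)
        ref = np.log(0.6) + stats.norm.logpdf(-1.2, -1.2, np.sqrt(0.7))
        assert logdensity_x(CASE1, -1.2, 1) == pytest.approx(ref, abs=1e-12)

    def test_x_sums_to_y(self):
        ys = np.linspace(-4, 4, 11)
        total = np.exp(logdensity_x(CASE1, ys, np.ones(11))) + np.exp(
            logdensity_x(CASE1, ys, np.zeros(11))
        )
        np.testing.assert_allclose(np.log(total), logdensity_y(CASE1, ys), atol=1e-10)

    def test_x_exchangeable_components(self):
        p = GMM2Params(0.5, 0.7, 0.7, 1.2)
        assert logdensity_x(p, 0.3, 1) == pytest.approx(
            logdensity_x(p, 0.3, 0), abs=1e-14
        )

    def test_x_rejects_bad_z(self):
        with pytest.raises(DataError):
            logdensity_x(CASE1, 0.0, 2)

    @settings(max_examples=50, deadline=None)
    @given(gmm_params(), st.floats(-5, 5), st.floats(-5, 5))
    def test_label_swap_invariance_property(self, p, y, a):
        assert logdensity_joint(p, y, a) == pytest.approx(
            logdensity_joint(p.swapped(), y, a), abs=1e-12
        )
        assert logdensity_y(p, y) == pytest.approx(
            logdensity_y(p.swapped(), y), abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(gmm_params(with_aux=False), st.floats(-6, 6))
    def test_logsumexp_over_z_property(self, p, y):
        from scipy.special import logsumexp

        lse = logsumexp([logdensity_x(p, y, 1), logdensity_x(p, y, 0)])
        assert lse == pytest.approx(logdensity_y(p, y), abs=1e-10)


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------

class TestPosterior:
    def test_symmetric_point(self):
        p = GMM2Params(0.5, -1.0, 1.0, 0.8)
        np.testing.assert_allclose(posterior_z(p, 0.0), [0.5, 0.5], atol=1e-14)

    def test_bayes_oracle_joint(self):
        y, a = -1.2, 1.8
        cov = np.array([[0.7, 0.0], [0.0, 0.49]])
        n1 = 0.6 * stats.multivariate_normal.pdf([y, a], [-1.2, 1.8], cov)
        n2 = 0.4 * stats.multivariate_normal.pdf([y, a], [1.2, -1.8], cov)
        post = posterior_z(CASE1, y, a)
        assert post[0] == pytest.approx(n1 / (n1 + n2), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(gmm_params(), st.floats(-5, 5), st.floats(-5, 5))
    def test_sums_to_one_property(self, p, y, a):
        assert posterior_z(p, y).sum() == pytest.approx(1.0, abs=1e-12)
        assert posterior_z(p, y, a).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_em_responsibilities(self, fit_b_n200, case1_n200):
        post = posterior_z(fit_b_n200.params, case1_n200.y, case1_n200.a)
        np.testing.assert_allclose(post, fit_b_n200.responsibilities, atol=1e-12)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

class TestFitEM:
    def test_parameter_recovery_case1_n2000(self):
        from auxsel.simulation import generate

        data = generate("case1", 2000, seed=10)
        fit = fit_em(data, use_auxiliary=True, settings=EMSettings(seed=0))
        theta = fit.params.theta()
        cands = [theta.to_vector(), theta.swapped().to_vector()]
        err = min(np.abs(np.asarray(c) - np.asarray(THETA0)).max() for c in cands)
        assert err < 0.1

    def test_recovery_n5000_within_3se(self, fit_b_n5000):
        # asymptotic Monte-Carlo SEs of theta-hat coordinates at n=5000 are
        # below ~0.03 for this model; 3 SE ~ 0.1 is a safe envelope
        theta = fit_b_n5000.params.theta()
        cands = [theta.to_vector(), theta.swapped().to_vector()]
        err = min(np.abs(np.asarray(c) - np.asarray(THETA0)).max() for c in cands)
        assert err < 0.1

    def test_separated_clusters(self, separated_data):
        fit = fit_em(separated_data, use_auxiliary=True, settings=EMSettings(seed=0))
        resp = fit.responsibilities
        assert np.all((resp < 1e-6) | (resp > 1 - 1e-6))
        z = separated_data.z.astype(bool)
        m1 = separated_data.y[z].mean()
        m2 = separated_data.y[~z].mean()
        fitted = sorted([fit.params.mu1y, fit.params.mu2y])
        assert fitted == pytest.approx(sorted([m1, m2]), abs=1e-3)

    def test_loglik_trace_monotone(self, fit_b_n200, fit_y_n200):
        for fit in (fit_b_n200, fit_y_n200):
            diffs = np.diff(fit.loglik_trace)
            assert diffs.min() > -1e-10

    def test_responsibility_rows_sum_to_one(self, fit_b_n200):
        np.testing.assert_allclose(
            fit_b_n200.responsibilities.sum(axis=1), 1.0, atol=1e-10
        )

    def test_loglik_recompute(self, fit_b_n200, case1_n200, fit_y_n200):
        ll = np.mean(
            logdensity_joint(fit_b_n200.params, case1_n200.y, case1_n200.a)
        )
        assert ll == pytest.approx(fit_b_n200.loglik_per_obs, abs=1e-8)
        lly = np.mean(logdensity_y(fit_y_n200.params, case1_n200.y))
        assert lly == pytest.approx(fit_y_n200.loglik_per_obs, abs=1e-8)

    def test_phi_absent_without_auxiliary(self, fit_y_n200):
        assert not fit_y_n200.params.has_aux

    def test_too_small_n(self):
        with pytest.raises(DataError):
            fit_em(Dataset(y=[1.0, 2.0, 3.0]), use_auxiliary=False)

    def test_missing_aux_column(self):
        with pytest.raises(DataError):
            fit_em(Dataset(y=np.arange(10.0)), use_auxiliary=True)

    def test_degenerate_data_raises(self):
        data = Dataset(y=np.zeros(20))
        with pytest.raises(FitDegenerateError):
            fit_em(data, use_auxiliary=False, settings=EMSettings(seed=0))

    def test_warm_start_single_run(self, case1_n200, fit_b_n200):
        refit = fit_em(
            case1_n200, use_auxiliary=True, settings=EMSettings(seed=0),
            init=fit_b_n200.params,
        )
        assert refit.n_restarts_used == 1
        assert refit.loglik_per_obs == pytest.approx(
            fit_b_n200.loglik_per_obs, abs=1e-9
        )


# ---------------------------------------------------------------------------
# Complete-data fit
# ---------------------------------------------------------------------------

class TestFitComplete:
    def test_exact_toy_degenerate(self):
        data = Dataset(y=[0.0, 0.0, 2.0, 2.0], z=[1, 1, 0, 0])
        with pytest.raises(FitDegenerateError):
            fit_complete(data)

    def test_hand_computed(self):
        data = Dataset(y=[-1.0, 1.0, -1.0, 1.0], z=[1, 1, 0, 0])
        fit = fit_complete(data)
        assert fit.params.pi1 == pytest.approx(0.5)
        assert fit.params.mu1y == pytest.approx(0.0)
        assert fit.params.mu2y == pytest.approx(0.0)
        assert fit.params.sigma_y2 == pytest.approx(1.0)

    def test_matches_numerical_optimizer(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(8)
        z = np.array([1] * 12 + [0] * 8)
        y = np.where(z == 1, -1.0, 2.0) + rng.standard_normal(20)
        data = Dataset(y=y, z=z)
        fit = fit_complete(data)

        def nll(vec):
            p = GMM2Params(*vec)
            return -np.mean(logdensity_x(p, y, z))

        res = minimize(
            nll, [0.5, -0.5, 1.5, 1.0],
            bounds=[(1e-3, 1 - 1e-3), (-10, 10), (-10, 10), (1e-3, 20)],
            method="L-BFGS-B",
        )
        np.testing.assert_allclose(res.x, fit.params.to_vector(), atol=1e-5)
        assert nll(fit.params.to_vector()) <= res.fun + 1e-6

    def test_requires_labels(self):
        with pytest.raises(DataError):
            fit_complete(Dataset(y=np.arange(6.0)))

    def test_empty_class(self):
        with pytest.raises(DataError):
            fit_complete(Dataset(y=np.arange(6.0), z=np.ones(6)))
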