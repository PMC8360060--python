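"""Model definitions: links, likelihoods, priors, unconstrained scale."""

import numpy as np
import pytest
from scipy.special import expit

import fbbreg as f
from fbbreg.regression import LINKS


def _toy_data(family_needs_zeros=False):
    g = np.random.default_rng(2)
    x = g.uniform(-1, 1, 40)
    n = g.poisson(30, 40) + 1
    y = g.binomial(n, expit(0.3 + x))
    if family_needs_zeros:
        y[:5] = 0
    X = np.column_stack([np.ones_like(x), x])
    return f.RegressionData(y=y, n=n, X=X)


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------

def test_linear_predictor_intercept_only():
    X = np.ones((5, 1))
    np.testing.assert_allclose(f.linear_predictor_mean(np.zeros(1), X), 0.5)


def test_linear_predictor_worked_example():
    mu = f.linear_predictor_mean(np.array([1.0, 2.0]), np.array([[1.0, 0.5]]))
    assert mu[0] == pytest.approx(expit(2.0))
    assert mu[0] == pytest.approx(0.88079707, abs=1e-7)


def test_linear_predictor_is_clamped_inside_unit_interval():
    mu = f.linear_predictor_mean(np.array([1000.0]), np.array([[1.0], [-1.0]]))
    assert np.all((mu > 0) & (mu < 1))


def test_linear_predictor_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension mismatch"):
        f.linear_predictor_mean(np.zeros(3), np.ones((4, 2)))


@pytest.mark.parametrize("link", sorted(LINKS))
def test_links_round_trip(link):
    mu = np.linspace(0.05, 0.95, 9)
    back = LINKS[link].inverse(LINKS[link].forward(mu))
    np.testing.assert_allclose(back, mu, atol=1e-9)


# ---------------------------------------------------------------------------
# data validation
# ---------------------------------------------------------------------------

def test_regression_data_rejects_y_above_n():
    with pytest.raises(ValueError, match="row 1"):
        f.RegressionData(y=[1, 5], n=[3, 3], X=np.ones((2, 1)))


def test_regression_data_warns_on_rank_deficiency():
    X = np.column_stack([np.ones(4), np.ones(4)])
    with pytest.warns(UserWarning, match="rank"):
        f.RegressionData(y=[1, 1, 1, 1], n=[2, 2, 2, 2], X=X)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_loglik_total_is_sum_of_vector():
    data = _toy_data()
    extras = {"phi": 3.0, "w": 0.4, "p": 0.5, "q": 0.2}
    for fam in f.FAMILIES:
        model = f.RegressionModel(family=fam)
        eta = np.concatenate([[0.3, 1.0], [extras[e] for e in model.extra_names]])
        total, vec = model.log_likelihood(data, eta)
        assert total == pytest.approx(vec.sum())
        assert len(vec) == data.n_obs
        assert np.all(np.isfinite(vec))


def test_fbb_family_matches_bb_family_at_inner_point():
    data = _toy_data()
    bb = f.RegressionModel(family="beta-binomial")
    fbb = f.RegressionModel(family="fbb")
    beta = np.array([0.4, 0.9])
    nu = 6.0
    # the inner-point identity needs mu = p, so use an intercept-only design
    X0 = np.ones((data.n_obs, 1))
    data0 = f.RegressionData(y=data.y, n=data.n, X=X0)
    b0 = 0.25
    mu = expit(b0)
    t_bb, _ = bb.log_likelihood(data0, np.array([b0, nu]))
    t_fbb, _ = fbb.log_likelihood(data0, np.array([b0, 1.0 / (nu + 1.0), nu + 1.0, mu]))
    assert t_fbb == pytest.approx(t_bb, rel=1e-10)


def test_bb_likelihood_approaches_binomial_in_small_theta_limit():
    data = _toy_data()
    bb = f.RegressionModel(family="beta-binomial")
    binm = f.RegressionModel(family="binomial")
    beta = np.array([0.3, 1.0])
    phi = 1.0 / 1e-8 - 1.0  # theta = 1e-8
    t_bb, _ = bb.log_likelihood(data, np.concatenate([beta, [phi]]))
    t_bin, _ = binm.log_likelihood(data, beta)
    assert t_bb == pytest.approx(t_bin, rel=1e-5)


def test_boundary_observations_are_finite():
    # y = 0 and y = n rows must not produce -inf for any family
    data = f.RegressionData(y=[0, 10], n=[10, 10], X=np.ones((2, 1)))
    for fam in f.FAMILIES:
        model = f.RegressionModel(family=fam)
        extras = {"phi": 2.0, "w": 0.5, "p": 0.5, "q": 0.3}
        eta = np.concatenate([[8.0], [extras[e] for e in model.extra_names]])
        total, vec = model.log_likelihood(data, eta)
        assert np.all(np.isfinite(vec))


def test_invalid_eta_is_rejected_not_raised():
    data = _toy_data()
    model = f.RegressionModel(family="fbb")
    total, vec = model.log_likelihood(data, np.array([0.0, 0.0, 1.5, 2.0, 0.5]))  # w > 1
    assert total == -np.inf
    total, _ = model.log_likelihood(data, np.array([0.0, 0.0, 0.5, -2.0, 0.5]))  # phi < 0
    assert total == -np.inf


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------

def test_log_posterior_flat_in_equal_likelihood_directions():
    data = _toy_data()
    model = f.RegressionModel(family="beta-binomial")
    eta1 = np.array([0.2, 0.7, 3.0])
    lp1 = model.log_posterior(data, eta1)
    assert np.isfinite(lp1)
    assert model.log_posterior(data, eta1) == lp1  # deterministic
    assert model.log_posterior(data, np.array([0.2, 0.7, -3.0])) == -np.inf


def test_zero_inflated_posterior_includes_q_prior_support():
    data = _toy_data(family_needs_zeros=True)
    model = f.RegressionModel(family="zi-binomial")
    assert np.isfinite(model.log_posterior(data, np.array([0.2, 0.7, 0.3])))
    assert model.log_posterior(data, np.array([0.2, 0.7, 1.2])) == -np.inf


def test_phi_prior_induced_by_uniform_theta():
    # density of phi under theta ~ U(0,1) is 1/(phi+1)^2
    data = _toy_data()
    model = f.RegressionModel(family="beta-binomial")
    lp3 = model.log_prior(np.array([0.0, 0.0, 3.0]), data)
    lp9 = model.log_prior(np.array([0.0, 0.0, 9.0]), data)
    assert lp3 - lp9 == pytest.approx(2.0 * (np.log(10.0) - np.log(4.0)))


def test_unconstrained_round_trip():
    data = _toy_data()
    for fam in f.FAMILIES:
        model = f.RegressionModel(family=fam)
        extras = {"phi": 2.5, "w": 0.3, "p": 0.6, "q": 0.2}
        eta = np.concatenate([[0.5, -1.0], [extras[e] for e in model.extra_names]])
        z = model.to_unconstrained(eta, data)
        back = model.to_natural(z, data)[0]
        np.testing.assert_allclose(back, eta, rtol=1e-9)


def test_unconstrained_posterior_matches_natural_up_to_jacobian():
    data = _toy_data()
    model = f.RegressionModel(family="fbb")
    eta = np.array([0.3, 1.0, 0.4, 2.0, 0.6])
    z = model.to_unconstrained(eta, data)
    lp_u = model.log_posterior_unconstrained(z, data)[0]
    lp_n = model.log_posterior(data, eta)
    theta = 1.0 / (2.0 + 1.0)
    jac = sum(np.log(v * (1 - v)) for v in (0.4, theta, 0.6))
    # the theta->phi change of variable cancels against the induced phi prior
    prior_phi = -2.0 * np.log1p(2.0)
    assert lp_u == pytest.approx(lp_n + jac - prior_phi, rel=1e-8)


def test_replicates_stay_in_support():
    data = _toy_data()
    rng = np.random.default_rng(0)
    for fam in f.FAMILIES:
        model = f.RegressionModel(family=fam)
        extras = {"phi": 2.0, "w": 0.5, "p": 0.5, "q": 0.3}
        eta = np.concatenate([[0.3, 1.0], [extras[e] for e in model.extra_names]])
        y_rep = model.replicate(eta[None, :], data, rng)
        assert y_rep.shape == (1, data.n_obs)
        assert np.all(y_rep >= 0) and np.all(y_rep <= data.n)
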