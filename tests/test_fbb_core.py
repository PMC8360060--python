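"""Exact-math checks for the BB / FBB / zero-inflated distribution family."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import binom

import fbbreg as f
from fbbreg.fbb_core import fb_log_pdf

UNIT = st.floats(0.05, 0.95)
PREC = st.floats(0.2, 50.0)


# ---------------------------------------------------------------------------
# pmf values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "y, expected", [(1, np.log(0.3)), (0, np.log(0.7))]
)
def test_bb_reduces_to_bernoulli_at_n1(y, expected):
    assert f.bb_log_pmf(y, f.BBParams(1, 0.3, 5.0)) == pytest.approx(expected, rel=1e-12)


def test_bb_log_pmf_matches_high_precision_formula():
    """Direct arbitrary-precision evaluation of the binomial-coefficient
    times beta-function-ratio form is the oracle."""
    sympy = pytest.importorskip("sympy")
    y, n, mu, phi = 3, 10, sympy.Rational(1, 2), 9
    a, b = phi * mu, phi * (1 - mu)
    exact = sympy.binomial(n, y) * sympy.beta(a + y, b + n - y) / sympy.beta(a, b)
    expected = float(sympy.log(exact).evalf(30))
    assert f.bb_log_pmf(3, f.BBParams(10, 0.5, 9.0)) == pytest.approx(expected, abs=1e-12)


@given(mu=UNIT, phi=PREC, n=st.integers(1, 200))
def test_bb_pmf_normalizes(mu, phi, n):
    logp = f.bb_log_pmf(np.arange(n + 1), f.BBParams(n, mu, phi))
    assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-10)


@given(mu=UNIT, w=UNIT, phi=PREC, p=UNIT, n=st.integers(1, 200))
def test_fbb_pmf_normalizes(mu, w, phi, p, n):
    logp = f.fbb_log_pmf(np.arange(n + 1), f.FBBParams(n, mu, w, phi, p))
    assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-10)


@given(q=UNIT, mu=UNIT, phi=PREC, n=st.integers(1, 100))
def test_zero_inflated_pmfs_normalize(q, mu, phi, n):
    y = np.arange(n + 1)
    zibb = f.zi_log_pmf(y, q, lambda t: f.bb_log_pmf(t, f.BBParams(n, mu, phi)))
    zibin = f.zi_log_pmf(y, q, lambda t: binom.logpmf(t, n, mu))
    assert np.exp(zibb).sum() == pytest.approx(1.0, abs=1e-10)
    assert np.exp(zibin).sum() == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("mu,w,phi,p", [(0.3, 0.6, 4.0, 0.4), (0.7, 0.2, 1.5, 0.8)])
def test_fbb_pmf_equals_compound_quadrature(mu, w, phi, p):
    """The mixture pmf must equal the binomial compounded over the
    flexible-beta mixing density (independent numerical oracle)."""
    n = 12
    params = f.FBBParams(n, mu, w, phi, p)
    for y in (0, 3, 7, 12):
        integral, _ = quad(
            lambda t: binom.pmf(y, n, t) * np.exp(fb_log_pdf(t, mu, w, phi, p)),
            0.0, 1.0, limit=200,
        )
        assert np.exp(f.fbb_log_pmf(y, params)) == pytest.approx(integral, rel=1e-7)


@given(p0=UNIT, nu=st.floats(0.5, 30.0))
def test_bb_is_inner_point_of_fbb_family(p0, nu):
    """FBB(n, mu=p0, w=1/(nu+1), phi=nu+1, p=p0) coincides with BB(n, p0, nu)."""
    n = 10
    y = np.arange(n + 1)
    fbb = f.fbb_log_pmf(y, f.FBBParams(n, p0, 1.0 / (nu + 1.0), nu + 1.0, p0))
    bb = f.bb_log_pmf(y, f.BBParams(n, p0, nu))
    np.testing.assert_allclose(fbb, bb, rtol=1e-9, atol=1e-12)


def test_fbb_can_be_bimodal():
    # strongly separated symmetric components give two local maxima
    pmf = np.exp(f.fbb_log_pmf(np.arange(11), f.FBBParams(10, 0.5, 0.9, 9.0, 0.5)))
    padded = np.concatenate([[-1.0], pmf, [-1.0]])
    local_max = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
    assert local_max.sum() >= 2
    # a weakly separated mixture stays unimodal
    uni = np.exp(f.fbb_log_pmf(np.arange(11), f.FBBParams(10, 0.5, 0.1, 9.0, 0.5)))
    padded = np.concatenate([[-1.0], uni, [-1.0]])
    local_max = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
    assert local_max.sum() == 1


def test_count_domain_errors():
    with pytest.raises(ValueError):
        f.bb_log_pmf(11, f.BBParams(10, 0.3, 2.0))
    with pytest.raises(ValueError):
        f.bb_log_pmf(-1, f.BBParams(10, 0.3, 2.0))
    with pytest.raises(ValueError):
        f.BBParams(10, 1.0, 2.0)
    with pytest.raises(ValueError):
        f.FBBParams(10, 0.5, 0.0, 2.0, 0.5)
    with pytest.raises(ValueError):
        f.BBParams(10, 0.5, -1.0)


# ---------------------------------------------------------------------------
# reparameterization pieces
# ---------------------------------------------------------------------------

def test_component_means_worked_example():
    lam1, lam2 = f.component_means(1.0 / 3.0, 0.75, 0.5)
    assert lam1 == pytest.approx(0.5833333333, abs=1e-9)
    assert lam2 == pytest.approx(0.0833333333, abs=1e-9)


@given(mu=UNIT, w=UNIT, p=UNIT)
def test_component_means_mixture_identity_and_order(mu, w, p):
    lam1, lam2 = f.component_means(mu, w, p)
    assert lam1 > lam2
    assert 0.0 < lam2 and lam1 < 1.0
    assert p * lam1 + (1.0 - p) * lam2 == pytest.approx(mu, abs=1e-12)


def test_component_means_collapse_as_w_vanishes():
    lam1, lam2 = f.component_means(0.5, 1e-9, 0.5)
    assert lam1 == pytest.approx(0.5, abs=1e-8)
    assert lam2 == pytest.approx(0.5, abs=1e-8)


def test_m_factor_examples_and_symmetry():
    assert f.m_factor(0.4, 0.4) == pytest.approx(1.0)
    assert f.m_factor(0.2, 0.5) == pytest.approx(0.25)
    g = np.random.default_rng(3)
    for a, b in g.uniform(0.05, 0.95, size=(20, 2)):
        assert f.m_factor(a, b) == pytest.approx(f.m_factor(b, a), rel=1e-12)
        assert 0.0 < f.m_factor(a, b) <= 1.0


# ---------------------------------------------------------------------------
# moments and intraclass correlation
# ---------------------------------------------------------------------------

def test_bb_moments_limits():
    _, var1 = f.bb_moments(f.BBParams(1, 0.3, 2.0))
    assert var1 == pytest.approx(0.3 * 0.7)
    _, var_big_phi = f.bb_moments(f.BBParams(20, 0.3, 1e9))
    assert var_big_phi == pytest.approx(20 * 0.3 * 0.7, rel=1e-6)


def _check_sampled_moments(theory_mean, theory_var, draws):
    b = len(draws)
    se_mean = draws.std(ddof=1) / np.sqrt(b)
    m2 = draws.var(ddof=1)
    m4 = np.mean((draws - draws.mean()) ** 4)
    se_var = np.sqrt(max(m4 - m2**2, 0.0) / b)
    assert draws.mean() == pytest.approx(theory_mean, abs=4 * se_mean)
    assert m2 == pytest.approx(theory_var, abs=4 * se_var)


def test_bb_moments_match_sampler(rng):
    params = f.BBParams(20, 0.3, 4.0)
    mean, var = f.bb_moments(params)
    _check_sampled_moments(mean, var, f.sample_bb(params, 1_000_000, rng).astype(float))


def test_fbb_moments_match_sampler(rng):
    params = f.FBBParams(10, 1.0 / 3.0, 0.75, 2.333, 0.5)
    mean, var = f.fbb_moments(params)
    _check_sampled_moments(mean, var, f.sample_fbb(params, 1_000_000, rng).astype(float))


def test_fbb_variance_dominates_matched_bb():
    g = np.random.default_rng(8)
    for _ in range(25):
        mu, w, p = g.uniform(0.05, 0.95, size=3)
        phi = g.uniform(0.5, 30)
        n = int(g.integers(2, 100))
        _, v_fbb = f.fbb_moments(f.FBBParams(n, mu, w, phi, p))
        _, v_bb = f.bb_moments(f.BBParams(n, mu, phi))
        assert v_fbb >= v_bb


def test_fbb_moments_match_bb_at_inner_point():
    p0, nu, n = 0.35, 4.0, 15
    assert f.fbb_moments(f.FBBParams(n, p0, 1 / (nu + 1), nu + 1, p0)) == pytest.approx(
        f.bb_moments(f.BBParams(n, p0, nu))
    )


@pytest.mark.parametrize("phi,expected", [(1.0, 0.5), (99.0, 0.01), (1e12, 0.0)])
def test_icc_bb(phi, expected):
    assert f.icc_bb(phi) == pytest.approx(expected, abs=1e-9)


def test_icc_fbb_worked_example_and_mu_equals_p():
    assert f.icc_fbb(0.2, 0.5, 3.0, 0.5) == pytest.approx(0.296875)
    theta = f.icc_bb(7.0)
    assert f.icc_fbb(0.4, 0.6, 7.0, 0.4) == pytest.approx(theta + (1 - theta) * 0.36)


@given(mu=UNIT, phi=PREC, p=UNIT)
def test_icc_fbb_monotone_in_w_symmetric_and_bounded(mu, phi, p):
    ws = np.linspace(0.05, 0.95, 10)
    vals = [f.icc_fbb(mu, w, phi, p) for w in ws]
    assert np.all(np.diff(vals) > 0)
    theta = f.icc_bb(phi)
    assert all(theta < v < 1.0 for v in vals)
    assert f.icc_fbb(mu, 0.5, phi, p) == pytest.approx(f.icc_fbb(p, 0.5, phi, mu), rel=1e-12)


def test_icc_fbb_limits_to_bb_value():
    theta = f.icc_bb(5.0)
    assert f.icc_fbb(0.3, 1e-4, 5.0, 0.6) == pytest.approx(theta, abs=1e-6)
    assert f.icc_fbb(0.3, 0.5, 5.0, 1e-4) == pytest.approx(theta, abs=1e-3)


# ---------------------------------------------------------------------------
# zero probabilities
# ---------------------------------------------------------------------------

def test_zero_prob_bb_basics():
    assert f.zero_prob_bb(f.BBParams(1, 0.3, 2.0)) == pytest.approx(0.7)
    assert f.zero_prob_bb(f.BBParams(5, 1.0 - 1e-9, 2.0)) == pytest.approx(0.0, abs=1e-6)
    params = f.BBParams(5, 0.3, 2.0)
    assert f.zero_prob_bb(params) == pytest.approx(np.exp(f.bb_log_pmf(0, params)), rel=1e-12)


def test_zero_prob_fbb_consistency_limits_and_argmax():
    params = f.FBBParams(8, 0.3, 0.5, 2.0, 0.6)
    assert f.zero_prob_fbb(params) == pytest.approx(np.exp(f.fbb_log_pmf(0, params)), rel=1e-12)
    # w -> 0 limit recovers the BB zero probability
    near = f.zero_prob_fbb(f.FBBParams(8, 0.3, 1e-4, 2.0, 0.6))
    assert near == pytest.approx(f.zero_prob_bb(f.BBParams(8, 0.3, 2.0)), abs=1e-6)
    # p at the boundary recovers it too
    for p_edge in (1e-4, 1.0 - 1e-4):
        edge = f.zero_prob_fbb(f.FBBParams(8, 0.3, 0.5, 2.0, p_edge))
        assert edge == pytest.approx(f.zero_prob_bb(f.BBParams(8, 0.3, 2.0)), abs=1e-3)
    # monotone increasing in w
    vals = [f.zero_prob_fbb(f.FBBParams(8, 0.3, w, 2.0, 0.6)) for w in np.linspace(0.05, 0.95, 12)]
    assert np.all(np.diff(vals) > 0)
    # maximized over p at p = mu
    grid = np.linspace(0.02, 0.98, 97)
    zp = [f.zero_prob_fbb(f.FBBParams(8, 0.3, 0.5, 2.0, p)) for p in grid]
    assert grid[int(np.argmax(zp))] == pytest.approx(0.3, abs=0.02)


# ---------------------------------------------------------------------------
# zero-inflated pmf and samplers
# ---------------------------------------------------------------------------

def test_zi_log_pmf_values():
    base = lambda y: np.where(np.asarray(y) == 0, np.log(0.1), np.log(0.9))
    assert f.zi_log_pmf(0, 0.5, base) == pytest.approx(np.log(0.55))
    tiny_q = f.zi_log_pmf(np.array([0, 1]), 1e-9, base)
    np.testing.assert_allclose(tiny_q, base(np.array([0, 1])), atol=1e-8)


def test_samplers_reproducible_and_in_support():
    params = f.FBBParams(10, 0.4, 0.6, 3.0, 0.5)
    a = f.sample_fbb(params, 1000, np.random.default_rng(5))
    b = f.sample_fbb(params, 1000, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)
    assert a.min() >= 0 and a.max() <= 10
    pi = f.sample_fb(0.4, 0.6, 3.0, 0.5, 1000, np.random.default_rng(6))
    assert np.all((pi > 0) & (pi < 1))


def test_fbb_sampler_matches_exact_pmf(rng):
    params = f.FBBParams(10, 0.4, 0.6, 3.0, 0.5)
    draws = f.sample_fbb(params, 1_000_000, rng)
    emp = np.bincount(draws, minlength=11) / len(draws)
    exact = np.exp(f.fbb_log_pmf(np.arange(11), params))
    tv = 0.5 * np.abs(emp - exact).sum()
    assert tv < 0.005
    assert draws.mean() == pytest.approx(10 * 0.4, abs=0.02)


def test_zi_sampler_inflates_zeros(rng):
    base = lambda size, g: f.sample_bb(f.BBParams(20, 0.7, 5.0), size, g)
    y = f.sample_zi(0.4, base, 50_000, rng)
    expected = 0.4 + 0.6 * f.zero_prob_bb(f.BBParams(20, 0.7, 5.0))
    assert (y == 0).mean() == pytest.approx(expected, abs=0.01)
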