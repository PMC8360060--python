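"""Beta-binomial, flexible beta-binomial, and zero-inflated count distributions.

The flexible beta-binomial (FBB) arises by compounding a binomial with a
flexible beta (FB) mixing density: a structured two-component mixture of
betas sharing a precision ``phi`` but with distinct means ``lambda1 >
lambda2``.  The regression-friendly parameterization used throughout this
package is ``(mu, w, phi, p)``:

* ``mu``  — overall mean of the mixing density, ``E[pi]``;
* ``w``   — normalized distance between the two component means, in (0,1);
* ``phi`` — common precision of the beta components, > 0;
* ``p``   — mixing proportion of the upper component, in (0,1).

This space is variation independent (no cross-parameter constraints), and
the component means are recovered as

    lambda1 = mu + (1-p) * w * min(mu/p, (1-mu)/(1-p))
    lambda2 = mu -   p   * w * min(mu/p, (1-mu)/(1-p))

so ``lambda1 > lambda2`` holds by construction and ``p*lambda1 +
(1-p)*lambda2 = mu`` identically.  The beta-binomial (BB) is an inner
point of the family: ``FBB(n, mu=p0, w=1/(nu+1), phi=nu+1, p=p0)`` equals
``BB(n, p0, nu)`` in distribution.

All probability mass functions are evaluated in log space through
log-gamma, and mixtures are combined with log-sum-exp, so that large
trial counts never overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "BBParams",
    "FBBParams",
    "ZIParams",
    "bb_log_pmf",
    "fbb_log_pmf",
    "zi_log_pmf",
    "bb_moments",
    "fbb_moments",
    "icc_bb",
    "icc_fbb",
    "component_means",
    "m_factor",
    "zero_prob_bb",
    "zero_prob_fbb",
    "fb_log_pdf",
    "sample_bb",
    "sample_fb",
    "sample_fbb",
    "sample_zi",
]

#: guard distance from the boundary of open parameter intervals
DEFAULT_EPS = 1e-12


def _check_unit(value: float, name: str, eps: float = DEFAULT_EPS) -> float:
    value = float(value)
    if not (eps < value < 1.0 - eps):
        raise ValueError(f"{name} must lie strictly inside (0, 1); got {value!r}")
    return value


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not value > 0.0 or not np.isfinite(value):
        raise ValueError(f"{name} must be finite and > 0; got {value!r}")
    return value


def _check_trials(n) -> int:
    if n != int(n) or n < 0:
        raise ValueError(f"trial count n must be a non-negative integer; got {n!r}")
    return int(n)


def _check_counts(y, n: int) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        if not np.all(np.equal(np.mod(y, 1), 0)):
            raise ValueError("counts y must be integers")
        y = y.astype(np.int64)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError(f"counts y must lie in {{0, ..., {n}}}")
    return y


@dataclass(frozen=True)
class BBParams:
    """Beta-binomial parameters in mean-precision form.

    ``theta = 1/(phi+1)`` is both the overdispersion parameter and the
    intraclass correlation of the Bernoulli trials forming the count.
    """

    n: int
    mu: float
    phi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", _check_trials(self.n))
        object.__setattr__(self, "mu", _check_unit(self.mu, "mu"))
        object.__setattr__(self, "phi", _check_positive(self.phi, "phi"))

    @property
    def theta(self) -> float:
        return 1.0 / (self.phi + 1.0)


@dataclass(frozen=True)
class FBBParams:
    """Flexible beta-binomial parameters ``(n, mu, w, phi, p)``.

    The four continuous parameters are variation independent; the
    component means ``lambda1 > lambda2`` and the separation factor
    ``m(mu, p)`` are derived quantities.
    """

    n: int
    mu: float
    w: float
    phi: float
    p: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", _check_trials(self.n))
        object.__setattr__(self, "mu", _check_unit(self.mu, "mu"))
        object.__setattr__(self, "w", _check_unit(self.w, "w"))
        object.__setattr__(self, "phi", _check_positive(self.phi, "phi"))
        object.__setattr__(self, "p", _check_unit(self.p, "p"))

    @property
    def theta(self) -> float:
        return 1.0 / (self.phi + 1.0)

    @property
    def lambdas(self) -> tuple[float, float]:
        return component_means(self.mu, self.w, self.p)

    @property
    def m(self) -> float:
        return m_factor(self.mu, self.p)


@dataclass(frozen=True)
class ZIParams:
    """Zero-inflated parameters: inflation probability ``q`` plus a base law.

    ``base`` is either :class:`BBParams` (giving the ZIBB) or a
    ``(n, pi)`` tuple of binomial parameters (giving the ZIBin).
    """

    q: float
    base: Union[BBParams, tuple]

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _check_unit(self.q, "q"))


# ---------------------------------------------------------------------------
# log pmfs (internal kernels are vectorized and unvalidated; public wrappers
# validate and accept parameter objects)
# ---------------------------------------------------------------------------

def _log_binom_coef(n, y):
    return gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)


def _bb_logpmf_kernel(y, n, mu, phi):
    """Vectorized BB log pmf; arguments broadcast, no validation."""
    a = phi * mu
    b = phi * (1.0 - mu)
    return _log_binom_coef(n, y) + betaln(a + y, b + n - y) - betaln(a, b)


def _binom_logpmf_kernel(y, n, pi):
    logp = np.log(pi)
    log1mp = np.log1p(-pi)
    return _log_binom_coef(n, y) + y * logp + (n - y) * log1mp


def bb_log_pmf(y, params: BBParams) -> np.ndarray:
    """Log pmf of the beta-binomial, computed entirely through log-gamma.

    ``y`` may be a scalar or array of counts in ``{0, ..., n}``.
    """
    y = _check_counts(y, params.n)
    out = _bb_logpmf_kernel(y, params.n, params.mu, params.phi)
    return out if out.ndim else float(out)


def m_factor(mu: float, p: float) -> float:
    """Separation bound ``m(mu, p)``: the smaller of two reciprocal odds ratios.

    Equals 1 iff ``mu == p`` and is symmetric in its arguments.
    """
    mu = _check_unit(mu, "mu")
    p = _check_unit(p, "p")
    r = (mu * (1.0 - p)) / (p * (1.0 - mu))
    return min(r, 1.0 / r)


def component_means(mu: float, w: float, p: float) -> tuple[float, float]:
    """Component means ``(lambda1, lambda2)`` of the FB mixing density.

    Satisfy ``lambda1 > lambda2`` and ``p*lambda1 + (1-p)*lambda2 = mu``.
    """
    mu = _check_unit(mu, "mu")
    w = _check_unit(w, "w")
    p = _check_unit(p, "p")
    d = min(mu / p, (1.0 - mu) / (1.0 - p))
    return mu + (1.0 - p) * w * d, mu - p * w * d


def _fbb_logpmf_kernel(y, n, mu, w, phi, p):
    d = np.minimum(mu / p, (1.0 - mu) / (1.0 - p))
    lam1 = mu + (1.0 - p) * w * d
    lam2 = mu - p * w * d
    return np.logaddexp(
        np.log(p) + _bb_logpmf_kernel(y, n, lam1, phi),
        np.log1p(-p) + _bb_logpmf_kernel(y, n, lam2, phi),
    )


def fbb_log_pmf(y, params: FBBParams) -> np.ndarray:
    """Log pmf of the flexible beta-binomial (log-sum-exp of two BB terms)."""
    y = _check_counts(y, params.n)
    out = _fbb_logpmf_kernel(y, params.n, params.mu, params.w, params.phi, params.p)
    return out if out.ndim else float(out)


def zi_log_pmf(y, q: float, base_log_pmf: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Log pmf of a zero-inflated distribution.

    ``base_log_pmf`` maps counts to the log pmf of the uninflated law.
    At zero the point mass and the base mass are combined with a stable
    log-sum-exp; elsewhere the base mass is thinned by ``1 - q``.
    """
    q = _check_unit(q, "q")
    y = np.asarray(y)
    base = np.asarray(base_log_pmf(y), dtype=float)
    out = np.log1p(-q) + base
    at_zero = y == 0
    if np.any(at_zero):
        zero_val = np.logaddexp(np.log(q), np.log1p(-q) + np.asarray(base_log_pmf(np.zeros_like(y)), dtype=float))
        out = np.where(at_zero, zero_val, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# moments and intraclass correlation
# ---------------------------------------------------------------------------

def bb_moments(params: BBParams) -> tuple[float, float]:
    """Mean ``n*mu`` and variance ``n*mu*(1-mu)*[1 + (n-1)/(phi+1)]``."""
    n, mu, phi = params.n, params.mu, params.phi
    mean = n * mu
    var = n * mu * (1.0 - mu) * (1.0 + (n - 1.0) / (phi + 1.0))
    return mean, var


def fbb_moments(params: FBBParams) -> tuple[float, float]:
    """Mean and variance of the FBB.

    The variance adds a cluster term ``(n-1) * phi/(phi+1) * w^2 * m(mu,p)``
    on top of the matched BB variance, and can equivalently be written as
    ``n*mu*(1-mu)*(1 + (n-1)*rho_FBB)``.
    """
    n, mu, w, phi, p = params.n, params.mu, params.w, params.phi, params.p
    mean = n * mu
    extra = (n - 1.0) * phi / (phi + 1.0) * w ** 2 * m_factor(mu, p)
    var = n * mu * (1.0 - mu) * (1.0 + (n - 1.0) / (phi + 1.0) + extra)
    return mean, var


def icc_bb(phi: float) -> float:
    """Intraclass correlation of the BB: ``1/(phi+1)``."""
    phi = _check_positive(phi, "phi")
    return 1.0 / (phi + 1.0)


def icc_fbb(mu: float, w: float, phi: float, p: float) -> float:
    """Intraclass correlation of the FBB: ``theta + (1-theta)*w^2*m(mu,p)``.

    Strictly increasing in ``w``, symmetric in ``(mu, p)``, and collapsing
    to the BB value ``theta`` as ``w -> 0``, ``p -> 0`` or ``p -> 1``.
    """
    w = _check_unit(w, "w")
    theta = icc_bb(phi)
    return theta + (1.0 - theta) * w ** 2 * m_factor(mu, p)


# ---------------------------------------------------------------------------
# zero probabilities
# ---------------------------------------------------------------------------

def _log_rising_factorial(x, n):
    # x^[n] = Gamma(x+n)/Gamma(x), in log space
    return gammaln(x + n) - gammaln(x)


def zero_prob_bb(params: BBParams) -> float:
    """P(Y = 0) under the BB, via log rising factorials."""
    n, mu, phi = params.n, params.mu, params.phi
    if n < 1:
        raise ValueError("zero probability requires n >= 1")
    return float(np.exp(_log_rising_factorial(phi * (1.0 - mu), n) - _log_rising_factorial(phi, n)))


def zero_prob_fbb(params: FBBParams) -> float:
    """P(Y = 0) under the FBB: the p-mixture of the component BB values."""
    lam1, lam2 = params.lambdas
    z1 = zero_prob_bb(BBParams(params.n, lam1, params.phi))
    z2 = zero_prob_bb(BBParams(params.n, lam2, params.phi))
    return params.p * z1 + (1.0 - params.p) * z2


# ---------------------------------------------------------------------------
# mixing density and samplers
# ---------------------------------------------------------------------------

def fb_log_pdf(pi, mu: float, w: float, phi: float, p: float) -> np.ndarray:
    """Log density of the flexible beta mixing distribution on (0, 1)."""
    lam1, lam2 = component_means(mu, w, p)
    pi = np.asarray(pi, dtype=float)

    def beta_logpdf(x, lam):
        a, b = phi * lam, phi * (1.0 - lam)
        return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)

    out = np.logaddexp(np.log(p) + beta_logpdf(pi, lam1), np.log1p(-p) + beta_logpdf(pi, lam2))
    return out if out.ndim else float(out)


def sample_bb(params: BBParams, size, rng: np.random.Generator) -> np.ndarray:
    """Draw BB counts via the beta-then-binomial compound construction."""
    pi = rng.beta(params.phi * params.mu, params.phi * (1.0 - params.mu), size=size)
    return rng.binomial(params.n, pi)


def sample_fb(mu: float, w: float, phi: float, p: float, size, rng: np.random.Generator) -> np.ndarray:
    """Draw from the flexible beta: component indicator, then a beta draw."""
    lam1, lam2 = component_means(mu, w, p)
    upper = rng.random(size) < p
    lam = np.where(upper, lam1, lam2)
    return rng.beta(phi * lam, phi * (1.0 - lam))


def sample_fbb(params: FBBParams, size, rng: np.random.Generator) -> np.ndarray:
    """Draw FBB counts: component indicator, beta success probability, binomial."""
    pi = sample_fb(params.mu, params.w, params.phi, params.p, size, rng)
    return rng.binomial(params.n, pi)


def sample_zi(q: float, base_sampler: Callable[..., np.ndarray], size, rng: np.random.Generator) -> np.ndarray:
    """Draw zero-inflated counts: base draws zeroed with probability ``q``."""
    q = _check_unit(q, "q")
    y = np.asarray(base_sampler(size, rng))
    inflate = rng.random(size) < q
    return np.where(inflate, 0, y)
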