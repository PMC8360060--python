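"""Bayesian regression models for bounded counts.

Five families share one interface: binomial (``binomial``), beta-binomial
(``beta-binomial``), flexible beta-binomial (``fbb``), and the
zero-inflated binomial / beta-binomial (``zi-binomial``,
``zi-beta-binomial``).  Each links the per-observation mean proportion to
covariates through ``g(mu_i) = x_i' beta`` (logit by default) and adds its
own global shape parameters:

=================  =======================================
family             extra parameters (natural scale)
=================  =======================================
binomial           —
beta-binomial      phi
fbb                w, phi, p
zi-binomial        q
zi-beta-binomial   phi, q
=================  =======================================

Priors follow a weakly informative default: independent normals with a
large standard deviation on the regression coefficients, and Uniform(0,1)
on ``theta = 1/(phi+1)``, ``w``, ``p`` and ``q``.  Posterior sampling is
performed on an unconstrained scale (identity for ``beta``, logit for the
unit-interval parameters, with ``phi`` sampled through ``theta``), so the
boundary of the parameter space is never reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .fbb_core import _bb_logpmf_kernel, _binom_logpmf_kernel, _fbb_logpmf_kernel

__all__ = [
    "FAMILIES",
    "LINKS",
    "Link",
    "PriorSpec",
    "RegressionData",
    "RegressionModel",
    "linear_predictor_mean",
]

_MU_EPS = 1e-10


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Link:
    """Strictly monotone, twice differentiable map from (0,1) to the reals."""

    name: str

    def forward(self, mu):
        mu = np.asarray(mu, dtype=float)
        if self.name == "logit":
            return np.log(mu) - np.log1p(-mu)
        if self.name == "probit":
            return ndtri(mu)
        if self.name == "cloglog":
            return np.log(-np.log1p(-mu))
        raise ValueError(f"unknown link {self.name!r}")

    def inverse(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.name == "logit":
            mu = expit(eta)
        elif self.name == "probit":
            mu = ndtr(eta)
        elif self.name == "cloglog":
            mu = -np.expm1(-np.exp(np.clip(eta, None, 30.0)))
        else:
            raise ValueError(f"unknown link {self.name!r}")
        return np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)


LINKS = {name: Link(name) for name in ("logit", "probit", "cloglog")}


def linear_predictor_mean(beta, X, link: Link = LINKS["logit"]) -> np.ndarray:
    """Mean proportions ``mu = g^{-1}(X beta)``, clamped strictly inside (0,1).

    ``beta`` may be a single vector ``(K+1,)`` or a stack ``(M, K+1)``; the
    result then has shape ``(N,)`` or ``(M, N)``.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    if beta.shape[-1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: beta has {beta.shape[-1]} coefficients, "
            f"design matrix has {X.shape[1]} columns"
        )
    return link.inverse(beta @ X.T)


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------

@dataclass
class RegressionData:
    """Observed counts ``y`` out of ``n`` trials with design matrix ``X``.

    ``X`` must carry the intercept as its first column.  A rank-deficient
    design raises a warning (not an error) at construction.
    """

    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    column_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.n = np.asarray(self.n)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not (len(self.y) == len(self.n) == self.X.shape[0]):
            raise ValueError("y, n and X must have equal numbers of rows")
        for arr, name in ((self.y, "y"), (self.n, "n")):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} must contain integers")
        self.y = self.y.astype(np.int64)
        self.n = self.n.astype(np.int64)
        if np.any(self.y < 0) or np.any(self.y > self.n):
            bad = int(np.flatnonzero((self.y < 0) | (self.y > self.n))[0])
            raise ValueError(f"row {bad}: y must satisfy 0 <= y <= n")
        if self.X.shape[0] > 0 and np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            warnings.warn("design matrix X is not of full column rank", stacklevel=2)
        if self.column_names is None:
            self.column_names = ["intercept"] + [f"x{j}" for j in range(1, self.X.shape[1])]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors: ``beta_j ~ N(0, beta_sd^2)``; Uniform(0,1) on
    ``theta = 1/(phi+1)``, ``w``, ``p`` and ``q``."""

    beta_sd: float = 100.0

    def __post_init__(self) -> None:
        if not self.beta_sd > 0:
            raise ValueError("beta_sd must be > 0")


# extra-parameter kinds: "phi" is positive, sampled through theta=1/(phi+1);
# "unit" lives on (0,1) directly
_FAMILY_EXTRAS = {
    "binomial": (),
    "beta-binomial": (("phi", "phi"),),
    "fbb": (("w", "unit"), ("phi", "phi"), ("p", "unit")),
    "zi-binomial": (("q", "unit"),),
    "zi-beta-binomial": (("phi", "phi"), ("q", "unit")),
}
FAMILIES = tuple(_FAMILY_EXTRAS)


@dataclass(frozen=True)
class RegressionModel:
    """A family plus link plus priors; together with data this defines a
    joint log posterior over the natural parameter vector
    ``eta = (beta_0..beta_K, extras...)``."""

    family: str
    link: Link = LINKS["logit"]
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_EXTRAS:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def extra_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in _FAMILY_EXTRAS[self.family])

    def param_names(self, data: RegressionData) -> list[str]:
        return [f"beta{j}" for j in range(data.n_coef)] + list(self.extra_names)

    def dim(self, data: RegressionData) -> int:
        return data.n_coef + len(self.extra_names)

    def split(self, eta: np.ndarray, data: RegressionData):
        """Split a natural parameter stack into (beta, {extra: column})."""
        eta = np.atleast_2d(np.asarray(eta, dtype=float))
        k = data.n_coef
        beta = eta[:, :k]
        extras = {
            name: eta[:, k + j : k + j + 1]
            for j, (name, _) in enumerate(_FAMILY_EXTRAS[self.family])
        }
        return beta, extras

    # -- unconstrained parameterization --------------------------------------

    def to_unconstrained(self, eta: np.ndarray, data: RegressionData) -> np.ndarray:
        eta = np.atleast_2d(np.asarray(eta, dtype=float))
        z = eta.copy()
        k = data.n_coef
        for j, (_, kind) in enumerate(_FAMILY_EXTRAS[self.family]):
            v = eta[:, k + j]
            if kind == "phi":
                v = 1.0 / (v + 1.0)  # theta
            z[:, k + j] = np.log(v) - np.log1p(-v)
        return z

    def to_natural(self, z: np.ndarray, data: RegressionData) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        eta = z.copy()
        k = data.n_coef
        for j, (_, kind) in enumerate(_FAMILY_EXTRAS[self.family]):
            v = expit(z[:, k + j])
            v = np.clip(v, 1e-14, 1.0 - 1e-14)
            if kind == "phi":
                v = 1.0 / v - 1.0  # phi
            eta[:, k + j] = v
        return eta

    # -- log densities --------------------------------------------------------

    def loglik_matrix(self, eta: np.ndarray, data: RegressionData) -> np.ndarray:
        """Per-observation log likelihood for a stack of natural parameter
        vectors: shape ``(M, N)`` for ``eta`` of shape ``(M, D)``."""
        beta, extras = self.split(eta, data)
        mu = linear_predictor_mean(beta, data.X, self.link)
        y, n = data.y, data.n
        fam = self.family
        if fam == "binomial":
            return _binom_logpmf_kernel(y, n, mu)
        if fam == "beta-binomial":
            return _bb_logpmf_kernel(y, n, mu, extras["phi"])
        if fam == "fbb":
            return _fbb_logpmf_kernel(y, n, mu, extras["w"], extras["phi"], extras["p"])
        # zero-inflated families
        q = extras["q"]
        if fam == "zi-binomial":
            base = _binom_logpmf_kernel(y, n, mu)
            base0 = _binom_logpmf_kernel(0, n, mu)
        else:
            base = _bb_logpmf_kernel(y, n, mu, extras["phi"])
            base0 = _bb_logpmf_kernel(0, n, mu, extras["phi"])
        nonzero = np.log1p(-q) + base
        zero = np.logaddexp(np.log(q), np.log1p(-q) + base0)
        return np.where(y == 0, zero, nonzero)

    def log_likelihood(self, data: RegressionData, eta) -> tuple[float, np.ndarray]:
        """Total log likelihood and the per-observation vector at ``eta``.

        Invalid parameter values yield ``-inf`` (a rejected state), never an
        exception, so samplers can probe freely.
        """
        eta = np.asarray(eta, dtype=float)
        if not self._in_support(eta, None):
            return -np.inf, np.full(data.n_obs, -np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            vec = self.loglik_matrix(eta[None, :], data)[0]
        if not np.all(np.isfinite(vec)):
            return -np.inf, np.full(data.n_obs, -np.inf)
        return float(vec.sum()), vec

    def _in_support(self, eta: np.ndarray, data) -> bool:
        if not np.all(np.isfinite(eta)):
            return False
        extras = _FAMILY_EXTRAS[self.family]
        if extras:
            tail = eta[-len(extras):]
            for (_, kind), v in zip(extras, tail):
                if kind == "phi" and not v > 0:
                    return False
                if kind == "unit" and not (0.0 < v < 1.0):
                    return False
        return True

    def log_prior(self, eta: np.ndarray, data: RegressionData) -> float:
        """Log prior density in the natural parameterization.

        The Uniform(0,1) prior on ``theta`` induces density
        ``1/(phi+1)^2`` on ``phi``; the unit-interval parameters carry a
        flat prior on their support.
        """
        eta = np.asarray(eta, dtype=float)
        if not self._in_support(eta, data):
            return -np.inf
        k = data.n_coef
        beta = eta[:k]
        sd = self.priors.beta_sd
        lp = float(-0.5 * np.sum((beta / sd) ** 2) - k * np.log(sd * np.sqrt(2.0 * np.pi)))
        for j, (_, kind) in enumerate(_FAMILY_EXTRAS[self.family]):
            if kind == "phi":
                lp += -2.0 * np.log1p(eta[k + j])
        return lp

    def log_posterior(self, data: RegressionData, eta) -> float:
        """Unnormalized log posterior in the natural parameterization."""
        lp = self.log_prior(np.asarray(eta, dtype=float), data)
        if not np.isfinite(lp):
            return -np.inf
        total, _ = self.log_likelihood(data, eta)
        return total + lp

    def log_posterior_unconstrained(self, z: np.ndarray, data: RegressionData) -> np.ndarray:
        """Vectorized log posterior on the unconstrained scale, including the
        log-Jacobian of the logit transforms.  ``z`` has shape ``(M, D)``;
        returns ``(M,)``.  Non-finite rows map to ``-inf``."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        eta = self.to_natural(z, data)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = self.loglik_matrix(eta, data).sum(axis=1)
        k = data.n_coef
        sd = self.priors.beta_sd
        lp = ll - 0.5 * np.sum((eta[:, :k] / sd) ** 2, axis=1) - k * np.log(sd * np.sqrt(2.0 * np.pi))
        # Uniform(0,1) priors on logit scale: log v + log(1-v) per parameter,
        # which is -u - 2*log(1+exp(-u)) = log sigmoid(u) + log sigmoid(-u)
        for j in range(len(_FAMILY_EXTRAS[self.family])):
            u = z[:, k + j]
            lp += -np.logaddexp(0.0, -u) - np.logaddexp(0.0, u)
        return np.where(np.isfinite(lp), lp, -np.inf)

    # -- posterior predictive sampling ----------------------------------------

    def replicate(self, eta: np.ndarray, data: RegressionData, rng: np.random.Generator) -> np.ndarray:
        """Draw replicated responses, one ``(N,)`` row per parameter vector
        in the ``(M, D)`` stack ``eta``."""
        beta, extras = self.split(eta, data)
        mu = linear_predictor_mean(beta, data.X, self.link)  # (M, N)
        n = np.broadcast_to(data.n, mu.shape)
        fam = self.family
        if fam == "binomial":
            return rng.binomial(n, mu)
        if fam == "beta-binomial":
            pi = rng.beta(extras["phi"] * mu, extras["phi"] * (1.0 - mu))
            return rng.binomial(n, pi)
        if fam == "fbb":
            w, phi, p = extras["w"], extras["phi"], extras["p"]
            d = np.minimum(mu / p, (1.0 - mu) / (1.0 - p))
            lam1 = mu + (1.0 - p) * w * d
            lam2 = mu - p * w * d
            lam = np.where(rng.random(mu.shape) < p, lam1, lam2)
            pi = rng.beta(phi * lam, phi * (1.0 - lam))
            return rng.binomial(n, pi)
        if fam == "zi-binomial":
            y = rng.binomial(n, mu)
        else:  # zi-beta-binomial
            pi = rng.beta(extras["phi"] * mu, extras["phi"] * (1.0 - mu))
            y = rng.binomial(n, pi)
        return np.where(rng.random(mu.shape) < extras["q"], 0, y)
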