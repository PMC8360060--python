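"""Bayesian model-fit diagnostics: WAIC, CPO, posterior predictive checks.

All quantities are computed from the ``B x N`` per-draw per-observation
log-likelihood matrix retained by :func:`fbbreg.inference.fit`, so no
refitting is ever needed.

* WAIC (deviance scale): ``-2 * (lppd - p_waic)`` with the pointwise
  log predictive density estimated by column-wise log-mean-exp and the
  effective number of parameters by the column-wise sample variance of
  the log likelihoods.  Lower is better.
* CPO: the leave-one-out predictive density of each observation,
  estimated by the harmonic mean of its per-draw likelihoods; small
  values flag observations the model finds surprising.
* Posterior predictive checks: a discrepancy statistic is compared
  between observed data and datasets replicated from the fitted model;
  the resulting p-value is ideally near 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorSample

__all__ = [
    "WaicResult",
    "PpcResult",
    "SelectionResult",
    "waic",
    "loo",
    "cpo",
    "posterior_predictive_replicates",
    "ppc",
    "ppc_pvalue",
    "model_selection",
    "DISCREPANCIES",
]

#: observations with natural-scale CPO at or below this default are
#: flagged as outlier candidates
CPO_OUTLIER_THRESHOLD = 0.01


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float

    def __post_init__(self):
        assert self.p_waic >= 0.0
        assert np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic))


def waic(loglik: np.ndarray) -> WaicResult:
    """Watanabe-Akaike information criterion on the deviance scale.

    ``loglik`` is the ``B x N`` matrix of per-draw per-observation log
    likelihoods.  Requires ``B >= 2`` (the complexity penalty is a
    sample variance over draws).
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2:
        raise ValueError("loglik must be a B x N matrix")
    b = loglik.shape[0]
    if b < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    lppd = float(np.sum(logsumexp(loglik, axis=0) - np.log(b)))
    p_waic = float(np.sum(loglik.var(axis=0, ddof=1)))
    return WaicResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic))


def cpo(loglik: np.ndarray, log_scale: bool = False) -> np.ndarray:
    """Conditional predictive ordinates, one per observation.

    Estimated as the harmonic mean of the per-draw likelihoods,
    ``CPO_i = B / sum_b exp(-ll_bi)``, evaluated stably through
    log-sum-exp.  An observation that is impossible under any retained
    draw (a ``-inf`` entry) gets CPO 0 with a warning.
    """
    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim == 1:
        loglik = loglik[:, None]
    b = loglik.shape[0]
    impossible = np.isneginf(loglik).any(axis=0)
    if impossible.any():
        warnings.warn(
            f"{int(impossible.sum())} observation(s) impossible under some draw; CPO set to 0",
            stacklevel=2,
        )
    with np.errstate(over="ignore"):
        log_cpo = np.log(b) - logsumexp(-loglik, axis=0)
    log_cpo = np.where(impossible, -np.inf, log_cpo)
    return log_cpo if log_scale else np.exp(log_cpo)


def loo(loglik: np.ndarray) -> float:
    """Leave-one-out cross-validation estimate on the deviance scale,
    ``-2 * sum_i log CPO_i``; close to WAIC for well-behaved fits."""
    return float(-2.0 * np.sum(cpo(loglik, log_scale=True)))


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

DISCREPANCIES = ("mean", "variance", "zero_prop", "deviance")


def _stat(name: str, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if name == "mean":
        return y.mean(axis=-1)
    if name == "variance":
        return y.var(axis=-1, ddof=1)
    if name == "zero_prop":
        return (y == 0).mean(axis=-1)
    raise ValueError(f"unknown discrepancy {name!r}")


@dataclass(frozen=True)
class PpcResult:
    discrepancy: str
    observed: np.ndarray  # scalar, or per-draw for parameter-dependent measures
    replicated: np.ndarray  # one value per retained draw used
    p_value: float

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0


def posterior_predictive_replicates(
    sample: PosteriorSample,
    rng: np.random.Generator,
    max_draws: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicated response vectors, one per retained draw.

    Returns ``(indices, y_rep)`` where ``y_rep`` has shape ``(M, N)`` and
    ``indices`` are the rows of ``sample.draws`` used.  ``max_draws``
    caps memory by thinning the draws evenly; pass ``None`` to use all.
    """
    b = sample.n_draws
    if max_draws is not None and max_draws < b:
        idx = np.linspace(0, b - 1, max_draws).round().astype(int)
    else:
        idx = np.arange(b)
    eta = sample.draws[idx]
    y_rep = sample.model.replicate(eta, sample.data, rng)
    return idx, y_rep


def ppc_pvalue(discrepancy: str, observed, replicated) -> PpcResult:
    """Posterior predictive p-value: fraction of replicates whose
    discrepancy meets or exceeds the observed one."""
    observed = np.asarray(observed, dtype=float)
    replicated = np.asarray(replicated, dtype=float)
    p = float(np.mean(replicated >= observed))
    return PpcResult(discrepancy=discrepancy, observed=observed, replicated=replicated, p_value=p)


def ppc(
    sample: PosteriorSample,
    discrepancies: Sequence[str] = DISCREPANCIES,
    rng: Optional[np.random.Generator] = None,
    max_draws: Optional[int] = 1000,
) -> Dict[str, PpcResult]:
    """Run posterior predictive checks for the requested discrepancies.

    ``mean``, ``variance`` and ``zero_prop`` compare plain statistics of
    the response; ``deviance`` is parameter dependent, comparing
    ``-2 * sum_i log f(y_i; eta_b)`` with the same quantity on the
    replicate drawn at ``eta_b``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    idx, y_rep = posterior_predictive_replicates(sample, rng, max_draws=max_draws)
    out: Dict[str, PpcResult] = {}
    for name in discrepancies:
        if name == "deviance":
            obs_dev = -2.0 * sample.loglik[idx].sum(axis=1)
            ll = _replicate_loglik(sample.model, sample.data, sample.draws[idx], y_rep)
            rep_dev = -2.0 * ll.sum(axis=1)
            out[name] = ppc_pvalue(name, obs_dev, rep_dev)
        else:
            obs = _stat(name, sample.data.y)
            rep = _stat(name, y_rep)
            out[name] = ppc_pvalue(name, obs, rep)
    return out


def _replicate_loglik(model, data, eta, y_rep):
    """Per-observation loglik of replicated responses at their own draws."""
    import copy

    data_rep = copy.copy(data)
    lls = np.empty((eta.shape[0], data.n_obs))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(eta.shape[0]):
            data_rep.y = y_rep[i]
            lls[i] = model.loglik_matrix(eta[i : i + 1], data_rep)[0]
    return lls


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    """WAIC-based ranking with pairwise selection proportions.

    ``pairwise.loc[a, b]`` is the fraction of replications in which model
    ``a`` attains strictly lower WAIC than model ``b``; exact ties are
    counted separately in ``ties.loc[a, b]`` and never silently awarded.
    """

    mean_waic: pd.Series
    ranking: list[str]
    pairwise: pd.DataFrame
    ties: pd.DataFrame


def model_selection(waic_per_model: Dict[str, Iterable[float]]) -> SelectionResult:
    """Rank models by mean WAIC (lower is better) across replications."""
    table = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in waic_per_model.items()}
    lengths = {len(v) for v in table.values()}
    if len(lengths) != 1:
        raise ValueError("all models must report the same number of replications")
    names = list(table)
    means = pd.Series({k: v.mean() for k, v in table.items()}, name="mean_waic")
    ranking = means.sort_values().index.tolist()
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    ties = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        for b_ in names:
            if a == b_:
                continue
            pairwise.loc[a, b_] = float(np.mean(table[a] < table[b_]))
            ties.loc[a, b_] = float(np.mean(table[a] == table[b_]))
    return SelectionResult(mean_waic=means, ranking=ranking, pairwise=pairwise, ties=ties)
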