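"""MCMC convergence diagnostics and PSIS leave-one-out cross-validation.

``rhat`` and ``ess`` follow the standard split-chain / autocorrelation
definitions (Gelman et al. 2013; Geyer initial monotone sequence).
``loo_psis`` delegates the Pareto-smoothed importance sampling machinery
to ArviZ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["LooResult", "ess", "loo_psis", "rhat"]


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(chains, n) -> (2*chains, n//2), dropping an odd trailing draw."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must have shape (chains, iterations)")
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    n = draws.shape[1] // 2 * 2
    half = n // 2
    return np.concatenate([draws[:, :half], draws[:, half:n]], axis=0)


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    split = _split_chains(draws)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance function via FFT."""
    n = x.size
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conjugate(f))[:n].real / n
    return acov


def ess(draws: np.ndarray) -> float:
    """Effective sample size from split chains.

    Combines per-chain autocovariances (Stan's formulation) and
    truncates the autocorrelation sum by Geyer's initial monotone
    positive sequence.
    """
    split = _split_chains(draws)
    m, n = split.shape
    if n < 4:
        raise ValueError("need at least 4 iterations per split chain")
    acovs = np.stack([_autocovariance(chain) for chain in split])
    chain_means = split.mean(axis=1)
    mean_var = acovs[:, 0].mean() * n / (n - 1)
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += chain_means.var(ddof=1)
    if var_plus == 0:
        return float(m * n)

    rho = np.empty(n)
    rho[0] = 1.0
    for t in range(1, n):
        rho[t] = 1.0 - (mean_var - acovs[:, t].mean()) / var_plus

    # Geyer: sum consecutive pairs (rho_0+rho_1), (rho_2+rho_3), ... while
    # positive, enforcing a monotone decreasing sequence of pair sums.
    prev_pair = np.inf
    pair_total = 0.0
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        pair_total += pair
        t += 2
    tau = max(-1.0 + 2.0 * pair_total, 1.0 / np.log10(m * n + 10))
    return float(min(m * n / tau, m * n))


@dataclass
class LooResult:
    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        """Observations with unreliable importance ratios (k > 0.7)."""
        return self.pareto_k > 0.7


def loo_psis(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from pointwise log-likelihood draws.

    ``loglik`` has shape ``(chains, draws, n_obs)``.
    """
    import arviz as az

    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 3:
        raise ValueError("loglik must have shape (chains, draws, n_obs)")
    idata = az.from_dict(log_likelihood={"y": loglik})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # relative efficiency defaults to 1 when no posterior draws accompany
        # the likelihood matrix; conservative for well-mixed chains
        result = az.loo(idata, pointwise=True, reff=1.0)
    return LooResult(
        elpd=float(result.elpd_loo),
        se=float(result.se),
        pointwise=np.asarray(result.loo_i.values, dtype=float),
        pareto_k=np.asarray(result.pareto_k.values, dtype=float),
    )
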