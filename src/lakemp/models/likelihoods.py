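"""Likelihoods for the two survey models.

* censored log-normal mixed model for harmonised net-tow concentrations
  (zeros carry a per-record detection limit and contribute the
  log-normal mass below it; study intercepts are exchangeable normal);
* Bernoulli / zero-truncated-Poisson hurdle model for per-lake
  microparticle counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, log_ndtr

__all__ = [
    "CensoredLnmData",
    "CensoredLnmParams",
    "HurdleData",
    "HurdleParams",
    "cens_lnm_loglik",
    "hurdle_loglik",
    "trunc_pois_logpmf",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class CensoredLnmData:
    """Per-tow observations; ``y == 0`` marks a censored record.

    A concentration exactly at its detection limit counts as observed.
    """

    y: np.ndarray  # particles m^-3, >= 0
    habitat_idx: np.ndarray  # int codes 0..H-1
    mesh_std: np.ndarray  # standardised mesh size
    study_idx: np.ndarray  # int codes 0..S-1
    detection_limit: np.ndarray  # particles m^-3, > 0
    habitat_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.habitat_idx = np.asarray(self.habitat_idx, dtype=int)
        self.mesh_std = np.asarray(self.mesh_std, dtype=float)
        self.study_idx = np.asarray(self.study_idx, dtype=int)
        self.detection_limit = np.asarray(self.detection_limit, dtype=float)
        if (self.y < 0).any():
            raise ValueError("concentrations cannot be negative")
        if (self.detection_limit <= 0).any():
            raise ValueError("detection limits must be positive")
        if not self.habitat_labels:
            self.habitat_labels = [f"habitat_{i}" for i in range(self.n_habitats)]

    @property
    def n_habitats(self) -> int:
        return int(self.habitat_idx.max()) + 1

    @property
    def n_studies(self) -> int:
        return int(self.study_idx.max()) + 1

    @property
    def censored(self) -> np.ndarray:
        return self.y == 0


@dataclass
class CensoredLnmParams:
    alpha: np.ndarray  # habitat means, log scale
    beta_mesh: float
    u: np.ndarray  # study intercepts
    sigma_study: float
    sigma: float


def cens_lnm_loglik(params: CensoredLnmParams, data: CensoredLnmData) -> float:
    """Joint log density of observations and study intercepts.

    Uncensored tows contribute the log-normal density at ``y``; censored
    tows the log of the log-normal mass below their detection limit;
    study intercepts their zero-mean normal density.
    """
    if params.sigma <= 0 or params.sigma_study < 0:
        return -np.inf
    alpha = np.asarray(params.alpha, dtype=float)
    u = np.asarray(params.u, dtype=float)
    mu = alpha[data.habitat_idx] + params.beta_mesh * data.mesh_std
    if u.size:
        mu = mu + u[data.study_idx]
    cens = data.censored
    total = 0.0
    if (~cens).any():
        y = data.y[~cens]
        z = (np.log(y) - mu[~cens]) / params.sigma
        total += float(
            np.sum(-np.log(y) - np.log(params.sigma) - 0.5 * _LOG_2PI - 0.5 * z**2)
        )
    if cens.any():
        z = (np.log(data.detection_limit[cens]) - mu[cens]) / params.sigma
        total += float(np.sum(log_ndtr(z)))
    if u.size:
        if params.sigma_study == 0:
            if np.any(u != 0):
                return -np.inf
        else:
            zu = u / params.sigma_study
            total += float(
                np.sum(-np.log(params.sigma_study) - 0.5 * _LOG_2PI - 0.5 * zu**2)
            )
    return total


def trunc_pois_logpmf(k, lam) -> np.ndarray | float:
    """Zero-truncated Poisson log pmf: ``k ln(lam) - lam - ln(1-e^-lam) - ln k!``."""
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 1) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("zero-truncated Poisson is defined for integer k >= 1")
    if np.any(lam_arr <= 0):
        raise ValueError("lam must be positive")
    k_arr = k_arr.astype(float)
    # log(1 - e^-lam) via expm1 for small-lam accuracy
    log_norm = np.log(-np.expm1(-lam_arr))
    out = k_arr * np.log(lam_arr) - lam_arr - log_norm - gammaln(k_arr + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class HurdleData:
    """Per-lake counts and a standardised predictor matrix.

    ``volume_m3`` is the constant tow volume used to report
    concentrations; it is a fixed divisor, not a model offset.
    """

    counts: np.ndarray
    X: np.ndarray  # n x p, standardised columns
    volume_m3: float = 7.1
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be non-negative integers")
        if self.X.shape[0] != self.counts.size:
            raise ValueError("X rows must match the number of counts")
        if self.volume_m3 <= 0:
            raise ValueError("tow volume must be positive")
        if not self.predictor_names:
            self.predictor_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.counts.size

    @property
    def concentrations(self) -> np.ndarray:
        return self.counts / self.volume_m3


@dataclass
class HurdleParams:
    pi: float  # detection probability
    beta0: float  # intercept, log count scale
    beta: np.ndarray  # predictor coefficients


_ETA_CLIP = 30.0


def hurdle_loglik(
    params: HurdleParams,
    data: HurdleData,
    truncated: bool = True,
) -> float:
    """Hurdle log-likelihood.

    Zeros contribute ``ln(1 - pi)``, positives ``ln(pi)`` plus the
    zero-truncated Poisson log pmf at ``lam_i = exp(beta0 + x_i' beta)``.
    With ``truncated=False`` and ``pi == 1`` the model collapses to plain
    Poisson regression (used for cross-checks against standard GLMs).
    """
    beta = np.asarray(params.beta, dtype=float)
    eta = np.clip(params.beta0 + data.X @ beta, -_ETA_CLIP, _ETA_CLIP)
    lam = np.exp(eta)
    k = data.counts.astype(float)
    if not truncated and params.pi == 1.0:
        return float(np.sum(k * eta - lam - gammaln(k + 1.0)))
    if not 0.0 < params.pi < 1.0:
        return -np.inf
    zeros = data.counts == 0
    total = float(zeros.sum()) * np.log(1.0 - params.pi)
    pos = ~zeros
    if pos.any():
        total += float(pos.sum()) * np.log(params.pi)
        if truncated:
            total += float(np.sum(trunc_pois_logpmf(data.counts[pos], lam[pos])))
        else:
            total += float(
                np.sum(k[pos] * eta[pos] - lam[pos] - gammaln(k[pos] + 1.0))
            )
    return total
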