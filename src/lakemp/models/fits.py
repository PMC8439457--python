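"""Posterior fitting, summaries, and effect curves for both survey models.

Default priors are weakly informative on the standardised scale:
Normal(0, 2.5) for location coefficients, half-Normal(0, 2.5) for
standard deviations, Beta(1, 1) for the detection probability. All are
overridable through :class:`PriorConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .. import towdb as towdb_mod
from ..emissions import cube_root
from ..limnoassays import standardize
from .diagnostics import ess, rhat
from .likelihoods import (
    CensoredLnmData,
    CensoredLnmParams,
    HurdleData,
    HurdleParams,
    cens_lnm_loglik,
    hurdle_loglik,
    trunc_pois_logpmf,
)
from .sampler import MCMCConfig, run_chains

__all__ = [
    "EffectCurve",
    "PosteriorFit",
    "PriorConfig",
    "bayes_r2",
    "build_cens_lnm_data",
    "build_hurdle_data",
    "fit_cens_lnm",
    "fit_hurdle",
    "habitat_contrast",
    "habitat_contrasts",
    "marginal_effect",
    "pointwise_loglik",
]

RHAT_GATE = 1.01
ESS_GATE = 800.0

HURDLE_PREDICTORS = [
    "plastic_input_cbrt",
    "wwtw_load",
    "forest_prop",
    "urban_prop",
    "respiration_cbrt",
    "log_spectral_slope",
]


@dataclass(frozen=True)
class PriorConfig:
    coef_sd: float = 2.5  # Normal(0, coef_sd) on location parameters
    sd_scale: float = 2.5  # half-Normal(0, sd_scale) on standard deviations
    pi_alpha: float = 1.0  # Beta prior on detection probability
    pi_beta: float = 1.0


def _normal_logpdf(x, sd):
    return -0.5 * np.asarray(x) ** 2 / sd**2 - np.log(sd)


@dataclass
class PosteriorFit:
    """Posterior draws with named access, diagnostics, and gates."""

    model: str
    draws: np.ndarray  # (chains, samples, d)
    param_names: list[str]
    slices: dict[str, slice]
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    meta: dict = field(default_factory=dict)

    def get(self, name: str) -> np.ndarray:
        """Draws for a named block, shape (chains, samples[, k])."""
        block = self.draws[:, :, self.slices[name]]
        return block[:, :, 0] if block.shape[-1] == 1 and name in self.param_names else block

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains, shape (chains*samples[, k])."""
        block = self.draws[:, :, self.slices[name]]
        flat = block.reshape(-1, block.shape[-1])
        return flat[:, 0] if flat.shape[-1] == 1 and name in self.param_names else flat

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.param_names):
            values = self.draws[:, :, j]
            pooled = values.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(pooled.mean()),
                    "sd": float(pooled.std(ddof=1)),
                    "q2.5": float(np.percentile(pooled, 2.5)),
                    "q97.5": float(np.percentile(pooled, 97.5)),
                    "rhat": self.rhat.get(name, np.nan),
                    "ess": self.ess.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        pooled = self.flat(name)
        lo = (1 - level) / 2 * 100
        return (
            float(np.percentile(pooled, lo, axis=0)),
            float(np.percentile(pooled, 100 - lo, axis=0)),
        )


def _diagnose(fit: PosteriorFit, rhat_gate: float, ess_gate: float) -> PosteriorFit:
    for j, name in enumerate(fit.param_names):
        values = fit.draws[:, :, j]
        fit.rhat[name] = rhat(values)
        fit.ess[name] = ess(values)
    fit.converged = all(r <= rhat_gate for r in fit.rhat.values()) and all(
        e >= ess_gate for e in fit.ess.values()
    )
    if not fit.converged:
        warnings.warn(
            f"{fit.model} fit failed convergence gates "
            f"(max rhat {max(fit.rhat.values()):.3f}, "
            f"min ess {min(fit.ess.values()):.0f}); inspect before use",
            stacklevel=2,
        )
    return fit


# --------------------------------------------------------------------------
# censored log-normal mixed model
# --------------------------------------------------------------------------


def build_cens_lnm_data(df: pd.DataFrame) -> CensoredLnmData:
    """Assemble model data from a harmonised tow table.

    Habitat codes follow :data:`lakemp.towdb.HABITATS` order restricted
    to habitats present; studies are coded by first appearance. Mesh size
    is standardised across tows (raw scale).
    """
    habitats = [h for h in towdb_mod.HABITATS if h in set(df["habitat"])]
    hab_code = {h: i for i, h in enumerate(habitats)}
    study_code: dict[str, int] = {}
    for sid in df["study_id"]:
        study_code.setdefault(sid, len(study_code))
    mesh = df["mesh_size_um"].to_numpy(float)
    if np.std(mesh, ddof=1) > 0:
        mesh_std, _, _ = standardize(mesh)
    else:
        mesh_std = np.zeros_like(mesh)
    return CensoredLnmData(
        y=df["concentration_per_m3"].to_numpy(float),
        habitat_idx=np.array([hab_code[h] for h in df["habitat"]]),
        mesh_std=mesh_std,
        study_idx=np.array([study_code[s] for s in df["study_id"]]),
        detection_limit=df["detection_limit_per_m3"].to_numpy(float),
        habitat_labels=habitats,
    )


def _cens_lnm_unpack(x: np.ndarray, H: int, S: int) -> CensoredLnmParams:
    return CensoredLnmParams(
        alpha=x[:H],
        beta_mesh=x[H],
        u=x[H + 1 : H + 1 + S],
        sigma_study=np.exp(x[H + 1 + S]),
        sigma=np.exp(x[H + 2 + S]),
    )


def _study_habitat_map(data: CensoredLnmData) -> np.ndarray | None:
    """Habitat code per study when unique, else None (mixed studies)."""
    mapping = np.full(data.n_studies, -1, dtype=int)
    for s, h in zip(data.study_idx, data.habitat_idx):
        if mapping[s] == -1:
            mapping[s] = h
        elif mapping[s] != h:
            return None
    return mapping


def fit_cens_lnm(
    data: CensoredLnmData,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorConfig = PriorConfig(),
    rhat_gate: float = RHAT_GATE,
    ess_gate: float = ESS_GATE,
) -> PosteriorFit:
    """Posterior for the censored log-normal mixed model.

    When each study sits in a single habitat the sampler works on the
    centered parameterisation (study-level means ``m_s = alpha_h + u_s``),
    which removes the translation ridge between habitat means and
    intercepts; draws are reported as ``u_s`` either way.
    Non-convergence does not raise: the fit comes back flagged
    (``converged=False``) with a warning.
    """
    H, S = data.n_habitats, data.n_studies
    study_hab = _study_habitat_map(data)
    centered = study_hab is not None

    def _priors_lp(params: CensoredLnmParams) -> float:
        lp = float(np.sum(_normal_logpdf(params.alpha, priors.coef_sd)))
        lp += float(_normal_logpdf(params.beta_mesh, priors.coef_sd))
        # half-normal on the SDs plus log-Jacobian of the log transform
        lp += float(
            -0.5 * params.sigma_study**2 / priors.sd_scale**2 + np.log(params.sigma_study)
        )
        lp += float(-0.5 * params.sigma**2 / priors.sd_scale**2 + np.log(params.sigma))
        return lp

    def logpost(x: np.ndarray) -> float:
        params = _cens_lnm_unpack(x, H, S)
        if centered:
            # third block holds study means; shift to intercepts (Jacobian 1)
            params = CensoredLnmParams(
                alpha=params.alpha,
                beta_mesh=params.beta_mesh,
                u=params.u - params.alpha[study_hab],
                sigma_study=params.sigma_study,
                sigma=params.sigma,
            )
        ll = cens_lnm_loglik(params, data)
        if not np.isfinite(ll):
            return -np.inf
        return ll + _priors_lp(params)

    x0 = np.zeros(H + S + 3)
    positive = ~data.censored
    logy = np.log(data.y[positive]) if positive.any() else np.array([0.0])
    for h in range(H):
        sel = positive & (data.habitat_idx == h)
        x0[h] = np.log(data.y[sel]).mean() if sel.any() else logy.mean()
    if centered:
        for s in range(S):
            sel = positive & (data.study_idx == s)
            x0[H + 1 + s] = np.log(data.y[sel]).mean() if sel.any() else x0[study_hab[s]]
    x0[H + 1 + S] = np.log(0.5)
    x0[H + 2 + S] = np.log(max(logy.std(), 0.3))

    draws = run_chains(logpost, x0, mcmc)
    if centered:
        draws[:, :, H + 1 : H + 1 + S] -= draws[:, :, study_hab]
    # report SDs on their natural scale
    draws[:, :, H + 1 + S] = np.exp(draws[:, :, H + 1 + S])
    draws[:, :, H + 2 + S] = np.exp(draws[:, :, H + 2 + S])
    names = (
        [f"alpha[{lab}]" for lab in data.habitat_labels]
        + ["beta_mesh"]
        + [f"u[{s}]" for s in range(S)]
        + ["sigma_study", "sigma"]
    )
    slices = {name: slice(j, j + 1) for j, name in enumerate(names)}
    slices["alpha"] = slice(0, H)
    slices["u"] = slice(H + 1, H + 1 + S)
    fit = PosteriorFit(
        model="cens_lnm",
        draws=draws,
        param_names=names,
        slices=slices,
        meta={"habitat_labels": data.habitat_labels},
    )
    return _diagnose(fit, rhat_gate, ess_gate)


def habitat_contrast(
    fit: PosteriorFit,
    habitat_a: str,
    habitat_b: str,
    at_mesh: float = 0.0,
) -> np.ndarray:
    """Per-draw difference in median-scale concentration (particles m^-3).

    The log-normal median at the reference mesh is
    ``exp(alpha_h + beta_mesh * at_mesh)``.
    """
    labels = fit.meta["habitat_labels"]
    for h in (habitat_a, habitat_b):
        if h not in labels:
            raise ValueError(f"unknown habitat {h!r}; fitted habitats: {labels}")
    alpha = fit.flat("alpha")
    beta_mesh = fit.flat("beta_mesh")
    med = np.exp(alpha + beta_mesh[:, None] * at_mesh)
    ia, ib = labels.index(habitat_a), labels.index(habitat_b)
    return med[:, ia] - med[:, ib]


def habitat_contrasts(fit: PosteriorFit, at_mesh: float = 0.0) -> pd.DataFrame:
    """Pairwise habitat differences with 95% credible intervals."""
    labels = fit.meta["habitat_labels"]
    rows = []
    for a in labels:
        for b in labels:
            if a == b:
                continue
            diff = habitat_contrast(fit, a, b, at_mesh)
            rows.append(
                {
                    "habitat_a": a,
                    "habitat_b": b,
                    "mean": float(diff.mean()),
                    "q2.5": float(np.percentile(diff, 2.5)),
                    "q97.5": float(np.percentile(diff, 97.5)),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Poisson hurdle model
# --------------------------------------------------------------------------


def build_hurdle_data(
    survey: pd.DataFrame,
    volume_m3: float | None = None,
) -> HurdleData:
    """Assemble the standardised design matrix from a survey table.

    Plastic input and respiration are cube-root transformed (they contain
    zeros), spectral slope log-transformed, then all six predictors are
    standardised to mean 0 / SD 1.
    """
    if volume_m3 is None:
        vols = survey["volume_m3"].unique()
        if len(vols) != 1:
            raise ValueError("survey has non-constant tow volumes; pass volume_m3")
        volume_m3 = float(vols[0])
    raw = np.column_stack(
        [
            cube_root(survey["plastic_input_tonnes"].to_numpy(float)),
            survey["wwtw_load_pe"].to_numpy(float),
            survey["forest_prop"].to_numpy(float),
            survey["urban_prop"].to_numpy(float),
            cube_root(survey["respiration_mg_o2_l_d"].to_numpy(float)),
            np.log(survey["spectral_slope_nm"].to_numpy(float)),
        ]
    )
    X = np.column_stack([standardize(raw[:, j])[0] for j in range(raw.shape[1])])
    return HurdleData(
        counts=survey["count"].to_numpy(),
        X=X,
        volume_m3=volume_m3,
        predictor_names=list(HURDLE_PREDICTORS),
    )


def _hurdle_unpack(x: np.ndarray) -> HurdleParams:
    return HurdleParams(pi=float(expit(x[0])), beta0=float(x[1]), beta=x[2:])


def fit_hurdle(
    data: HurdleData,
    mcmc: MCMCConfig = MCMCConfig(),
    priors: PriorConfig = PriorConfig(),
    rhat_gate: float = RHAT_GATE,
    ess_gate: float = ESS_GATE,
) -> PosteriorFit:
    """Posterior for the Bernoulli / zero-truncated-Poisson hurdle model.

    The detection part is intercept-only: one probability of recording
    any particles, shared across lakes.
    """
    p = data.X.shape[1]

    def logpost(x: np.ndarray) -> float:
        params = _hurdle_unpack(x)
        ll = hurdle_loglik(params, data)
        if not np.isfinite(ll):
            return -np.inf
        lp = float(_normal_logpdf(x[1], priors.coef_sd))
        lp += float(np.sum(_normal_logpdf(x[2:], priors.coef_sd)))
        # Beta prior on pi plus the logit-transform Jacobian pi*(1-pi)
        lp += priors.pi_alpha * np.log(params.pi) + priors.pi_beta * np.log(1 - params.pi)
        return ll + lp

    frac_pos = max(min((data.counts > 0).mean(), 0.95), 0.05)
    pos_counts = data.counts[data.counts > 0]
    mean_pos = pos_counts.mean() if pos_counts.size else 1.0
    x0 = np.zeros(p + 2)
    x0[0] = np.log(frac_pos / (1 - frac_pos))
    x0[1] = np.log(mean_pos)

    draws = run_chains(logpost, x0, mcmc)
    draws[:, :, 0] = expit(draws[:, :, 0])  # report pi on probability scale
    names = ["pi", "beta0"] + [f"beta[{n}]" for n in data.predictor_names]
    slices = {name: slice(j, j + 1) for j, name in enumerate(names)}
    slices["beta"] = slice(2, 2 + p)
    fit = PosteriorFit(
        model="hurdle",
        draws=draws,
        param_names=names,
        slices=slices,
        meta={"predictor_names": list(data.predictor_names), "volume_m3": data.volume_m3},
    )
    return _diagnose(fit, rhat_gate, ess_gate)


# --------------------------------------------------------------------------
# fit summaries shared by both models
# --------------------------------------------------------------------------


def bayes_r2(fit: PosteriorFit, data) -> np.ndarray:
    """Per-draw Bayesian R^2: var(fitted) / (var(fitted) + var(residual))."""
    if fit.model == "hurdle":
        pi = fit.flat("pi")
        beta0 = fit.flat("beta0")
        beta = fit.flat("beta")
        lam = np.exp(beta0[:, None] + beta @ data.X.T)
        denom = -np.expm1(-lam)
        mean_i = pi[:, None] * lam / denom
        second_moment = pi[:, None] * (lam + lam**2) / denom
        var_i = second_moment - mean_i**2
        var_fit = mean_i.var(axis=1, ddof=1)
        var_res = var_i.mean(axis=1)
        return var_fit / (var_fit + var_res)
    if fit.model == "cens_lnm":
        alpha = fit.flat("alpha")
        beta_mesh = fit.flat("beta_mesh")
        u = fit.flat("u")
        sigma = fit.flat("sigma")
        mu = (
            alpha[:, data.habitat_idx]
            + beta_mesh[:, None] * data.mesh_std
            + u[:, data.study_idx]
        )
        var_fit = mu.var(axis=1, ddof=1)
        return var_fit / (var_fit + sigma**2)
    raise ValueError(f"unknown model {fit.model!r}")


@dataclass
class EffectCurve:
    """Marginal-effect curve of expected concentration (particles m^-3)."""

    predictor: str
    x: np.ndarray  # grid, standardised scale
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    @property
    def endpoint_ratio(self) -> float:
        """Posterior-mean prediction at the last grid point over the first."""
        return float(self.mean[-1] / self.mean[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "mean": self.mean, "q2.5": self.lo, "q97.5": self.hi}
        )


def _expected_concentration(pi, beta0, beta, X_grid, volume, marginalize_pi):
    lam = np.exp(beta0[:, None] + beta @ X_grid.T)
    mean_count = lam / -np.expm1(-lam)
    if marginalize_pi:
        mean_count = pi[:, None] * mean_count
    return mean_count / volume


def marginal_effect(
    fit: PosteriorFit,
    data: HurdleData,
    predictor_index: int,
    grid: np.ndarray | None = None,
    n_draws: int = 1000,
    marginalize_pi: bool = True,
) -> EffectCurve:
    """Expected concentration along one predictor, others held at 0 (mean).

    Uses an evenly spaced subset of ``n_draws`` posterior draws; by
    default the detection probability multiplies the truncated-Poisson
    mean (set ``marginalize_pi=False`` to condition on detection).
    """
    if fit.model != "hurdle":
        raise ValueError("marginal effects are defined for the hurdle fit")
    col = data.X[:, predictor_index]
    if grid is None:
        grid = np.linspace(col.min(), col.max(), 50)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < col.min() - 1e-9 or grid.max() > col.max() + 1e-9:
        warnings.warn("effect grid extends outside the observed predictor range", stacklevel=2)
    X_grid = np.zeros((grid.size, data.X.shape[1]))
    X_grid[:, predictor_index] = grid

    total = fit.n_draws
    idx = np.linspace(0, total - 1, min(n_draws, total)).astype(int)
    pi = fit.flat("pi")[idx]
    beta0 = fit.flat("beta0")[idx]
    beta = fit.flat("beta")[idx]
    conc = _expected_concentration(pi, beta0, beta, X_grid, data.volume_m3, marginalize_pi)
    return EffectCurve(
        predictor=data.predictor_names[predictor_index],
        x=grid,
        mean=conc.mean(axis=0),
        lo=np.percentile(conc, 2.5, axis=0),
        hi=np.percentile(conc, 97.5, axis=0),
    )


def pointwise_loglik(fit: PosteriorFit, data, thin: int = 1) -> np.ndarray:
    """Per-observation log-likelihood draws, shape (chains, draws, n).

    For the mixed model this is conditional on the study intercepts.
    """
    chains, samples, _ = fit.draws.shape
    take = slice(None, None, thin)
    if fit.model == "hurdle":
        pi = fit.get("pi")[:, take]
        beta0 = fit.get("beta0")[:, take]
        beta = fit.get("beta")[:, take]
        eta = beta0[..., None] + np.einsum("csp,np->csn", beta, data.X)
        lam = np.exp(np.clip(eta, -30, 30))
        zeros = data.counts == 0
        out = np.empty((chains, pi.shape[1], data.n))
        out[:, :, zeros] = np.log(1 - pi)[..., None]
        if (~zeros).any():
            k = data.counts[~zeros]
            out[:, :, ~zeros] = np.log(pi)[..., None] + trunc_pois_logpmf(
                k[None, None, :], lam[:, :, ~zeros]
            )
        return out
    if fit.model == "cens_lnm":
        alpha = fit.get("alpha")[:, take]
        beta_mesh = fit.get("beta_mesh")[:, take]
        u = fit.get("u")[:, take]
        sigma = fit.get("sigma")[:, take]
        mu = (
            alpha[:, :, data.habitat_idx]
            + beta_mesh[..., None] * data.mesh_std
            + u[:, :, data.study_idx]
        )
        out = np.empty_like(mu)
        cens = data.censored
        from scipy.special import log_ndtr

        if (~cens).any():
            y = data.y[~cens]
            z = (np.log(y) - mu[:, :, ~cens]) / sigma[..., None]
            out[:, :, ~cens] = (
                -np.log(y)
                - np.log(sigma)[..., None]
                - 0.5 * np.log(2 * np.pi)
                - 0.5 * z**2
            )
        if cens.any():
            z = (np.log(data.detection_limit[cens]) - mu[:, :, cens]) / sigma[..., None]
            out[:, :, cens] = log_ndtr(z)
        return out
    raise ValueError(f"unknown model {fit.model!r}")
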