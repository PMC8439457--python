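"""Synthetic inputs with the statistical structure the analyses assume.

Four generators emulate the external data products so that every
downstream stage is testable without downloads: a study-structured net
tow database with detection-limit censoring, a hurdle-Poisson lake
survey driven by known coefficients, a toy raster landscape draining to
a single outlet, and exponential-decay / banded spectra.

All generators are deterministic in their seed; sub-streams are derived
via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import Raster
from .towdb import HABITATS

__all__ = [
    "CdomParams",
    "FtirParams",
    "GlobalTowSimConfig",
    "LakeSimConfig",
    "PredictorDists",
    "TOY_CLASS_MAP",
    "ToyLandscape",
    "gen_lake_survey",
    "gen_spectra",
    "gen_towdb",
    "gen_toy_landscape",
]


# --------------------------------------------------------------------------
# global net-tow database
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GlobalTowSimConfig:
    """Generative twin of the censored log-normal mixed model."""

    n_studies: int = 30
    tows_per_study: int = 20
    habitat_log_means: dict = field(
        default_factory=lambda: {"lake": -1.0, "river": -0.5, "marine_estuarine": -0.8}
    )
    mesh_effect: float = -0.3  # slope per standardised mesh unit
    study_sd: float = 0.6  # SD of study intercepts, log scale
    resid_sd: float = 0.8  # residual SD, log scale
    volume_range_m3: tuple[float, float] = (2.0, 500.0)
    mesh_range_um: tuple[float, float] = (45.0, 780.0)
    lake_area_log10_mean: float = 1.5
    lake_area_log10_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1 or self.tows_per_study < 1:
            raise ValueError("n_studies and tows_per_study must be positive")
        bad = set(self.habitat_log_means) - set(HABITATS)
        if bad:
            raise ValueError(f"invalid habitat label(s): {sorted(bad)}")
        if not self.habitat_log_means:
            raise ValueError("habitat_log_means cannot be empty")
        if self.study_sd < 0 or self.resid_sd < 0:
            raise ValueError("study_sd and resid_sd cannot be negative")
        if self.volume_range_m3[0] <= 0:
            raise ValueError("tow volumes must be positive")


def gen_towdb(config: GlobalTowSimConfig) -> pd.DataFrame:
    """Simulate a harmonised net-tow table.

    Latent log concentration = habitat mean + mesh effect x standardised
    mesh + study intercept + residual noise; latent concentrations below
    one particle per tow volume are recorded as 0 (censored), and every
    record carries its detection limit ``1 / volume``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    habitats = list(config.habitat_log_means)
    rows = []
    n = config.n_studies * config.tows_per_study
    mesh_all = rng.uniform(*config.mesh_range_um, size=n)
    mesh_mean, mesh_sd = mesh_all.mean(), mesh_all.std(ddof=1)
    if mesh_sd == 0:
        mesh_sd = 1.0
    i = 0
    for s in range(config.n_studies):
        habitat = habitats[s % len(habitats)]
        u_s = config.study_sd * rng.standard_normal()
        lake_area = (
            10.0 ** rng.normal(config.lake_area_log10_mean, config.lake_area_log10_sd)
            if habitat == "lake"
            else np.nan
        )
        latitude = rng.uniform(-60.0, 70.0)
        for _ in range(config.tows_per_study):
            mesh = mesh_all[i]
            i += 1
            volume = rng.uniform(*config.volume_range_m3)
            mesh_std = (mesh - mesh_mean) / mesh_sd
            latent = (
                config.habitat_log_means[habitat]
                + config.mesh_effect * mesh_std
                + u_s
                + config.resid_sd * rng.standard_normal()
            )
            if not np.isfinite(latent):
                raise ValueError("non-finite latent concentration generated")
            conc = float(np.exp(latent))
            limit = 1.0 / volume
            rows.append(
                {
                    "study_id": f"study_{s:03d}",
                    "habitat": habitat,
                    "mesh_size_um": mesh,
                    "net_mouth_diameter_m": 0.3,
                    "tow_distance_m": volume / (np.pi * 0.15**2),
                    "volume_m3": volume,
                    "concentration_per_m3": conc if conc >= limit else 0.0,
                    "detection_limit_per_m3": limit,
                    "lake_area_km2": lake_area,
                    "latitude_deg": latitude,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# lake survey
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorDists:
    """Marginal distributions of the six raw lake predictors.

    Shapes mirror the skew that motivates the model's transforms:
    log-normals for plastic input, wastewater load (with a point mass at
    zero) and spectral slope, a half-normal for respiration, Betas for
    the cover proportions.
    """

    plastic_logmean: float = 0.0
    plastic_logsd: float = 1.0
    wwtw_zero_prob: float = 0.3
    wwtw_logmean: float = 7.0
    wwtw_logsd: float = 1.5
    forest_a: float = 2.0
    forest_b: float = 2.0
    urban_a: float = 1.5
    urban_b: float = 6.0
    respiration_scale: float = 1.5
    slope_logmean: float = float(np.log(0.02))
    slope_logsd: float = 0.3


@dataclass(frozen=True)
class LakeSimConfig:
    """Generative twin of the Poisson hurdle model."""

    n_lakes: int = 67
    beta: tuple = (0.3, 0.2, -0.2, 0.0, -0.3, 0.0)
    intercept: float = 0.7  # log mean count
    detect_prob: float = 56 / 67
    volume_m3: float = 7.1
    predictor_dists: PredictorDists = field(default_factory=PredictorDists)
    seed: int = 0

    def __post_init__(self):
        if self.n_lakes < 1:
            raise ValueError("n_lakes must be positive")
        if not 0 <= self.detect_prob <= 1:
            raise ValueError("detect_prob must lie in [0, 1]")
        if self.volume_m3 <= 0:
            raise ValueError("volume_m3 must be positive")
        if len(self.beta) != 6:
            raise ValueError("beta must have six coefficients")


def _draw_predictors(config: LakeSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    d = config.predictor_dists
    n = config.n_lakes
    plastic = rng.lognormal(d.plastic_logmean, d.plastic_logsd, n)
    wwtw = rng.lognormal(d.wwtw_logmean, d.wwtw_logsd, n)
    wwtw[rng.random(n) < d.wwtw_zero_prob] = 0.0
    forest = rng.beta(d.forest_a, d.forest_b, n)
    urban = rng.beta(d.urban_a, d.urban_b, n) * (1.0 - forest)
    respiration = np.abs(rng.normal(0.0, d.respiration_scale, n))
    slope = rng.lognormal(d.slope_logmean, d.slope_logsd, n)
    df = pd.DataFrame(
        {
            "plastic_input_tonnes": plastic,
            "wwtw_load_pe": wwtw,
            "forest_prop": forest,
            "urban_prop": urban,
            "respiration_mg_o2_l_d": respiration,
            "spectral_slope_nm": slope,
        }
    )
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite predictor draws")
    return df


def _standardised_design(predictors: pd.DataFrame) -> np.ndarray:
    from .emissions import cube_root
    from .limnoassays import standardize

    raw = np.column_stack(
        [
            cube_root(predictors["plastic_input_tonnes"].to_numpy()),
            predictors["wwtw_load_pe"].to_numpy(),
            predictors["forest_prop"].to_numpy(),
            predictors["urban_prop"].to_numpy(),
            cube_root(predictors["respiration_mg_o2_l_d"].to_numpy()),
            np.log(predictors["spectral_slope_nm"].to_numpy()),
        ]
    )
    return np.column_stack([standardize(raw[:, j])[0] for j in range(raw.shape[1])])


def _zero_truncated_poisson(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws: uniform on (e^-lam, 1), then Poisson quantile."""
    lam = np.asarray(lam, dtype=float)
    p0 = np.exp(-lam)
    u = p0 + (1.0 - p0) * rng.random(lam.shape)
    k = stats.poisson.ppf(np.clip(u, None, 1.0 - 1e-16), lam).astype(int)
    return np.maximum(k, 1)


def gen_lake_survey(config: LakeSimConfig) -> pd.DataFrame:
    """Simulate the per-lake survey table.

    A lake yields a positive count with probability ``detect_prob``;
    positive counts are zero-truncated Poisson with log mean
    ``intercept + x' beta`` on the standardised predictor scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    predictors = _draw_predictors(config, rng)
    X = _standardised_design(predictors)
    lam = np.exp(config.intercept + X @ np.asarray(config.beta, dtype=float))
    detected = rng.random(config.n_lakes) < config.detect_prob
    counts = np.zeros(config.n_lakes, dtype=int)
    if detected.any():
        counts[detected] = _zero_truncated_poisson(lam[detected], rng)
    out = pd.DataFrame(
        {
            "lake_id": [f"lake_{i:03d}" for i in range(config.n_lakes)],
            "count": counts,
            "volume_m3": config.volume_m3,
            "concentration_per_m3": counts / config.volume_m3,
        }
    )
    return pd.concat([out, predictors], axis=1)


# --------------------------------------------------------------------------
# toy landscape
# --------------------------------------------------------------------------

#: land-cover codes for the toy landscape and their model classes
TOY_CLASS_MAP = {1: "urban", 2: "urban", 23: "forest", 24: "forest", 25: "forest", 12: "other", 18: "other", 26: "other"}

_URBAN_CODES = (1, 2)
_FOREST_CODES = (23, 24, 25)
_OTHER_CODES = (12, 18, 26)


@dataclass
class ToyLandscape:
    dem: Raster
    lake_mask: Raster
    landcover: Raster
    population: Raster
    runoff_mm_day: np.ndarray  # 12 monthly values
    wwtw_points: list[tuple[float, float, float]]

    @property
    def lake_cells(self) -> np.ndarray:
        return self.lake_mask.values.astype(bool)


def gen_toy_landscape(size_px: int, seed: int = 0, cell_size_m: float = 25.0) -> ToyLandscape:
    """A single-valley landscape draining to one east-edge outlet.

    The DEM is a V-shaped valley sloping east with small positive noise;
    every cell has a strictly descending 8-neighbour path to the outlet
    at the middle of the east edge. The lake is a wedge of valley cells
    whose tip collects all lake drainage, so the lake lies inside the
    watershed of its own pour point.
    """
    if size_px < 5:
        raise ValueError("size_px must be at least 5")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n = size_px
    rows, cols = np.mgrid[0:n, 0:n]
    mid = n // 2
    base = 2.0 * np.abs(rows - mid) + 1.0 * (n - 1 - cols)
    dem_values = base + rng.uniform(0.0, 0.3, size=(n, n))

    c1 = n - 1 - max(2, n // 5)
    c0 = max(1, c1 - max(1, n // 3))
    lake = np.zeros((n, n), dtype=bool)
    lake[mid, c0 : c1 + 1] = True
    if c1 > c0:
        lake[mid - 1, c0:c1] = True
        lake[mid + 1, c0:c1] = True

    codes = rng.choice(
        np.array(_URBAN_CODES + _FOREST_CODES + _OTHER_CODES),
        size=(n, n),
        p=np.array([0.075, 0.075, 0.40 / 3, 0.40 / 3, 0.40 / 3, 0.15, 0.15, 0.15]),
    )
    urban = np.isin(codes, _URBAN_CODES)
    population = np.where(
        urban, rng.lognormal(4.0, 0.5, (n, n)), rng.lognormal(1.0, 0.5, (n, n))
    )

    month = np.arange(12)
    runoff = 1.5 + np.sin(2 * np.pi * (month - 3) / 12.0) + rng.uniform(0, 0.2, 12)
    runoff = np.clip(runoff, 0.1, None)

    wwtw_points = []
    for _ in range(3):
        r = int(rng.integers(0, n))
        c = int(rng.integers(0, n))
        x = (c + 0.5) * cell_size_m
        y = (n - 1 - r + 0.5) * cell_size_m
        load = float(rng.lognormal(7.0, 1.0))
        wwtw_points.append((x, y, load))

    def raster(values):
        return Raster(values=np.asarray(values, dtype=float), cell_size_m=cell_size_m)

    return ToyLandscape(
        dem=raster(dem_values),
        lake_mask=raster(lake.astype(float)),
        landcover=raster(codes.astype(float)),
        population=raster(population),
        runoff_mm_day=runoff,
        wwtw_points=wwtw_points,
    )


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CdomParams:
    a0: float = 0.8  # absorbance at the reference wavelength
    s_per_nm: float = 0.02  # exponential decay coefficient
    lambda0_nm: float = 275.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class FtirParams:
    bands: tuple = ((1715, 25, 1.0), (1240, 30, 0.8))  # (centre, width, height)
    noise_sd: float = 0.0
    step_cm: float = 4.0


def gen_spectra(kind: str, params=None, seed: int = 0) -> pd.DataFrame:
    """Generate a CDOM absorbance or FTIR band spectrum table.

    ``cdom``: ``A(lambda) = a0 * exp(-S (lambda - lambda0))`` on a 1-nm
    grid over 200-700 nm plus optional Gaussian noise. ``ftir``: a sum
    of Gaussian bands on a 400-4000 cm^-1 grid.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    if kind == "cdom":
        p = params or CdomParams()
        wl = np.arange(200.0, 701.0, 1.0)
        absorbance = p.a0 * np.exp(-p.s_per_nm * (wl - p.lambda0_nm))
        if p.noise_sd > 0:
            absorbance = absorbance + rng.normal(0.0, p.noise_sd, wl.size)
        return pd.DataFrame({"wavelength_nm": wl, "absorbance": absorbance})
    if kind == "ftir":
        p = params or FtirParams()
        grid = np.arange(400.0, 4000.0 + p.step_cm / 2, p.step_cm)
        intensity = np.zeros_like(grid)
        for centre, width, height in p.bands:
            intensity += height * np.exp(-0.5 * ((grid - centre) / width) ** 2)
        if p.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, p.noise_sd, grid.size)
        return pd.DataFrame({"wavenumber": grid, "intensity": intensity})
    raise ValueError(f"unknown spectrum kind {kind!r}; use 'cdom' or 'ftir'")
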