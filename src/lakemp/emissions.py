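"""Plastic mass inputs to a lake from mismanaged waste, runoff, and retention.

Monthly emission follows ``E_m = a * (sum_i MPW_i * area_i * g(R_i) *
days)^b`` where MPW is mismanaged-plastic-waste generation (tonnes km^-2
day^-1), R is monthly runoff (mm day^-1) and ``g`` is a runoff-coupling
function, by default linear in runoff normalised by a reference rate.
The calibrated coefficients of the published river-emission formula are
not reprinted here, so ``(a, b)`` and the coupling are explicit,
documented parameters defaulting to the linear identity ``a=1, b=1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rasters import Raster

__all__ = [
    "EmissionParams",
    "cube_root",
    "gdp_correct_mpw",
    "integrate_retention",
    "monthly_emission",
    "mpw_from_population",
]


@dataclass(frozen=True)
class EmissionParams:
    """Coefficients of the pluggable emission formula."""

    a: float = 1.0
    b: float = 1.0
    runoff_coupling: str = "linear"  # or "sqrt"
    runoff_ref_mm_day: float = 1.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("emission coefficients a and b must be positive")
        if self.runoff_coupling not in {"linear", "sqrt"}:
            raise ValueError(f"unknown runoff coupling {self.runoff_coupling!r}")

    def coupling(self, runoff_mm_day: np.ndarray) -> np.ndarray:
        scaled = np.asarray(runoff_mm_day, dtype=float) / self.runoff_ref_mm_day
        if self.runoff_coupling == "linear":
            return scaled
        return np.sqrt(scaled)


def mpw_from_population(
    population: Raster,
    per_capita_waste_kg_day: float,
    mismanaged_fraction: float,
) -> Raster:
    """MPW generation grid (tonnes km^-2 day^-1) from population density.

    ``population`` holds persons per cell; waste generation and the
    mismanaged fraction are inputs, not constants.
    """
    if per_capita_waste_kg_day < 0 or not 0 <= mismanaged_fraction <= 1:
        raise ValueError("waste rate must be >=0 and mismanaged fraction in [0, 1]")
    valid = population.mask_valid()
    tonnes_per_cell_day = population.values * per_capita_waste_kg_day * mismanaged_fraction / 1000.0
    values = np.where(valid, tonnes_per_cell_day / population.cell_area_km2(), population.nodata)
    return population.copy_with(values)


def gdp_correct_mpw(mpw: Raster, gdp_ratio: Raster) -> Raster:
    """Cellwise scaling by a subnational/national GDP-per-capita ratio grid."""
    if not mpw.aligned_with(gdp_ratio):
        raise ValueError("MPW and GDP-ratio grids are not aligned")
    valid = mpw.mask_valid() & gdp_ratio.mask_valid()
    values = np.where(valid, mpw.values * gdp_ratio.values, mpw.nodata)
    return mpw.copy_with(values)


def monthly_emission(
    mpw: Raster,
    catchment_mask: np.ndarray,
    runoff_mm_day,
    params: EmissionParams = EmissionParams(),
    days_in_month: int = 30,
) -> float:
    """Plastic mass emitted to the lake in one month, tonnes.

    ``runoff_mm_day`` may be a scalar or a grid aligned with ``mpw``.
    """
    if not 28 <= days_in_month <= 31:
        raise ValueError("days_in_month must be between 28 and 31")
    mask = np.asarray(catchment_mask, dtype=bool) & mpw.mask_valid()
    runoff = np.broadcast_to(np.asarray(runoff_mm_day, dtype=float), mpw.shape)
    if (runoff[mask] < 0).any():
        raise ValueError("runoff cannot be negative")
    area = mpw.cell_area_km2()
    inner = float(
        np.sum(mpw.values[mask] * area * params.coupling(runoff[mask]) * days_in_month)
    )
    if inner == 0.0:
        return 0.0
    return params.a * inner**params.b


def integrate_retention(
    monthly_emissions: Sequence[float],
    retention_time_months: float,
    sampling_month: int | None = None,
) -> float:
    """Sum emissions over the retention window ending at ``sampling_month``.

    ``sampling_month`` indexes into the series (default: last entry). A
    fractional retention time weights the earliest month of the window
    proportionally, e.g. retention 1.5 gives the sampling month plus half
    the preceding month.
    """
    series = np.asarray(monthly_emissions, dtype=float)
    if retention_time_months <= 0:
        raise ValueError("retention time must be positive")
    if sampling_month is None:
        sampling_month = series.size - 1
    if not 0 <= sampling_month < series.size:
        raise ValueError("sampling_month outside the emission series")
    n_full = int(np.floor(retention_time_months))
    frac = retention_time_months - n_full
    first = sampling_month - n_full + 1
    if first - (1 if frac > 0 else 0) < 0:
        raise ValueError("retention window extends before the start of the series")
    total = float(series[first : sampling_month + 1].sum())
    if frac > 0:
        total += frac * float(series[first - 1])
    return total


def cube_root(x) -> np.ndarray | float:
    """Real cube root of non-negative input (0 maps to 0).

    The transform applied to zero-inflated skewed predictors before
    standardisation.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("cube_root expects non-negative input")
    result = np.cbrt(arr)
    return float(result) if np.isscalar(x) or arr.ndim == 0 else result
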