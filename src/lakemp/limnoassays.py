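"""In-lake degradation-potential predictors from raw assay readings.

Covers bottle-incubation oxygen budgets (respiration, primary
productivity; respiratory quotient assumed 1 so O2 change is reported
as-is) and the 275-295 nm spectral slope of dissolved organic matter
absorbance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssayResult",
    "primary_productivity",
    "respiration_rate",
    "spectral_slope",
    "standardize",
]

INCUBATION_COLUMNS = ["lake_id", "bottle_id", "treatment", "o2_start", "o2_end", "duration_h"]


@dataclass
class AssayResult:
    """A rate estimate plus data-quality flags."""

    rate: float
    n_bottles: int
    flags: list[str] = field(default_factory=list)

    @property
    def unreplicated(self) -> bool:
        return "unreplicated" in self.flags


def _treatment_rows(records: pd.DataFrame, treatment: str) -> pd.DataFrame:
    if "treatment" not in records.columns:
        raise ValueError("incubation table needs a 'treatment' column")
    bad = set(records["treatment"]) - {"dark", "light"}
    if bad:
        raise ValueError(f"unknown treatment label(s): {sorted(bad)}")
    sub = records[records["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no {treatment}-bottle records supplied")
    if (sub["duration_h"] <= 0).any():
        raise ValueError("incubation duration must be positive")
    return sub


def respiration_rate(records: pd.DataFrame) -> AssayResult:
    """Oxygen consumption in dark bottles, mg O2 L^-1 day^-1.

    Mean over bottles of ``(o2_start - o2_end) / duration_h * 24``. Net O2
    production in the dark yields a negative rate with a warning flag; a
    single bottle is allowed but flagged as unreplicated.
    """
    sub = _treatment_rows(records, "dark")
    per_bottle = (sub["o2_start"] - sub["o2_end"]) / sub["duration_h"] * 24.0
    rate = float(per_bottle.mean())
    flags = []
    if len(sub) < 2:
        flags.append("unreplicated")
    if rate < 0:
        flags.append("net_o2_production_in_dark")
    return AssayResult(rate=rate, n_bottles=len(sub), flags=flags)


def primary_productivity(records: pd.DataFrame) -> AssayResult:
    """Oxygen production in light bottles, mg O2 L^-1 h^-1.

    Sign convention is opposite to respiration: positive when O2 rises.
    """
    sub = _treatment_rows(records, "light")
    per_bottle = (sub["o2_end"] - sub["o2_start"]) / sub["duration_h"]
    rate = float(per_bottle.mean())
    flags = []
    if len(sub) < 2:
        flags.append("unreplicated")
    if rate < 0:
        flags.append("net_o2_consumption_in_light")
    return AssayResult(rate=rate, n_bottles=len(sub), flags=flags)


def spectral_slope(
    wavelengths_nm: np.ndarray,
    absorbance: np.ndarray,
    lo_nm: float = 275.0,
    hi_nm: float = 295.0,
) -> float:
    """Exponential decay coefficient S (nm^-1) over ``[lo_nm, hi_nm]``.

    Ordinary least squares of ``ln(absorbance)`` on wavelength; ``S`` is
    minus the fitted slope, so decaying spectra give positive values.
    Non-positive absorbances inside the window are dropped; fewer than 3
    remaining points is an error.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    ab = np.asarray(absorbance, dtype=float)
    if wl.shape != ab.shape:
        raise ValueError("wavelength and absorbance arrays differ in shape")
    window = (wl >= lo_nm) & (wl <= hi_nm)
    window &= ab > 0
    if window.sum() < 3:
        raise ValueError(
            f"need >=3 points with positive absorbance in [{lo_nm:g}, {hi_nm:g}] nm"
        )
    slope, _ = np.polyfit(wl[window], np.log(ab[window]), deg=1)
    return float(-slope)


def standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centre and scale to mean 0, SD 1; returns ``(z, mean, sd)``.

    Sample (n-1) SD. The returned moments allow back-transformation of
    fitted coefficients.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardise")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("cannot standardise a constant vector")
    return (x - mean) / sd, mean, sd
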