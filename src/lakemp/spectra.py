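"""FTIR spectrum preprocessing and library matching.

Pipeline order mirrors the lab workflow: Savitzky-Golay smoothing, then
baseline correction and peak normalisation, then Pearson-correlation
matching against a labelled reference library over 700-1850 cm^-1.

The "15% adaptive baseline" of the original acquisition software is not
publicly specified; here it is approximated by morphological opening (a
rolling minimum followed by a rolling maximum) with a window equal to
15% of the spectral span.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

__all__ = [
    "FtirSpectrum",
    "MatchResult",
    "baseline_and_normalize",
    "builtin_library",
    "library_match",
    "preprocess",
    "read_spectrum",
    "savgol_smooth",
    "write_spectrum",
]

MATCH_REGION_CM = (700.0, 1850.0)
RESAMPLE_STEP_CM = 4.0


@dataclass(frozen=True)
class FtirSpectrum:
    wavenumber: np.ndarray  # cm^-1, strictly monotone
    intensity: np.ndarray
    label: str | None = None

    def __post_init__(self):
        wn = np.asarray(self.wavenumber, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "intensity", it)
        if wn.shape != it.shape or wn.ndim != 1:
            raise ValueError("wavenumber and intensity must be matching 1-D arrays")
        diffs = np.diff(wn)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")

    def ascending(self) -> "FtirSpectrum":
        if self.wavenumber[0] < self.wavenumber[-1]:
            return self
        return replace(self, wavenumber=self.wavenumber[::-1], intensity=self.intensity[::-1])


def savgol_smooth(spectrum: FtirSpectrum, window_cm: float = 20.0, poly_order: int = 3) -> FtirSpectrum:
    """Savitzky-Golay smoothing over a fixed wavenumber interval.

    The window is converted to an odd number of grid points; it must
    cover at least ``poly_order + 1`` points.
    """
    spec = spectrum.ascending()
    spacing = float(np.median(np.diff(spec.wavenumber)))
    npoints = int(round(window_cm / spacing)) + 1
    if npoints % 2 == 0:
        npoints += 1
    if npoints < poly_order + 1:
        raise ValueError(
            f"window of {window_cm:g} cm^-1 covers only {npoints} points; "
            f"need >= {poly_order + 1} for a degree-{poly_order} fit"
        )
    if npoints > spec.intensity.size:
        raise ValueError("smoothing window longer than the spectrum")
    smoothed = savgol_filter(spec.intensity, window_length=npoints, polyorder=poly_order)
    return replace(spec, intensity=smoothed)


def _opening_baseline(intensity: np.ndarray, window_pts: int) -> np.ndarray:
    low = minimum_filter1d(intensity, size=window_pts, mode="nearest")
    return maximum_filter1d(low, size=window_pts, mode="nearest")


def baseline_and_normalize(spectrum: FtirSpectrum, baseline_frac: float = 0.15) -> FtirSpectrum:
    """Subtract an adaptive baseline, then scale the peak maximum to 1."""
    spec = spectrum.ascending()
    if np.ptp(spec.intensity) == 0:
        raise ValueError("cannot baseline-correct a constant spectrum")
    window_pts = max(3, int(round(baseline_frac * spec.intensity.size)))
    corrected = spec.intensity - _opening_baseline(spec.intensity, window_pts)
    peak = corrected.max()
    if peak <= 0:
        raise ValueError("spectrum is non-positive after baseline correction")
    return replace(spec, intensity=corrected / peak)


def preprocess(spectrum: FtirSpectrum, window_cm: float = 20.0, poly_order: int = 3) -> FtirSpectrum:
    """The full pipeline: smooth, baseline-correct, normalise."""
    return baseline_and_normalize(savgol_smooth(spectrum, window_cm, poly_order))


@dataclass(frozen=True)
class MatchResult:
    label: str | None
    r: float
    all_r: dict[str, float]

    @property
    def matched(self) -> bool:
        return self.label is not None


def _resample(spec: FtirSpectrum, grid: np.ndarray) -> np.ndarray:
    s = spec.ascending()
    return np.interp(grid, s.wavenumber, s.intensity)


def library_match(
    query: FtirSpectrum,
    library: list[FtirSpectrum],
    region: tuple[float, float] = MATCH_REGION_CM,
    threshold: float = 0.90,
) -> MatchResult:
    """Best Pearson-correlation match over ``region``; none below threshold.

    Query and library entries are linearly resampled to a common
    4 cm^-1 grid inside the region before correlating.
    """
    if not library:
        raise ValueError("reference library is empty")
    lo, hi = region
    grid = np.arange(lo, hi + RESAMPLE_STEP_CM / 2, RESAMPLE_STEP_CM)
    q = _resample(query, grid)
    if np.std(q) == 0:
        raise ValueError("query spectrum is constant over the match region")
    all_r: dict[str, float] = {}
    best_label, best_r = None, -np.inf
    for i, entry in enumerate(library):
        label = entry.label if entry.label is not None else f"entry_{i}"
        e = _resample(entry, grid)
        if np.std(e) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(q, e)[0, 1])
        all_r[label] = r
        if np.isfinite(r) and r > best_r:
            best_label, best_r = label, r
    if best_r >= threshold:
        return MatchResult(label=best_label, r=best_r, all_r=all_r)
    return MatchResult(label=None, r=best_r, all_r=all_r)


# --- bundled synthetic reference library ---------------------------------

_LIBRARY_BANDS = {
    # label: [(centre cm^-1, width cm^-1, height), ...] -- stylised band
    # patterns, not measured polymer spectra.
    "polyamide": [(1640, 30, 1.0), (1540, 30, 0.8), (2930, 50, 0.5), (3300, 80, 0.6)],
    "polyester": [(1715, 25, 1.0), (1240, 30, 0.8), (1090, 30, 0.7), (720, 15, 0.3)],
    "polyethylene": [(2915, 25, 1.0), (2850, 25, 0.9), (1470, 20, 0.3), (718, 10, 0.2)],
    "polyvinyl_chloride": [(610, 25, 0.8), (960, 25, 0.5), (1250, 30, 0.6), (2910, 40, 0.7)],
    "cellulose": [(1030, 50, 1.0), (1160, 25, 0.4), (2900, 60, 0.3), (3340, 120, 0.7)],
}


def _band_spectrum(bands, grid: np.ndarray) -> np.ndarray:
    out = np.zeros_like(grid)
    for centre, width, height in bands:
        out += height * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    return out


def builtin_library(step_cm: float = RESAMPLE_STEP_CM) -> list[FtirSpectrum]:
    """Small bundled library of labelled synthetic band patterns."""
    grid = np.arange(400.0, 4000.0 + step_cm / 2, step_cm)
    return [
        FtirSpectrum(wavenumber=grid, intensity=_band_spectrum(bands, grid), label=label)
        for label, bands in _LIBRARY_BANDS.items()
    ]


def read_spectrum(path, label: str | None = None) -> FtirSpectrum:
    """Two-column delimited text: wavenumber, intensity."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("spectrum file needs two columns (wavenumber, intensity)")
    if label is None:
        label = Path(path).stem
    return FtirSpectrum(
        wavenumber=df.iloc[:, 0].to_numpy(float),
        intensity=df.iloc[:, 1].to_numpy(float),
        label=label,
    )


def write_spectrum(spec: FtirSpectrum, path) -> None:
    pd.DataFrame({"wavenumber": spec.wavenumber, "intensity": spec.intensity}).to_csv(
        path, sep="\t", index=False
    )
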