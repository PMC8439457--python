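"""Reading, validation, and harmonisation of surface net-tow records.

A "tow" is one horizontal surface trawl with a plankton net. Records are
held in a :class:`pandas.DataFrame` following :data:`TOWDB_COLUMNS`;
harmonisation converts areal concentrations to volumetric units, derives
tow volumes from net geometry, and attaches per-record detection limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "MESH_PLAUSIBLE_UM",
    "RELIABILITY_WEIGHTS",
    "ReliabilityChecklist",
    "RowIssue",
    "areal_to_volumetric",
    "compute_sample_volume",
    "detection_limit",
    "harmonise_towdb",
    "read_towdb",
    "reliability_score",
    "round_to_sigfigs",
    "validate_towdb",
    "write_towdb",
]

HABITATS = ("lake", "river", "marine_estuarine")

#: mesh sizes (um) outside this window are flagged as implausible
MESH_PLAUSIBLE_UM = (45.0, 780.0)

TOWDB_COLUMNS = [
    "study_id",
    "habitat",
    "mesh_size_um",
    "net_mouth_diameter_m",
    "tow_distance_m",
    "volume_m3",
    "concentration_per_m3",
    "detection_limit_per_m3",
    "lake_area_km2",
    "latitude_deg",
]

_OPTIONAL = {"net_mouth_diameter_m", "tow_distance_m", "lake_area_km2", "latitude_deg"}


def compute_sample_volume(mouth_diameter_m: float, tow_distance_m: float) -> float:
    """Volume of water filtered by one tow, in litres.

    Mouth area of a fully submerged circular net times tow distance:
    ``pi * (d/2)**2 * distance * 1000``.
    """
    if mouth_diameter_m <= 0:
        raise ValueError("net mouth diameter must be positive")
    if tow_distance_m < 0:
        raise ValueError("tow distance cannot be negative")
    return math.pi * (mouth_diameter_m / 2.0) ** 2 * tow_distance_m * 1000.0


def round_to_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Round to ``sigfigs`` significant figures (0 maps to 0)."""
    if x == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (magnitude - sigfigs + 1)
    return round(x / factor) * factor


def areal_to_volumetric(
    concentration_per_km2: float,
    mouth_diameter_m: float,
    submerged_fraction: float = 1.0,
) -> float:
    """Convert an areal concentration (km^-2) to volumetric (m^-3).

    Over a transect, the particle count is ``C_A * width * distance`` and
    the filtered volume is ``mouth_area * distance``; taking the transect
    width equal to the mouth diameter gives
    ``C_V = C_A * 4 / (pi * d * f)`` with ``C_A`` in m^-2 and ``f`` the
    submerged fraction of the circular mouth.
    """
    if mouth_diameter_m <= 0:
        raise ValueError("net mouth diameter must be positive")
    if not 0 < submerged_fraction <= 1:
        raise ValueError("submerged_fraction must be in (0, 1]")
    c_per_m2 = concentration_per_km2 / 1e6
    return c_per_m2 * 4.0 / (math.pi * mouth_diameter_m * submerged_fraction)


def detection_limit(volume_m3: float) -> float:
    """Smallest observable nonzero concentration: one particle per tow volume."""
    if volume_m3 <= 0:
        raise ValueError("tow volume must be positive")
    return 1.0 / volume_m3


@dataclass(frozen=True)
class ReliabilityChecklist:
    """Seven-item methods-reliability rubric (weights 2,2,2,2,1,1,1)."""

    reproducible_sampling: bool
    trawled_over_500L: bool
    precombusted_storage: bool
    lab_contamination_mitigation: bool
    airborne_mitigation_with_controls: bool
    negative_controls: bool
    polymer_id_subset: bool


RELIABILITY_WEIGHTS = (2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0)


def reliability_score(checklist: ReliabilityChecklist) -> float:
    """Weighted sum of rubric awards; all items true scores 11.00."""
    items = [getattr(checklist, f.name) for f in fields(ReliabilityChecklist)]
    for f, v in zip(fields(ReliabilityChecklist), items):
        if not isinstance(v, (bool, np.bool_)):
            raise TypeError(f"checklist item {f.name!r} must be boolean")
    return float(sum(w * bool(v) for w, v in zip(RELIABILITY_WEIGHTS, items)))


@dataclass(frozen=True)
class RowIssue:
    row: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.column}: {self.message}"


def _to_number(value):
    """Parse a cell that may use a decimal comma; unparseable -> NaN."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    text = str(value).strip()
    if not text or text.lower() in {"na", "nan", ""}:
        return np.nan
    try:
        return float(text)
    except ValueError:
        try:
            return float(text.replace(",", "."))
        except ValueError:
            return np.nan


def validate_towdb(df: pd.DataFrame) -> list[RowIssue]:
    """Check per-row invariants; returns one issue per violation.

    Row numbers are 0-based positions in the frame.
    """
    issues: list[RowIssue] = []
    for pos in range(len(df)):
        row = df.iloc[pos]
        habitat = row.get("habitat")
        if habitat not in HABITATS:
            issues.append(RowIssue(pos, "habitat", f"unknown habitat label {habitat!r}"))
        mesh = _to_number(row.get("mesh_size_um"))
        if np.isnan(mesh):
            issues.append(RowIssue(pos, "mesh_size_um", "non-numeric mesh size"))
        elif mesh <= 0:
            issues.append(RowIssue(pos, "mesh_size_um", "mesh size must be positive"))
        elif not MESH_PLAUSIBLE_UM[0] <= mesh <= MESH_PLAUSIBLE_UM[1]:
            issues.append(
                RowIssue(
                    pos,
                    "mesh_size_um",
                    f"mesh {mesh:g} um outside plausibility window "
                    f"{MESH_PLAUSIBLE_UM[0]:g}-{MESH_PLAUSIBLE_UM[1]:g} um",
                )
            )
        volume = _to_number(row.get("volume_m3"))
        if not np.isnan(volume) and volume <= 0:
            issues.append(RowIssue(pos, "volume_m3", "tow volume must be positive"))
        conc = _to_number(row.get("concentration_per_m3"))
        if not np.isnan(conc) and conc < 0:
            issues.append(RowIssue(pos, "concentration_per_m3", "negative concentration"))
    return issues


def harmonise_towdb(df: pd.DataFrame, submerged_fraction: float = 1.0) -> pd.DataFrame:
    """Fill volumes, convert areal units, and attach detection limits.

    * missing ``volume_m3`` is derived from net geometry when available;
    * a ``concentration_per_km2`` column, when present, is converted to
      ``concentration_per_m3`` for rows missing the volumetric value
      (rows without geometry are left missing, never guessed);
    * missing ``detection_limit_per_m3`` defaults to one particle per tow
      volume (overridable per record by supplying the column).
    """
    out = df.copy()
    for col in TOWDB_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    numeric_cols = [c for c in TOWDB_COLUMNS if c not in {"study_id", "habitat"}]
    for col in numeric_cols:
        out[col] = out[col].map(_to_number)
    if "concentration_per_km2" in out.columns:
        out["concentration_per_km2"] = out["concentration_per_km2"].map(_to_number)

    geom_ok = (out["net_mouth_diameter_m"] > 0) & (out["tow_distance_m"] >= 0)
    need_volume = out["volume_m3"].isna() & geom_ok
    if need_volume.any():
        litres = [
            compute_sample_volume(d, dist)
            for d, dist in zip(
                out.loc[need_volume, "net_mouth_diameter_m"],
                out.loc[need_volume, "tow_distance_m"],
            )
        ]
        out.loc[need_volume, "volume_m3"] = np.asarray(litres) / 1000.0

    if "concentration_per_km2" in out.columns:
        convertible = (
            out["concentration_per_m3"].isna()
            & out["concentration_per_km2"].notna()
            & (out["net_mouth_diameter_m"] > 0)
        )
        out.loc[convertible, "concentration_per_m3"] = [
            areal_to_volumetric(c, d, submerged_fraction)
            for c, d in zip(
                out.loc[convertible, "concentration_per_km2"],
                out.loc[convertible, "net_mouth_diameter_m"],
            )
        ]

    need_limit = out["detection_limit_per_m3"].isna() & (out["volume_m3"] > 0)
    out.loc[need_limit, "detection_limit_per_m3"] = 1.0 / out.loc[need_limit, "volume_m3"]
    return out


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_towdb(path, strict: bool = True, harmonise: bool = True) -> pd.DataFrame:
    """Read a delimited tow database; validates and (optionally) harmonises.

    With ``strict=True`` any invariant violation raises a ``ValueError``
    listing offending rows; otherwise offending rows are dropped and the
    issues attached as ``df.attrs['issues']``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if harmonise:
        df = harmonise_towdb(df)
    issues = validate_towdb(df)
    if issues:
        if strict:
            details = "; ".join(str(i) for i in issues[:20])
            raise ValueError(f"{len(issues)} invalid tow record(s): {details}")
        bad = sorted({i.row for i in issues})
        df = df.drop(df.index[bad]).reset_index(drop=True)
    df.attrs["issues"] = issues
    return df


def write_towdb(df: pd.DataFrame, path, sep: str = "\t") -> None:
    cols = [c for c in TOWDB_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep=sep, index=False)
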