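"""Stomatal density and anatomical maximum stomatal conductance.

Anatomical g_smax is the theoretical ceiling on diffusive conductance set by
stomatal dimensions and density, from the standard diffusion equation

    g_smax = d · SD · a_max / ( v · ( l + (π/2)·√(a_max/π) ) )

with d the diffusivity of water vapour in air (m² s⁻¹), v the molar volume of
air (m³ mol⁻¹), SD stomatal density (m⁻²), a_max the maximal pore area (m²)
and l the pore depth (m).  The pore is modelled as an ellipse whose major
axis equals the pore length p and whose minor axis is p/2, so
a_max = π·p²/8; pore depth is taken as a quarter of the guard-cell length.
The √(a_max/π) term is the radius of the circle of equal area — the end
correction of the diffusion path.

Leaf-level g_smax sums the two surfaces: the abaxial and adaxial stomatal
populations are conductances in parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import AnatomyRecord, Constants

__all__ = [
    "GsmaxResult",
    "stomatal_density",
    "accession_density",
    "pore_area_max",
    "anatomical_gsmax",
    "leaf_gsmax",
    "gsmax_table",
    "UM2_TO_M2",
    "MM2_TO_M2",
]

UM2_TO_M2 = 1e-12
MM2_TO_M2 = 1e-6  # mm⁻² → m⁻² multiplies by 1e6; area mm² → m² by 1e-6


@dataclass(frozen=True)
class GsmaxResult:
    """Anatomical g_smax for one leaf surface, with the SI inputs used."""

    surface: str
    SD: float           # stomata m⁻²
    a_max: float        # m²
    pore_depth_l: float  # m
    gsmax: float        # mol m⁻² s⁻¹

    def __post_init__(self) -> None:
        for name in ("SD", "a_max", "pore_depth_l", "gsmax"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def stomatal_density(records: Iterable[AnatomyRecord]) -> pd.DataFrame:
    """Pooled stomatal density per (plant, surface).

    Counts and areas are pooled over all fields of view of a plant-surface
    (SD = Σcounts/Σareas), which weights fields by their area.  Returns a
    DataFrame with columns accession, plant_id, surface, n_fields, SD_mm2,
    SD_m2.
    """
    rows = [
        (r.accession, r.plant_id, r.surface, r.field_count, r.field_area)
        for r in records
    ]
    if not rows:
        raise ValueError("no anatomy records given")
    df = pd.DataFrame(rows, columns=["accession", "plant_id", "surface", "count", "area"])
    grouped = df.groupby(["accession", "plant_id", "surface"], sort=True).agg(
        n_fields=("count", "size"), total_count=("count", "sum"), total_area=("area", "sum")
    ).reset_index()
    if (grouped["total_area"] <= 0).any():
        bad = grouped.loc[grouped["total_area"] <= 0].iloc[0]
        raise ValueError(
            f"plant {bad['plant_id']!r} surface {bad['surface']!r}: zero total field area"
        )
    grouped["SD_mm2"] = grouped["total_count"] / grouped["total_area"]
    grouped["SD_m2"] = grouped["SD_mm2"] * 1e6
    return grouped.drop(columns=["total_count", "total_area"])


def accession_density(density: pd.DataFrame) -> pd.DataFrame:
    """Per-accession surface means of plant-level stomatal densities."""
    return (
        density.groupby(["accession", "surface"], sort=True)
        .agg(n_plants=("plant_id", "nunique"), SD_mm2=("SD_mm2", "mean"), SD_m2=("SD_m2", "mean"))
        .reset_index()
    )


def pore_area_max(pore_length_um) -> float | np.ndarray:
    """Maximal pore area (m²) of an elliptical pore of length p µm.

    Semi-axes p/2 and p/4 give a_max = π·p²/8.
    """
    p = np.asarray(pore_length_um, dtype=float)
    if np.any(p <= 0):
        raise ValueError(f"pore length must be positive, got {pore_length_um}")
    a = math.pi * p**2 / 8.0 * UM2_TO_M2
    return float(a) if np.isscalar(pore_length_um) else a


def anatomical_gsmax(
    SD: float,
    pore_length_um: float,
    guard_cell_length_um: float,
    consts: Constants = Constants(),
    surface: str = "abaxial",
) -> GsmaxResult:
    """Anatomical maximum stomatal conductance for one surface.

    Parameters
    ----------
    SD : float
        Stomatal density in m⁻² (mm⁻² values must be converted first; inputs
        below 10⁶ m⁻² are rejected as almost certainly mm⁻²).
    pore_length_um, guard_cell_length_um : float
        Pore and guard-cell lengths in µm; pore depth l = guard-cell length/4.
    """
    if not (SD > 0 and pore_length_um > 0 and guard_cell_length_um > 0):
        raise ValueError("SD, pore length and guard-cell length must all be positive")
    if SD < 1e6:
        raise ValueError(
            f"SD={SD:g} m⁻² is implausibly low — was a mm⁻² value passed? "
            f"(multiply by 1e6 to convert)"
        )
    a_max = pore_area_max(pore_length_um)
    l = guard_cell_length_um / 4.0 * 1e-6
    gsmax = (consts.d * SD * a_max) / (consts.v * (l + (math.pi / 2.0) * math.sqrt(a_max / math.pi)))
    return GsmaxResult(surface=surface, SD=float(SD), a_max=a_max, pore_depth_l=l, gsmax=float(gsmax))


def leaf_gsmax(ab: GsmaxResult, ad: GsmaxResult) -> float:
    """Leaf-level anatomical g_smax: the two surfaces conduct in parallel, so add."""
    if ab is None or ad is None:
        raise ValueError("both abaxial and adaxial results are required for leaf g_smax")
    return ab.gsmax + ad.gsmax


def gsmax_table(
    records: Iterable[AnatomyRecord],
    consts: Constants = Constants(),
) -> pd.DataFrame:
    """Per-plant anatomical g_smax from raw anatomy records.

    Geometry (pore and guard-cell length) is averaged over the measured
    stomata of each plant-surface *before* applying the conductance equation.
    Returns one row per plant with per-surface densities and g_smax plus the
    leaf-level (summed) value; plants lacking geometry on a surface get NaN.
    """
    records = list(records)
    density = stomatal_density(records)
    geom_rows = [
        (r.accession, r.plant_id, r.surface, r.guard_cell_length, r.pore_length)
        for r in records
        if r.guard_cell_length is not None and r.pore_length is not None
    ]
    geom = pd.DataFrame(geom_rows, columns=["accession", "plant_id", "surface", "gcl", "pore"])
    if len(geom):
        geom = geom.groupby(["accession", "plant_id", "surface"], sort=True).mean().reset_index()
        merged = density.merge(geom, on=["accession", "plant_id", "surface"], how="left")
    else:
        merged = density.assign(gcl=np.nan, pore=np.nan)

    gsmax_vals = []
    for _, row in merged.iterrows():
        if np.isfinite(row["gcl"]) and np.isfinite(row["pore"]):
            gsmax_vals.append(
                anatomical_gsmax(row["SD_m2"], row["pore"], row["gcl"], consts,
                                 surface=row["surface"]).gsmax
            )
        else:
            gsmax_vals.append(np.nan)
    merged["gsmax"] = gsmax_vals

    wide = merged.pivot_table(
        index=["accession", "plant_id"],
        columns="surface",
        values=["SD_mm2", "gsmax"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{'ab' if b == 'abaxial' else 'ad'}" for a, b in wide.columns]
    wide = wide.reset_index()
    if "gsmax_ab" in wide and "gsmax_ad" in wide:
        wide["gsmax_leaf"] = wide["gsmax_ab"] + wide["gsmax_ad"]
    else:
        wide["gsmax_leaf"] = np.nan
    return wide
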