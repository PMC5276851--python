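"""Steady-state ammonia-oxidizer biomass model for a fluidized sand biofilter.

The model asks whether the ammonia removed across the biofilter can support
the standing stock of ammonia-oxidizing microorganisms (AOM) measured by
qPCR. At steady state the ammonia-oxidizer biomass concentration is

    X_AO = (theta_x / theta) * [Y_AO / (1 + b_AO * theta_x)] * dS_NH3

where theta is the hydraulic retention time (d), theta_x the mean cell
residence time (MCRT, d), Y_AO the growth yield (kg VSS per kg NH4+-N),
b_AO the endogenous respiration constant (1/d) and dS_NH3 the
influent-minus-effluent ammonia-N removal (mg/L). X_AO (mg VSS/L) is
converted to cells per litre through a spherical cell biovolume and a
cellular carbon density, then to cells per gram of wet sand through the
sand loading (grams of sand per litre of biofilter water).

Because the true MCRT of a fluidized sand bed is unknown, the model is
swept over a grid of candidate MCRTs; an envelope from the minimum and
maximum observed removal rates brackets the mean curve.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AOMModelParams",
    "BiofilterGeometry",
    "BiomassCurve",
    "AMOA_ASSAYS",
    "delta_substrate",
    "steady_state_biomass",
    "cell_volume",
    "biomass_to_cells",
    "cells_per_gram",
    "mcrt_sweep",
    "observed_aom_total",
    "model_observed_ratio",
    "hydraulic_retention_time",
]

#: mg of N per litre for a 1 uM solution of an N(1) species (14.007 g/mol).
MG_N_PER_L_PER_UM = 0.014007

#: The amoA-bearing (ammonia-oxidizing) assays whose copy numbers sum to
#: total AOM abundance: total archaeal amoA, the two Nitrosomonas amoA
#: genotypes, and comammox Nitrospira amoA.
AMOA_ASSAYS = ("aoa_total", "nitroso_1", "nitroso_2", "comammox")


@dataclass
class AOMModelParams:
    """Parameters of the steady-state AOM biomass model.

    Defaults reproduce the published configuration for the UWM biofilter:
    HRT 0.0066 d (~9.52 min), yield 0.34 kg VSS per kg NH4+-N, endogenous
    respiration 0.15 1/d, 0.96 um cell diameter (Ca. Nitrosocosmicus
    franklandus), 310 fg C/um^3 carbon density. ``sand_loading`` has no
    published value; 40.4 g/L is a calibration chosen so the mean model
    curve at a 20-day MCRT sits ~6.2x above the depth-averaged qPCR AOM
    total (see docs/methods.md) — treat it as illustrative, not measured.
    ``vss_to_carbon`` defaults to 1.0, i.e. the carbon density is applied
    directly to the VSS-based biomass; a literature VSS->C fraction (~0.53)
    can be supplied instead.
    """

    theta: float = 0.0066  # hydraulic retention time, d
    Y_AO: float = 0.34  # growth yield, kg VSS / kg NH4+-N
    b_AO: float = 0.15  # endogenous respiration, 1/d
    delta_S_NH3: float = 0.0726  # ammonia-N removal, mg/L
    cell_diameter: float = 0.96  # um
    carbon_density: float = 310.0  # fg C / um^3
    vss_to_carbon: float = 1.0  # fraction of VSS treated as cell carbon
    sand_loading: float = 40.4  # g wet sand per L biofilter water
    amoA_copies_per_cell: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "theta",
            "Y_AO",
            "b_AO",
            "cell_diameter",
            "carbon_density",
            "sand_loading",
            "amoA_copies_per_cell",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.delta_S_NH3 < 0:
            raise ValueError("delta_S_NH3 must be >= 0")
        if not 0 < self.vss_to_carbon <= 1:
            raise ValueError("vss_to_carbon must be in (0, 1]")


@dataclass
class BiofilterGeometry:
    """Cylindrical biofilter geometry. Heights and diameter in metres,
    flow in litres per minute."""

    height: float = 2.74
    diameter: float = 1.83
    water_level: float = 2.64
    sand_height: float = 1.73
    max_flow: float = 757.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if not 0 < self.water_level <= self.height:
            raise ValueError("water_level must satisfy 0 < water_level <= height")
        if self.max_flow <= 0:
            raise ValueError("max_flow must be > 0")


@dataclass
class BiomassCurve:
    """Model output over an MCRT grid, unit-converted to cells per gram."""

    mcrt_grid: np.ndarray  # d
    X_AO: np.ndarray  # mg VSS / L
    cells_per_liter: np.ndarray
    cells_per_gram: np.ndarray
    envelope_low: np.ndarray  # cells/g from minimum observed removal
    envelope_high: np.ndarray  # cells/g from maximum observed removal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_x_days": self.mcrt_grid,
                "X_AO_mg_per_L": self.X_AO,
                "cells_per_L": self.cells_per_liter,
                "cells_per_g": self.cells_per_gram,
                "envelope_low_cells_per_g": self.envelope_low,
                "envelope_high_cells_per_g": self.envelope_high,
            }
        )

    def at(self, theta_x: float) -> float:
        """Cells/g at theta_x, linearly interpolated within the grid."""
        grid = self.mcrt_grid
        if not grid[0] <= theta_x <= grid[-1]:
            raise ValueError(f"theta_x={theta_x} outside grid [{grid[0]}, {grid[-1]}]")
        return float(np.interp(theta_x, grid, self.cells_per_gram))


def delta_substrate(influent_uM: float, effluent_uM: float) -> float:
    """Ammonia-N removal in mg N/L from influent/effluent totals in uM.

    A negative difference (effluent above influent) is clamped to zero
    with a warning: the steady-state model has no meaning for net ammonia
    production across the filter.
    """
    if influent_uM < 0 or effluent_uM < 0:
        raise ValueError("concentrations must be >= 0")
    diff = influent_uM - effluent_uM
    if diff < 0:
        warnings.warn(
            f"effluent ammonia ({effluent_uM} uM) exceeds influent "
            f"({influent_uM} uM); clamping removal to 0",
            stacklevel=2,
        )
        diff = 0.0
    return diff * MG_N_PER_L_PER_UM


def steady_state_biomass(params: AOMModelParams, theta_x: float) -> float:
    """X_AO (mg VSS/L) at mean cell residence time ``theta_x`` (days)."""
    if theta_x <= 0:
        raise ValueError("theta_x must be > 0")
    return (
        (theta_x / params.theta)
        * (params.Y_AO / (1.0 + params.b_AO * theta_x))
        * params.delta_S_NH3
    )


def steady_state_limit(params: AOMModelParams) -> float:
    """X_AO limit as theta_x -> infinity: Y_AO * dS / (b_AO * theta)."""
    return params.Y_AO * params.delta_S_NH3 / (params.b_AO * params.theta)


def cell_volume(diameter: float) -> float:
    """Biovolume (um^3) of a spherical cell of the given diameter (um)."""
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi / 6.0 * diameter**3


def biomass_to_cells(X_AO: float, params: AOMModelParams) -> float:
    """Convert biomass (mg VSS/L) to cells per litre.

    mg/L -> fg/L (1e12), optionally discounted to carbon via
    ``vss_to_carbon``, divided by per-cell carbon content
    (carbon_density * cell biovolume).
    """
    if X_AO < 0:
        raise ValueError("X_AO must be >= 0")
    vol = cell_volume(params.cell_diameter)
    if vol == 0:
        raise ValueError("cell volume is zero; cannot convert biomass to cells")
    fg_per_cell = params.carbon_density * vol
    return X_AO * 1e12 * params.vss_to_carbon / fg_per_cell


def cells_per_gram(cells_per_liter: float, sand_loading: float) -> float:
    """Cells per gram wet sand given sand loading in g sand / L water."""
    if sand_loading <= 0:
        raise ValueError("sand_loading must be > 0")
    return cells_per_liter / sand_loading


def mcrt_sweep(
    params: AOMModelParams,
    grid: Sequence[float] | None = None,
    *,
    deltaS_min: float | None = None,
    deltaS_mean: float | None = None,
    deltaS_max: float | None = None,
) -> BiomassCurve:
    """Sweep the model over an MCRT grid (default 1-30 days).

    The mean curve uses ``deltaS_mean`` (default: params.delta_S_NH3); the
    envelope re-evaluates the model at the minimum and maximum observed
    removal rates.
    """
    g = np.asarray(grid if grid is not None else np.arange(1.0, 31.0), dtype=float)
    if g.size == 0:
        raise ValueError("MCRT grid is empty")
    if np.any(g <= 0) or np.any(np.diff(g) <= 0):
        raise ValueError("MCRT grid must be strictly increasing and positive")
    ds_mean = params.delta_S_NH3 if deltaS_mean is None else deltaS_mean
    ds_min = ds_mean if deltaS_min is None else deltaS_min
    ds_max = ds_mean if deltaS_max is None else deltaS_max

    def curve_cells_per_g(ds: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = AOMModelParams(**{**params.__dict__, "delta_S_NH3": ds})
        x = np.array([steady_state_biomass(p, t) for t in g])
        cl = np.array([biomass_to_cells(v, p) for v in x])
        cg = cl / params.sand_loading
        return x, cl, cg

    x_mean, cl_mean, cg_mean = curve_cells_per_g(ds_mean)
    _, _, cg_low = curve_cells_per_g(ds_min)
    _, _, cg_high = curve_cells_per_g(ds_max)
    return BiomassCurve(g, x_mean, cl_mean, cg_mean, cg_low, cg_high)


def observed_aom_total(
    markers: pd.DataFrame,
    params: AOMModelParams | None = None,
    *,
    assays: Sequence[str] = AMOA_ASSAYS,
) -> tuple[float, pd.Series]:
    """Total observed AOM abundance from the amoA qPCR assays.

    ``markers`` is the long marker table (assay, sample_id, cn_per_g).
    Copy numbers of all amoA assays are summed within each sample; the
    summary value is the mean of those per-sample sums. Returns
    ``(mean, per-sample sums)`` in CN/g, or in cells/g (CN divided by
    ``amoA_copies_per_cell``) when ``params`` is given — with the default
    single-copy amoA assumption the two scales coincide.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    present = set(markers["assay"].unique())
    missing = [a for a in assays if a not in present]
    if missing:
        warnings.warn(f"amoA assays missing from table: {missing}", stacklevel=2)
    use = [a for a in assays if a in present]
    if not use:
        raise ValueError("no amoA assays present in marker table")
    sub = markers[markers["assay"].isin(use)]
    per_sample = sub.groupby("sample_id")["cn_per_g"].sum()
    if params is not None:
        per_sample = per_sample / params.amoA_copies_per_cell
    return float(per_sample.mean()), per_sample


def model_observed_ratio(
    curve: BiomassCurve, observed_cells_per_g: float, theta_x: float
) -> float:
    """Model-to-observed cell abundance ratio at a chosen MCRT."""
    if observed_cells_per_g <= 0:
        raise ValueError("observed abundance must be > 0")
    return curve.at(theta_x) / observed_cells_per_g


def hydraulic_retention_time(
    geometry: BiofilterGeometry, *, use_water_level: bool = False
) -> tuple[float, float]:
    """HRT of the biofilter as ``(minutes, days)``.

    Cylinder volume pi*(d/2)^2*h in litres divided by maximum flow. By
    default the full column height is used, which reproduces the reported
    ~9.52 min for the UWM geometry; ``use_water_level=True`` substitutes
    the water level (~9.17 min).
    """
    h = geometry.water_level if use_water_level else geometry.height
    volume_l = math.pi * (geometry.diameter / 2.0) ** 2 * h * 1000.0
    minutes = volume_l / geometry.max_flow
    return minutes, minutes / 1440.0
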