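"""Annual cropland WUE pipeline: daily GPP and MR -> annual NPP -> WUE rasters.

The production sequence mirrors the three-step workflow: (1) daily ET is
summed to an annual total; (2) daily GPP from the EF-LUE model and daily
maintenance respiration are summed and closed into annual NPP; (3) the
annual WUE = NPP/ET ratio is computed on cropland pixels, with the
cropland mask from a fine land-cover grid by the strict >50% majority
rule and WUE values above 50 g C/kg H2O/yr masked as outliers.

Two execution modes share the same numerical kernels: a site mode over a
single daily record (used for calibration/validation) and a raster mode
over small daily grid stacks, which writes single-band float32 GeoTIFFs
in EPSG:4326.  In-memory grids use NaN for missing values; files use the
-9999 sentinel.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ZoneParameterTable
from .geotiff import NODATA, GeoTransform, write_geotiff
from .lue import DailyForcing, gpp_from_arrays
from .params import LUEParameters, RespirationConstants
from .respiration import annual_npp, daily_mr

__all__ = [
    "AnnualGrid",
    "CroplandMask",
    "RasterInputs",
    "aggregate_majority",
    "resample_average",
    "annual_sum",
    "compute_wue",
    "run_annual_site",
    "run_annual_raster",
    "run_annual",
    "WUE_OUTLIER_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Annual WUE above this value (g C/kg H2O/yr) is treated as an outlier.
WUE_OUTLIER_THRESHOLD = 50.0


@dataclass
class AnnualGrid:
    """A georeferenced annual raster (NPP, ET or WUE) for one calendar year.

    ``values`` is a 2-D float array with NaN marking nodata in memory;
    the ``nodata`` sentinel is applied on file write.
    """

    values: np.ndarray
    transform: GeoTransform
    year: int
    units: str = ""
    crs: str = "EPSG:4326"
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("AnnualGrid values must be 2-D")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def congruent_with(self, other: "AnnualGrid") -> bool:
        return (self.values.shape == other.values.shape
                and self.transform == other.transform
                and self.year == other.year)

    def write(self, path) -> None:
        write_geotiff(path, self.values, self.transform, self.nodata)


@dataclass
class CroplandMask:
    """1-km cropland mask plus the fine-grid coverage fraction it came from."""

    mask: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.mask.shape != self.fraction.shape:
            raise ValueError("mask and fraction must share a shape")


def _blocks(fine: np.ndarray, factor: int) -> np.ndarray:
    rows, cols = fine.shape
    if rows % factor or cols % factor:
        raise ValueError(f"fine grid {fine.shape} not divisible by factor {factor}")
    return fine.reshape(rows // factor, factor, cols // factor, factor)


def aggregate_majority(fine_grid: np.ndarray, factor: int,
                       cropland_class: int = 1) -> CroplandMask:
    """Majority aggregation of a fine land-cover grid to the analysis grid.

    A coarse cell is cropland iff the fraction of its fine cells in the
    cropland class is strictly greater than 0.5 (exactly half is not
    cropland).
    """
    is_crop = (np.asarray(fine_grid) == cropland_class).astype(float)
    fraction = _blocks(is_crop, factor).mean(axis=(1, 3))
    return CroplandMask(mask=fraction > 0.5, fraction=fraction)


def resample_average(fine_grid: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a continuous fine grid to the analysis grid.

    NaN cells are excluded from each block mean; an all-NaN block stays
    NaN.
    """
    blocks = _blocks(np.asarray(fine_grid, dtype=float), factor)
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(blocks)
        total = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
        count = valid.sum(axis=(1, 3))
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


def _check_days(n: int, year: int | None) -> None:
    if year is not None:
        expected = 366 if _is_leap(year) else 365
        if n != expected:
            raise ValueError(f"year {year} needs {expected} daily layers, got {n}")
    elif n not in (365, 366):
        raise ValueError(f"need a whole calendar year of layers, got {n}")


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def annual_sum(daily_stack: np.ndarray, transform: GeoTransform, year: int,
               units: str = "", strict: bool = True) -> AnnualGrid:
    """Per-pixel annual total of a (n_days, rows, cols) daily stack.

    In strict mode (default) a pixel with any missing day is nodata; in
    tolerant mode available days are summed and the coverage count is
    logged.
    """
    stack = np.asarray(daily_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("daily stack must be (n_days, rows, cols)")
    _check_days(stack.shape[0], year)
    if strict:
        values = stack.sum(axis=0)
    else:
        values = np.nansum(stack, axis=0)
        coverage = np.isfinite(stack).sum(axis=0)
        values = np.where(coverage > 0, values, np.nan)
        logger.info("annual_sum: tolerant mode, min/median coverage %d/%d days",
                    int(coverage.min()), int(np.median(coverage)))
    return AnnualGrid(values=values, transform=transform, year=year, units=units)


def compute_wue(npp: AnnualGrid, et: AnnualGrid, mask: CroplandMask,
                threshold: float = WUE_OUTLIER_THRESHOLD) -> AnnualGrid:
    """Annual WUE = NPP/ET (g C/kg H2O/yr) on cropland pixels.

    1 mm of water over 1 m2 is 1 kg, so NPP in g C/m2/yr over ET in
    mm/yr is directly g C per kg of water.  Non-cropland pixels, zero-ET
    pixels and WUE values above ``threshold`` become nodata.
    """
    if not npp.congruent_with(et):
        raise ValueError("NPP and ET grids are not congruent")
    if mask.mask.shape != npp.values.shape:
        raise ValueError("cropland mask shape mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        wue = npp.values / et.values
    bad = (~mask.mask) | ~np.isfinite(wue) | (et.values <= 0) | (wue > threshold)
    n_outlier = int(np.sum(np.isfinite(wue) & (wue > threshold) & mask.mask))
    n_zero_et = int(np.sum(mask.mask & np.isfinite(npp.values) & (et.values <= 0)))
    if n_outlier or n_zero_et:
        logger.info("compute_wue: masked %d outlier (>%g) and %d zero-ET pixels",
                    n_outlier, threshold, n_zero_et)
    wue = np.where(bad, np.nan, wue)
    return AnnualGrid(values=wue, transform=npp.transform, year=npp.year,
                      units="g C/kg H2O/yr")


@dataclass
class RasterInputs:
    """One year of daily driver stacks plus static grids for raster mode.

    Daily stacks are (n_days, rows, cols); vegetation composites are
    (n_nodes, rows, cols) at their 8-day node dates.  ``fine_landcover``
    is the fine class grid (1 = cropland) at ``fine_factor`` times the
    analysis resolution.
    """

    year: int
    dates: pd.DatetimeIndex
    ta: np.ndarray
    td: np.ndarray
    sw: np.ndarray
    et: np.ndarray
    rn: np.ndarray
    g: np.ndarray
    veg_dates: pd.DatetimeIndex
    fapar_8day: np.ndarray
    lai_8day: np.ndarray
    zone_map: np.ndarray
    fine_landcover: np.ndarray
    fine_factor: int
    transform: GeoTransform

    @property
    def shape(self) -> tuple[int, int]:
        return self.zone_map.shape


def _interp_stack(node_days: np.ndarray, node_stack: np.ndarray,
                  out_days: np.ndarray) -> np.ndarray:
    """Linear interpolation of a (n_nodes, r, c) stack along time.

    Terminal values are held constant outside the node range (same
    convention as the site-mode 8-day interpolation).
    """
    node_days = np.asarray(node_days, dtype=float)
    out_days = np.asarray(out_days, dtype=float)
    idx = np.clip(np.searchsorted(node_days, out_days, side="right") - 1,
                  0, len(node_days) - 2)
    d0, d1 = node_days[idx], node_days[idx + 1]
    w = np.clip((out_days - d0) / (d1 - d0), 0.0, 1.0)
    w = w[:, None, None]
    return (1.0 - w) * node_stack[idx] + w * node_stack[idx + 1]


def run_annual_site(record, params: LUEParameters,
                    consts: RespirationConstants = RespirationConstants(),
                    year: int | None = None,
                    wue_threshold: float = WUE_OUTLIER_THRESHOLD) -> dict:
    """Site-mode annual run for one daily record under one parameter set.

    Returns per-stage outputs: daily GPP and MR series, the annual carbon
    budget, the annual ET sum and the annual WUE (NaN where ET is zero or
    WUE exceeds the outlier threshold).
    """
    frame = record.data if hasattr(record, "data") else record
    if year is not None:
        frame = frame[frame.index.year == year]
    forcing = DailyForcing.from_frame(frame)
    gpp = gpp_from_arrays(forcing.ta, forcing.td, forcing.sw, forcing.et,
                          forcing.rn, forcing.g, forcing.fapar, params)
    mr = daily_mr(forcing.lai, forcing.ta, consts)
    budget = annual_npp(gpp, mr, consts, year=year)
    et_sum = float(np.sum(forcing.et))
    if et_sum > 0:
        wue = budget.npp / et_sum
        if wue > wue_threshold:
            logger.info("site WUE %.2f exceeds %g: masked", wue, wue_threshold)
            wue = math.nan
    else:
        wue = math.nan
    return {
        "gpp_daily": pd.Series(gpp, index=frame.index),
        "mr_daily": pd.Series(mr, index=frame.index),
        "budget": budget,
        "gpp_sum": budget.gpp_sum,
        "mr_sum": budget.mr_sum,
        "npp": budget.npp,
        "et_sum": et_sum,
        "wue": wue,
    }


def run_annual_raster(inputs: RasterInputs, table: ZoneParameterTable,
                      consts: RespirationConstants = RespirationConstants(),
                      out_dir=None, strict: bool = True,
                      wue_threshold: float = WUE_OUTLIER_THRESHOLD
                      ) -> dict[str, AnnualGrid]:
    """Raster-mode annual run: daily stacks -> annual GPP/MR/NPP/ET/WUE grids.

    Per-pixel parameters come from the climate-zone map through the
    calibrated lookup (Default fallback for unlisted codes); the kernels
    are evaluated zone by zone with the same code path as site mode, so a
    one-pixel raster reproduces the site-mode numbers.  If ``out_dir`` is
    given, each annual grid is written as ``<var>_<year>.tif``.
    """
    t0 = time.perf_counter()
    _check_days(inputs.ta.shape[0], inputs.year)
    rows, cols = inputs.shape
    day_num = inputs.dates.view("int64").astype(float)
    node_num = inputs.veg_dates.view("int64").astype(float)
    fapar = _interp_stack(node_num, inputs.fapar_8day, day_num)
    lai = _interp_stack(node_num, inputs.lai_8day, day_num)
    logger.info("interpolation stage: %.3fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    gpp = np.full(inputs.ta.shape, np.nan)
    for code in np.unique(inputs.zone_map):
        sel = inputs.zone_map == code
        p = table.lookup(str(code))
        gpp[:, sel] = gpp_from_arrays(
            inputs.ta[:, sel], inputs.td[:, sel], inputs.sw[:, sel],
            inputs.et[:, sel], inputs.rn[:, sel], inputs.g[:, sel],
            fapar[:, sel], p)
    mr = daily_mr(lai, inputs.ta, consts)
    logger.info("daily GPP/MR stage: %.3fs", time.perf_counter() - t1)

    t2 = time.perf_counter()
    tr, year = inputs.transform, inputs.year
    gpp_grid = annual_sum(gpp, tr, year, units="g C/m2/yr", strict=strict)
    mr_grid = annual_sum(mr, tr, year, units="g C/m2/yr", strict=strict)
    et_grid = annual_sum(inputs.et, tr, year, units="mm/yr", strict=strict)
    diff = gpp_grid.values - mr_grid.values
    npp_vals = np.maximum(0.0, diff / (1.0 + consts.gr_fraction))
    npp_grid = AnnualGrid(npp_vals, tr, year, units="g C/m2/yr")
    mask = aggregate_majority(inputs.fine_landcover, inputs.fine_factor)
    wue_grid = compute_wue(npp_grid, et_grid, mask, threshold=wue_threshold)
    logger.info("annual aggregation stage: %.3fs (%d nodata WUE pixels)",
                time.perf_counter() - t2, int((~wue_grid.valid).sum()))

    grids = {"gpp": gpp_grid, "mr": mr_grid, "npp": npp_grid,
             "et": et_grid, "wue": wue_grid}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for var, grid in grids.items():
            grid.write(out_dir / f"{var}_{year}.tif")
    return grids


def run_annual(inputs, params_or_table,
               consts: RespirationConstants = RespirationConstants(),
               year: int | None = None, **kwargs):
    """Dispatch to site mode or raster mode based on the input type."""
    if isinstance(inputs, RasterInputs):
        return run_annual_raster(inputs, params_or_table, consts, **kwargs)
    return run_annual_site(inputs, params_or_table, consts, year=year, **kwargs)
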