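"""Synthetic flux-site records and raster stacks for the WUE pipeline.

Real production runs consume reanalysis meteorology, satellite fAPAR/LAI
composites, a daily ET/energy-balance product, a fine land-cover map and
a Koeppen-Geiger climate-zone map.  This module emulates the *structure*
of those inputs — daily drivers with a seasonal cycle, 8-day vegetation
composites with a growing-season hump, block-structured zone maps, a
fine cropland grid aggregated by majority — with physically admissible
ranges, so every downstream stage can be exercised and tested without
downloads.  It makes no attempt to reproduce real-product climatology or
spatial autocorrelation beyond blockiness.

All generators are deterministic functions of their seed: the same seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import ZoneParameterTable, default_zone_table
from .lue import FORCING_COLUMNS, DailyForcing, daily_gpp, interpolate_8day_to_daily
from .params import WATTS_TO_MJ_DAY, LAMBDA_V_MJ_KG, LUEParameters

__all__ = [
    "SyntheticConfig",
    "SiteRecordSet",
    "generate_daily_forcing",
    "generate_vegetation_nodes",
    "generate_site_observations",
    "generate_site_records",
    "generate_fine_landcover",
    "generate_zone_map",
    "generate_raster_inputs",
    "write_site_csv",
    "read_site_csv",
]

#: The climate-zone codes of the calibrated lookup (dry/temperate/continental
#: sub-types where cropland flux sites exist).
DEFAULT_ZONES = ("Bwk", "BSk", "Csa", "Cfa", "Cfb", "Dfa", "Dfb", "Dfc")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world.

    Temporal extent (whole calendar years from ``start_year``), number of
    sites, climate zones present, coarse (analysis) grid shape, the
    integer block factor of the fine land-cover grid, and the
    observation-noise scale as a fraction of mean modelled GPP.
    Seasonal-shape parameters produce mid-latitude cropland magnitudes:
    annual mean air temperature ~12 degC with a 14 degC seasonal
    amplitude (summer daily means approaching 30 degC), shortwave
    5-27 MJ/m2/d, and a summer-peaking evaporative fraction around
    0.45-0.8 with occasional exceedance above 1 to exercise clamping.
    """

    n_years: int = 1
    n_sites: int = 3
    zone_labels: tuple[str, ...] = DEFAULT_ZONES
    grid_shape_1km: tuple[int, int] = (12, 12)
    fine_factor: int = 3
    noise_sd_frac: float = 0.05
    seed: int = 0
    start_year: int = 2001
    # seasonal forcing shape
    ta_mean_c: float = 12.0
    ta_amplitude_c: float = 14.0
    ta_noise_sd_c: float = 2.0
    dew_depression_mean_c: float = 3.0
    sw_mean: float = 16.0
    sw_amplitude: float = 11.0
    ef_mean: float = 0.55
    ef_amplitude: float = 0.25
    ef_noise_sd: float = 0.10
    neg_energy_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.n_sites < 1:
            raise ValueError("n_years and n_sites must be positive")
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if min(self.grid_shape_1km) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


@dataclass
class SiteRecordSet:
    """A flux site's daily record: drivers plus observed GPP.

    ``data`` is a DataFrame with a daily DatetimeIndex covering whole
    calendar years and the forcing columns plus ``gpp_obs`` (g C/m2/d;
    NaN marks missing observations).
    """

    site_id: str
    zone: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValueError("record index must be datetime")
        if len(idx) > 1:
            steps = np.diff(idx.view("int64"))
            if not np.all(steps == steps[0]) or pd.Timedelta(steps[0], "ns") != pd.Timedelta(days=1):
                raise ValueError("record dates must be strictly increasing at a daily step")
        first, last = idx[0], idx[-1]
        if (first.month, first.day) != (1, 1) or (last.month, last.day) != (12, 31):
            raise ValueError("records must cover whole calendar years")
        with np.errstate(invalid="ignore"):
            if np.any(self.data["gpp_obs"].to_numpy(float) < 0):
                raise ValueError("negative observed GPP")

    @property
    def forcing(self) -> DailyForcing:
        return DailyForcing.from_frame(self.data)

    @property
    def gpp_obs(self) -> np.ndarray:
        return self.data["gpp_obs"].to_numpy(float)

    def to_frame(self) -> pd.DataFrame:
        return self.data


def _seasonal(doy: np.ndarray) -> np.ndarray:
    """Unit-amplitude northern-hemisphere seasonal cycle (peak mid-July)."""
    return np.sin(2.0 * np.pi * (doy - 105.0) / 365.25)


def _daily_index(config: SyntheticConfig) -> pd.DatetimeIndex:
    return pd.date_range(f"{config.start_year}-01-01",
                         f"{config.start_year + config.n_years - 1}-12-31",
                         freq="D")


def generate_vegetation_nodes(config: SyntheticConfig, site_index: int
                              ) -> tuple[pd.Series, pd.Series]:
    """8-day fAPAR and LAI composite series with a growing-season hump.

    Nodes fall on days 1, 9, ..., 361 of each year (46 per year, like
    satellite composites).  Returns (fapar_nodes, lai_nodes).
    """
    rng = np.random.default_rng([config.seed, 7, site_index])
    dates = []
    for yr in range(config.start_year, config.start_year + config.n_years):
        base = pd.Timestamp(f"{yr}-01-01")
        dates.extend(base + pd.Timedelta(days=8 * k) for k in range(46))
    idx = pd.DatetimeIndex(dates)
    doy = idx.dayofyear.to_numpy(float)
    scale = rng.uniform(0.80, 1.00)
    hump = np.exp(-(((doy - 200.0) / 55.0) ** 2))
    fapar = np.clip(0.05 + 0.85 * scale * hump
                    + rng.normal(0.0, 0.015, len(idx)), 0.0, 1.0)
    lai = np.clip(6.5 * scale * hump + rng.normal(0.0, 0.08, len(idx)), 0.0, None)
    return pd.Series(fapar, index=idx), pd.Series(lai, index=idx)


def _forcing_frame(config: SyntheticConfig, site_index: int) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 3, site_index])
    idx = _daily_index(config)
    n = len(idx)
    doy = idx.dayofyear.to_numpy(float)
    season = _seasonal(doy)

    ta = config.ta_mean_c + config.ta_amplitude_c * season \
        + rng.normal(0.0, config.ta_noise_sd_c, n)
    dew_dep = np.abs(rng.normal(config.dew_depression_mean_c, 1.5, n))
    td = ta - dew_dep
    sw = np.clip(config.sw_mean + config.sw_amplitude * season
                 + rng.normal(0.0, 2.0, n), 0.0, None)

    # net radiation loosely tracks shortwave; a small fraction of days has
    # negative available energy to exercise the F_W fallback
    rn = 0.55 * sw / WATTS_TO_MJ_DAY + rng.normal(0.0, 8.0, n)
    rn = np.clip(rn, 5.0, None)
    neg = rng.random(n) < config.neg_energy_frac
    rn[neg] = -np.abs(rng.normal(5.0, 2.0, int(neg.sum())))
    g = np.where(rn > 0, 0.1 * rn, 0.0)

    ef = np.clip(config.ef_mean + config.ef_amplitude * season
                 + rng.normal(0.0, config.ef_noise_sd, n), 0.0, 1.04)
    avail_mj = np.clip(rn - g, 0.0, None) * WATTS_TO_MJ_DAY
    et = ef * avail_mj / LAMBDA_V_MJ_KG

    fapar_nodes, lai_nodes = generate_vegetation_nodes(config, site_index)
    fapar = interpolate_8day_to_daily(fapar_nodes, idx).to_numpy()
    lai = interpolate_8day_to_daily(lai_nodes, idx).to_numpy()

    frame = pd.DataFrame(
        dict(zip(FORCING_COLUMNS, (ta, td, sw, et, rn, g, fapar, lai))),
        index=idx)
    DailyForcing.from_frame(frame).validate()
    return frame


def generate_daily_forcing(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Per-site daily driver frames (fAPAR/LAI interpolated from 8-day nodes).

    Returns a mapping site_id -> DataFrame with the forcing columns and a
    daily DatetimeIndex over whole calendar years.  Deterministic in
    ``config.seed``.
    """
    return {f"site{i:02d}": _forcing_frame(config, i)
            for i in range(config.n_sites)}


def generate_site_observations(forcing: pd.DataFrame, truth: LUEParameters,
                               noise_sd_frac: float, seed: int,
                               site_id: str = "site00",
                               zone: str = "Default") -> SiteRecordSet:
    """Observed GPP = model GPP under ``truth`` + truncated Gaussian noise.

    The noise standard deviation is ``noise_sd_frac`` times the mean
    modelled GPP; negative draws are truncated at zero.  With
    ``noise_sd_frac = 0`` the observations equal the model exactly, so a
    noiseless record round-trips through calibration to ``truth``.
    """
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    model = daily_gpp(DailyForcing.from_frame(forcing), truth)
    rng = np.random.default_rng([seed, 11])
    sd = noise_sd_frac * float(np.nanmean(model))
    obs = model + (rng.normal(0.0, sd, len(model)) if sd > 0 else 0.0)
    obs = np.clip(obs, 0.0, None)
    data = forcing.copy()
    data["gpp_obs"] = obs
    return SiteRecordSet(site_id=site_id, zone=zone, data=data)


def generate_site_records(config: SyntheticConfig,
                          truth_table: ZoneParameterTable | None = None
                          ) -> list[SiteRecordSet]:
    """Full synthetic site network: forcing plus noisy observations.

    Sites cycle through ``config.zone_labels``; each site's true
    parameters come from ``truth_table`` (default: the packaged
    calibrated lookup) for its zone.
    """
    truth_table = truth_table or default_zone_table()
    forcing = generate_daily_forcing(config)
    records = []
    for i, (site_id, frame) in enumerate(forcing.items()):
        zone = config.zone_labels[i % len(config.zone_labels)]
        records.append(generate_site_observations(
            frame, truth_table.lookup(zone), config.noise_sd_frac,
            seed=config.seed * 1000 + i, site_id=site_id, zone=zone))
    return records


def generate_fine_landcover(grid_shape_1km: tuple[int, int], fine_factor: int,
                            cropland_fraction_field: np.ndarray,
                            seed: int) -> np.ndarray:
    """Fine-resolution land-cover class grid (1 = cropland, 0 = other).

    For each coarse cell the number of cropland fine cells is the nearest
    integer to ``fraction * fine_factor**2`` (so the realized fraction
    matches the request to within 1/fine_factor^2), placed at seeded
    random positions within the block.
    """
    rows, cols = grid_shape_1km
    frac = np.asarray(cropland_fraction_field, dtype=float)
    if frac.shape != (rows, cols):
        raise ValueError("cropland_fraction_field must match grid_shape_1km")
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("cropland fractions must lie in [0, 1]")
    rng = np.random.default_rng([seed, 13])
    f = fine_factor
    fine = np.zeros((rows * f, cols * f), dtype=np.int8)
    for r in range(rows):
        for c in range(cols):
            k = int(round(frac[r, c] * f * f))
            block = np.zeros(f * f, dtype=np.int8)
            block[:k] = 1
            rng.shuffle(block)
            fine[r * f:(r + 1) * f, c * f:(c + 1) * f] = block.reshape(f, f)
    return fine


def generate_zone_map(grid_shape_1km: tuple[int, int],
                      zone_labels: Sequence[str], seed: int) -> np.ndarray:
    """Climate-zone raster: contiguous horizontal bands, one per label.

    Every label appears at least once; band order is a seeded shuffle.
    Requires at least as many rows as labels.
    """
    if len(zone_labels) == 0:
        raise ValueError("zone_labels must be non-empty")
    rows, cols = grid_shape_1km
    if rows < len(zone_labels):
        raise ValueError(f"need >= {len(zone_labels)} rows for "
                         f"{len(zone_labels)} contiguous zone bands")
    rng = np.random.default_rng([seed, 17])
    labels = list(zone_labels)
    rng.shuffle(labels)
    out = np.empty((rows, cols), dtype="<U8")
    for band, row_idx in zip(labels, np.array_split(np.arange(rows), len(labels))):
        out[row_idx, :] = band
    return out


def generate_raster_inputs(config: SyntheticConfig, year: int | None = None):
    """One year of synthetic daily driver stacks on the small analysis grid.

    Each climate-zone band of the zone map shares one generated daily
    driver series (so the blockiness of real climate-zone structure is
    present); vegetation composites get a smooth per-pixel scaling in
    [0.8, 1.0] for spatial texture.  The fine land-cover grid comes from
    a per-cell cropland-fraction field drawn uniform on [0.2, 1.0].
    Returns a :class:`cropwue.pipeline.RasterInputs`.
    """
    from .geotiff import GeoTransform
    from .pipeline import RasterInputs

    year = year or config.start_year
    one_year = SyntheticConfig(**{**config.__dict__, "n_years": 1,
                                  "start_year": year})
    rows, cols = config.grid_shape_1km
    zone_map = generate_zone_map(config.grid_shape_1km, config.zone_labels,
                                 config.seed)
    idx = _daily_index(one_year)
    n_days = len(idx)

    stacks = {k: np.empty((n_days, rows, cols)) for k in
              ("ta", "td", "sw", "et", "rn", "g")}
    codes = list(dict.fromkeys(zone_map.ravel().tolist()))
    veg_nodes: dict[str, tuple[pd.Series, pd.Series]] = {}
    for zi, code in enumerate(codes):
        frame = _forcing_frame(one_year, 100 + zi)
        sel = zone_map == code
        for k, col in zip(("ta", "td", "sw", "et", "rn", "g"),
                          ("ta_c", "td_c", "sw_mj_m2_d", "et_mm_d",
                           "rn_w_m2", "g_w_m2")):
            stacks[k][:, sel] = frame[col].to_numpy()[:, None]
        veg_nodes[code] = generate_vegetation_nodes(one_year, 100 + zi)

    veg_dates = veg_nodes[codes[0]][0].index
    rng = np.random.default_rng([config.seed, 23])
    pixel_scale = rng.uniform(0.8, 1.0, (rows, cols))
    fapar_8day = np.empty((len(veg_dates), rows, cols))
    lai_8day = np.empty((len(veg_dates), rows, cols))
    for code in codes:
        sel = zone_map == code
        fnod, lnod = veg_nodes[code]
        fapar_8day[:, sel] = fnod.to_numpy()[:, None] * pixel_scale[sel]
        lai_8day[:, sel] = lnod.to_numpy()[:, None] * pixel_scale[sel]

    frac = rng.uniform(0.2, 1.0, (rows, cols))
    fine = generate_fine_landcover(config.grid_shape_1km, config.fine_factor,
                                   frac, config.seed)
    # ~1-km pixels in degrees, arbitrary mid-latitude window
    transform = GeoTransform(west=10.0, north=50.0, xres=1 / 112.0,
                             yres=1 / 112.0)
    return RasterInputs(year=year, dates=idx, veg_dates=veg_dates,
                        fapar_8day=fapar_8day, lai_8day=lai_8day,
                        zone_map=zone_map, fine_landcover=fine,
                        fine_factor=config.fine_factor, transform=transform,
                        **stacks)


def write_site_csv(record: SiteRecordSet, path) -> None:
    """Write a site record in the standard CSV dialect (ISO dates)."""
    df = record.data.copy()
    df.insert(0, "date", df.index.strftime("%Y-%m-%d"))
    df.to_csv(path, index=False, float_format="%.6f")


def read_site_csv(path, site_id: str | None = None,
                  zone: str = "Default") -> SiteRecordSet:
    """Read a site record written by :func:`write_site_csv`."""
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    if site_id is None:
        import os
        site_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SiteRecordSet(site_id=site_id, zone=zone, data=df)
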