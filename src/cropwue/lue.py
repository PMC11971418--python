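"""Daily GPP from the evaporative-fraction light-use-efficiency (EF-LUE) model.

GPP (g C/m2/d) is the product of absorbed PAR and the maximum light-use
efficiency, down-regulated by three multiplicative stress factors::

    GPP = fAPAR * PAR * eps_max * F_T * F_VPD * F_W

where ``PAR = par_fraction * shortwave``, ``F_T`` is a parabolic air
temperature response with hard cutoffs, ``F_VPD`` a hyperbolic
vapour-pressure-deficit response, and ``F_W`` the evaporative fraction
``EF = lambda*ET / (Rn - G)`` clamped to [0, 1].  All factor functions are
vectorized over numpy arrays and accept scalars.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import LAMBDA_V_MJ_KG, WATTS_TO_MJ_DAY, LUEParameters

__all__ = [
    "DailyForcing",
    "temperature_factor",
    "vpd_from_temperatures",
    "vpd_factor",
    "water_factor",
    "daily_gpp",
    "interpolate_8day_to_daily",
]

logger = logging.getLogger(__name__)

#: Column names of the site-record CSV dialect, in writing order.
FORCING_COLUMNS = (
    "ta_c",
    "td_c",
    "sw_mj_m2_d",
    "et_mm_d",
    "rn_w_m2",
    "g_w_m2",
    "fapar",
    "lai",
)


@dataclass
class DailyForcing:
    """One aligned series of daily driver values for a site or pixel.

    All fields are 1-D numpy arrays of equal length: air temperature
    ``ta`` and dew-point ``td`` (deg C), shortwave irradiance ``sw``
    (MJ/m2/d), evapotranspiration ``et`` (mm/d), net radiation ``rn``
    and soil heat flux ``g`` (mean daily W/m2), ``fapar`` (0-1) and
    leaf area index ``lai`` (m2/m2).
    """

    ta: np.ndarray
    td: np.ndarray
    sw: np.ndarray
    et: np.ndarray
    rn: np.ndarray
    g: np.ndarray
    fapar: np.ndarray
    lai: np.ndarray

    def __post_init__(self) -> None:
        arrays = {k: np.asarray(getattr(self, k), dtype=float) for k in
                  ("ta", "td", "sw", "et", "rn", "g", "fapar", "lai")}
        n = len(arrays["ta"])
        for k, v in arrays.items():
            if v.ndim != 1 or len(v) != n:
                raise ValueError(f"forcing field {k!r} must be 1-D of length {n}")
            setattr(self, k, v)

    def __len__(self) -> int:
        return len(self.ta)

    def validate(self) -> None:
        """Raise if any physical-range invariant is violated (NaNs pass)."""
        with np.errstate(invalid="ignore"):
            if np.any(self.fapar < 0) or np.any(self.fapar > 1):
                raise ValueError("fapar outside [0, 1]")
            if np.any(self.lai < 0):
                raise ValueError("negative LAI")
            if np.any(self.et < 0):
                raise ValueError("negative ET")
            if np.any(self.sw < 0):
                raise ValueError("negative shortwave irradiance")
            if np.any(self.td > self.ta):
                raise ValueError("dew point exceeds air temperature")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DailyForcing":
        """Build from a DataFrame in the site-record CSV dialect."""
        return cls(
            ta=df["ta_c"].to_numpy(float),
            td=df["td_c"].to_numpy(float),
            sw=df["sw_mj_m2_d"].to_numpy(float),
            et=df["et_mm_d"].to_numpy(float),
            rn=df["rn_w_m2"].to_numpy(float),
            g=df["g_w_m2"].to_numpy(float),
            fapar=df["fapar"].to_numpy(float),
            lai=df["lai"].to_numpy(float),
        )

    def to_frame(self, index=None) -> pd.DataFrame:
        data = dict(zip(FORCING_COLUMNS,
                        (self.ta, self.td, self.sw, self.et,
                         self.rn, self.g, self.fapar, self.lai)))
        return pd.DataFrame(data, index=index)


def temperature_factor(ta, params: LUEParameters):
    """Air-temperature stress factor F_T in [0, 1].

    Parabolic response that equals 1 at ``t_opt`` and 0 at (and beyond)
    the cutoffs ``t_min``/``t_max``::

        F_T = (T - Tmin)(T - Tmax) / [ (T - Tmin)(T - Tmax) - (T - Topt)^2 ]

    Outside [t_min, t_max] the factor is 0 (zero LUE); at the cutoffs the
    quotient itself vanishes, so the clamp is continuous.
    """
    ta = np.asarray(ta, dtype=float)
    num = (ta - params.t_min) * (ta - params.t_max)
    den = num - (ta - params.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den != 0.0, num / den, 1.0)
    f = np.where((ta < params.t_min) | (ta > params.t_max), 0.0, f)
    f = np.where(np.isnan(ta), np.nan, f)
    return f if f.ndim else float(f)


def vpd_from_temperatures(ta, td, magnus_coef: float = 17.27):
    """Vapour-pressure deficit (kPa) from air and dew-point temperature.

    Tetens form: ``VPD = 0.6108 * (exp(c*T/(T+237.3)) - exp(c*Td/(Td+237.3)))``
    with ``c = magnus_coef``.  Requires ``td <= ta`` elementwise (the dew
    point cannot exceed the air temperature), which guarantees VPD >= 0.
    """
    ta = np.asarray(ta, dtype=float)
    td = np.asarray(td, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(td > ta):
            raise ValueError("dew point exceeds air temperature")
        if np.any(ta <= -237.3) or np.any(td <= -237.3):
            raise ValueError("temperature at or below -237.3 degC")
    esat = 0.6108 * np.exp(magnus_coef * ta / (ta + 237.3))
    eact = 0.6108 * np.exp(magnus_coef * td / (td + 237.3))
    vpd = esat - eact
    return vpd if vpd.ndim else float(vpd)


def vpd_factor(vpd, params: LUEParameters):
    """VPD stress factor ``F_VPD = VPD0 / (VPD0 + VPD)``, in (0, 1]."""
    vpd = np.asarray(vpd, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(vpd < 0):
            raise ValueError("negative VPD")
    f = params.vpd0 / (params.vpd0 + vpd)
    return f if f.ndim else float(f)


def water_factor(et, rn, g, lambda_v: float = LAMBDA_V_MJ_KG,
                 degenerate_fallback: float = 0.0):
    """Water-availability factor: evaporative fraction clamped to [0, 1].

    ``EF = lambda*ET / (Rn - G)`` with both terms on a daily-energy basis:
    latent heat is ``lambda_v * ET`` in MJ/m2/d (1 mm of water = 1 kg/m2),
    available energy is ``(Rn - G) * 0.0864`` MJ/m2/d from mean daily W/m2.
    Days with non-positive available energy have no defined EF; they get
    ``degenerate_fallback`` (default 0: no energy to drive transpiration-
    coupled assimilation) and are counted in a log message.
    """
    et = np.asarray(et, dtype=float)
    avail = (np.asarray(rn, dtype=float) - np.asarray(g, dtype=float)) * WATTS_TO_MJ_DAY
    latent = lambda_v * et
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.where(avail > 0, latent / np.where(avail > 0, avail, 1.0),
                      degenerate_fallback)
    n_degenerate = int(np.sum(avail <= 0))
    if n_degenerate:
        logger.info("water_factor: %d day(s) with non-positive available "
                    "energy set to fallback %.3g", n_degenerate, degenerate_fallback)
    ef = np.where(np.isnan(avail) | np.isnan(et), np.nan, ef)
    f = np.clip(ef, 0.0, 1.0)
    return f if f.ndim else float(f)


def gpp_from_arrays(ta, td, sw, et, rn, g, fapar, params: LUEParameters,
                    lambda_v: float = LAMBDA_V_MJ_KG):
    """GPP kernel over driver arrays of any (broadcastable) shape.

    Used by both the site path (:func:`daily_gpp`) and the raster
    pipeline, so the two modes evaluate the identical expression.
    """
    par = params.par_fraction * np.asarray(sw, dtype=float)
    f_t = temperature_factor(ta, params)
    vpd = vpd_from_temperatures(ta, td, params.magnus_coef)
    f_vpd = vpd_factor(vpd, params)
    f_w = water_factor(et, rn, g, lambda_v)
    return np.asarray(fapar, dtype=float) * par * params.eps_max * f_t * f_vpd * f_w


def daily_gpp(forcing: DailyForcing, params: LUEParameters,
              lambda_v: float = LAMBDA_V_MJ_KG):
    """Daily GPP (g C/m2/d) for a forcing series under one parameter set.

    Returns an array aligned with the forcing; NaN drivers give NaN GPP.
    """
    return gpp_from_arrays(forcing.ta, forcing.td, forcing.sw, forcing.et,
                           forcing.rn, forcing.g, forcing.fapar, params,
                           lambda_v)


def interpolate_8day_to_daily(nodes: pd.Series,
                              target_index: pd.DatetimeIndex | None = None) -> pd.Series:
    """Linearly interpolate an 8-day composite series to daily values.

    ``nodes`` is a Series indexed by (strictly increasing) composite dates.
    Node values are preserved exactly; days between nodes are linear;
    days before the first / after the last node hold the terminal value.
    ``target_index`` defaults to the daily span of the node dates.
    A single-node series returns a constant with a warning.
    """
    if not nodes.index.is_monotonic_increasing or nodes.index.has_duplicates:
        raise ValueError("node dates must be strictly increasing")
    if len(nodes) == 0:
        raise ValueError("empty node series")
    if target_index is None:
        target_index = pd.date_range(nodes.index[0], nodes.index[-1], freq="D")
    if len(nodes) == 1:
        warnings.warn("single-node series: returning a constant", stacklevel=2)
        return pd.Series(float(nodes.iloc[0]), index=target_index)
    x_nodes = nodes.index.view("int64").astype(float)
    x_out = target_index.view("int64").astype(float)
    values = np.interp(x_out, x_nodes, nodes.to_numpy(float))
    return pd.Series(values, index=target_index)
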