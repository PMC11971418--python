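"""Calibration of the EF-LUE parameters against flux-site GPP records.

The calibratable triple (eps_max, t_opt, vpd0) is fitted per climate zone
by bounded nonlinear least squares (Trust Region Reflective) on daily GPP
residuals, pooling all sites of the zone.  Zones without sites fall back
to a "Default" triple fitted on all sites worldwide.  The fitted lookup
is applied spatially by stamping each pixel of a climate-zone raster with
its zone's triple.

The fit is exposed statsmodels-style: build an :class:`EFLUEModel` from
records (``EFLUEModel.from_records``) and call :meth:`EFLUEModel.fit`,
which returns an :class:`EFLUEResults` with the estimates, diagnostics
and a ``summary()`` table.  :func:`fit_zone` is a thin convenience
wrapper around that pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .lue import DailyForcing, daily_gpp
from .params import LUEParameters, OptimizationSpec

__all__ = [
    "EFLUEModel",
    "EFLUEResults",
    "ZoneParameterTable",
    "TooFewDataError",
    "fit_zone",
    "fit_per_site",
    "build_parameter_table",
    "parameters_to_raster",
    "default_zone_table",
]


class TooFewDataError(ValueError):
    """Raised when a zone's pooled records have too few valid days to fit."""


class EFLUEModel:
    """EF-LUE light-use-efficiency model bound to daily GPP observations.

    Parameters
    ----------
    forcing : DailyForcing
        Pooled daily drivers (order does not matter; days are independent).
    gpp_obs : array-like
        Observed daily GPP, g C/m2/d.  NaNs are dropped, not imputed.
    spec : OptimizationSpec
        Start point, bounds and tolerances for the bounded fit.
    template : LUEParameters, optional
        Carries the fixed fields (t_min, t_max, par_fraction, magnus_coef)
        used while the triple varies.
    """

    def __init__(self, forcing: DailyForcing, gpp_obs,
                 spec: OptimizationSpec = OptimizationSpec(),
                 template: LUEParameters | None = None):
        gpp_obs = np.asarray(gpp_obs, dtype=float)
        if len(gpp_obs) != len(forcing):
            raise ValueError("observations and forcing must be aligned")
        drivers = np.column_stack([forcing.ta, forcing.td, forcing.sw,
                                   forcing.et, forcing.rn, forcing.g,
                                   forcing.fapar, forcing.lai])
        valid = np.isfinite(gpp_obs) & np.all(np.isfinite(drivers), axis=1)
        self.forcing = DailyForcing(*(np.asarray(getattr(forcing, k))[valid]
                                      for k in ("ta", "td", "sw", "et",
                                                "rn", "g", "fapar", "lai")))
        self.gpp_obs = gpp_obs[valid]
        self.nobs = int(valid.sum())
        self.spec = spec
        self.template = template or LUEParameters(*spec.init)

    @classmethod
    def from_records(cls, records: Iterable, spec: OptimizationSpec = OptimizationSpec(),
                     template: LUEParameters | None = None) -> "EFLUEModel":
        """Pool one or more site record sets into a single model."""
        records = list(records)
        if not records:
            raise ValueError("no records supplied")
        frames = [r.to_frame() for r in records]
        pooled = pd.concat(frames, ignore_index=True)
        return cls(DailyForcing.from_frame(pooled),
                   pooled["gpp_obs"].to_numpy(float), spec=spec,
                   template=template)

    def predict(self, triple) -> np.ndarray:
        """Model daily GPP for a candidate (eps_max, t_opt, vpd0) triple."""
        params = replace(self.template, eps_max=float(triple[0]),
                         t_opt=float(triple[1]), vpd0=float(triple[2]))
        return daily_gpp(self.forcing, params)

    def _residuals(self, x) -> np.ndarray:
        return self.predict(x) - self.gpp_obs

    def fit(self) -> "EFLUEResults":
        """Bounded trust-region least squares from the configured start point."""
        if self.nobs < self.spec.min_valid_days:
            raise TooFewDataError(
                f"{self.nobs} valid days < required {self.spec.min_valid_days}")
        identifiable = float(np.std(self.gpp_obs)) > 0.0
        x0 = np.asarray(self.spec.init, dtype=float)
        cost0 = 0.5 * float(np.sum(self._residuals(x0) ** 2))
        sol = least_squares(self._residuals, x0,
                            bounds=(self.spec.lower, self.spec.upper),
                            method="trf", ftol=self.spec.ftol,
                            xtol=self.spec.xtol, max_nfev=self.spec.max_nfev)
        params = replace(self.template, eps_max=float(sol.x[0]),
                         t_opt=float(sol.x[1]), vpd0=float(sol.x[2]))
        rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
        return EFLUEResults(model=self, params=params, cost=float(sol.cost),
                            cost_at_init=cost0, rmse=rmse, nobs=self.nobs,
                            nfev=int(sol.nfev), converged=bool(sol.success),
                            identifiable=identifiable, message=str(sol.message))


@dataclass
class EFLUEResults:
    """Fit results: the optimized triple plus diagnostics."""

    model: EFLUEModel
    params: LUEParameters
    cost: float
    cost_at_init: float
    rmse: float
    nobs: int
    nfev: int
    converged: bool
    identifiable: bool
    message: str

    @property
    def triple(self) -> tuple[float, float, float]:
        return self.params.triple

    def summary(self) -> str:
        lines = [
            "EF-LUE calibration results",
            "==========================",
            f"n daily observations : {self.nobs}",
            f"eps_max (g C/MJ)     : {self.params.eps_max:10.4f}",
            f"t_opt (degC)         : {self.params.t_opt:10.4f}",
            f"vpd0 (kPa)           : {self.params.vpd0:10.4f}",
            f"RMSE (g C/m2/d)      : {self.rmse:10.4f}",
            f"cost at init / final : {self.cost_at_init:.6g} / {self.cost:.6g}",
            f"function evaluations : {self.nfev}",
            f"converged            : {self.converged}",
        ]
        if not self.identifiable:
            lines.append("WARNING: zero observation variance; "
                         "parameters not identifiable")
        return "\n".join(lines)


def fit_zone(records: Sequence, spec: OptimizationSpec = OptimizationSpec(),
             template: LUEParameters | None = None) -> EFLUEResults:
    """Pooled fit of all records sharing a climate zone (production path)."""
    return EFLUEModel.from_records(records, spec=spec, template=template).fit()


def fit_per_site(records: Sequence, spec: OptimizationSpec = OptimizationSpec(),
                 template: LUEParameters | None = None) -> dict[str, EFLUEResults]:
    """Diagnostic mode: one independent fit per site."""
    return {r.site_id: EFLUEModel.from_records([r], spec=spec,
                                               template=template).fit()
            for r in records}


@dataclass
class ZoneParameterTable:
    """Per-climate-zone (eps_max, t_opt, vpd0) lookup with a Default fallback.

    Zones with fitted parameters use their own triple; any other zone code
    resolves to ``default_entry`` (the all-sites pooled fit).
    """

    zones: dict[str, LUEParameters] = field(default_factory=dict)
    default_entry: LUEParameters | None = None

    def __post_init__(self) -> None:
        if self.default_entry is None:
            raise ValueError("default_entry is required")

    def lookup(self, zone: str) -> LUEParameters:
        return self.zones.get(zone, self.default_entry)

    def __contains__(self, zone: str) -> bool:
        return zone in self.zones

    def to_frame(self) -> pd.DataFrame:
        rows = [{"zone": z, "eps_max": p.eps_max, "t_opt": p.t_opt,
                 "vpd0": p.vpd0} for z, p in sorted(self.zones.items())]
        d = self.default_entry
        rows.append({"zone": "Default", "eps_max": d.eps_max,
                     "t_opt": d.t_opt, "vpd0": d.vpd0})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   template: LUEParameters | None = None) -> "ZoneParameterTable":
        template = template or LUEParameters(1.0, 20.0, 1.0)
        zones: dict[str, LUEParameters] = {}
        default = None
        for row in df.itertuples(index=False):
            p = replace(template, eps_max=float(row.eps_max),
                        t_opt=float(row.t_opt), vpd0=float(row.vpd0))
            if row.zone == "Default":
                default = p
            else:
                zones[str(row.zone)] = p
        return cls(zones=zones, default_entry=default)

    @classmethod
    def from_csv(cls, path,
                 template: LUEParameters | None = None) -> "ZoneParameterTable":
        return cls.from_frame(pd.read_csv(path), template=template)


def default_zone_table(template: LUEParameters | None = None) -> ZoneParameterTable:
    """The packaged calibrated lookup (eight climate zones plus Default)."""
    text = resources.files("cropwue").joinpath("data/zone_parameters.csv").read_text()
    return ZoneParameterTable.from_frame(pd.read_csv(io.StringIO(text)),
                                         template=template)


def build_parameter_table(zone_records: Mapping[str, Sequence],
                          all_site_records: Sequence,
                          spec: OptimizationSpec = OptimizationSpec(),
                          template: LUEParameters | None = None) -> ZoneParameterTable:
    """Fit each zone's pooled records plus the worldwide Default fallback.

    ``zone_records`` maps climate-zone code to that zone's site records;
    ``all_site_records`` is the worldwide pool used for the Default entry.
    Fails if the pooled Default fit is impossible.
    """
    default = fit_zone(list(all_site_records), spec=spec, template=template)
    zones = {zone: fit_zone(list(recs), spec=spec, template=template).params
             for zone, recs in sorted(zone_records.items())}
    return ZoneParameterTable(zones=zones, default_entry=default.params)


def parameters_to_raster(table: ZoneParameterTable, zone_map: np.ndarray,
                         nodata_label: str = "") -> np.ndarray:
    """Stamp each pixel of a zone-code raster with its parameter triple.

    ``zone_map`` is a 2-D array of zone-code strings; pixels whose code is
    not in the table get the Default triple; pixels equal to
    ``nodata_label`` get NaN in all three bands.  Returns a (3, rows,
    cols) float array with bands (eps_max, t_opt, vpd0).
    """
    zone_map = np.asarray(zone_map)
    if zone_map.ndim != 2:
        raise ValueError("zone map must be 2-D")
    out = np.full((3,) + zone_map.shape, np.nan, dtype=float)
    for code in np.unique(zone_map):
        sel = zone_map == code
        if code == nodata_label:
            continue
        p = table.lookup(str(code))
        out[0][sel] = p.eps_max
        out[1][sel] = p.t_opt
        out[2][sel] = p.vpd0
    return out
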