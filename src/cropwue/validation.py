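"""Accuracy metrics and zonal anomaly series for annual WUE validation.

Estimated annual values (GPP, NPP, ET or WUE) are compared with
observations through Pearson correlation, RMSE, BIAS (mean estimate
minus mean observation) and the Kling-Gupta efficiency in its Gupta et
al. (2009) equal-weights form:

    KGE = 1 - sqrt((r - 1)^2 + (sigma_e/sigma_o - 1)^2 + (mu_e/mu_o - 1)^2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricReport", "compute_metrics", "zonal_anomaly_series"]


@dataclass(frozen=True)
class MetricReport:
    """Paired-comparison metrics; ``rho``/``kge`` are NaN when degenerate."""

    rho: float
    rmse: float
    bias: float
    kge: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"rho": self.rho, "rmse": self.rmse, "bias": self.bias,
                "kge": self.kge, "n": self.n, "degenerate": self.degenerate}


def compute_metrics(estimates, observations) -> MetricReport:
    """Pearson rho, RMSE, BIAS and KGE between paired annual series.

    Requires at least two finite pairs.  If either series has zero
    variance (or the observation mean is zero) the correlation-based
    metrics are undefined: they come back NaN with ``degenerate=True``.
    """
    e = np.asarray(estimates, dtype=float)
    o = np.asarray(observations, dtype=float)
    if e.shape != o.shape or e.ndim != 1:
        raise ValueError("estimates and observations must be equal-length 1-D")
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(o))):
        raise ValueError("metrics require finite values only")
    n = len(e)
    if n < 2:
        raise ValueError("need at least two pairs")
    rmse = float(np.sqrt(np.mean((e - o) ** 2)))
    bias = float(np.mean(e) - np.mean(o))
    degenerate = float(np.std(e)) == 0.0 or float(np.std(o)) == 0.0 \
        or float(np.mean(o)) == 0.0
    if degenerate:
        return MetricReport(rho=np.nan, rmse=rmse, bias=bias, kge=np.nan,
                            n=n, degenerate=True)
    rho = float(stats.pearsonr(e, o).statistic)
    alpha = float(np.std(e) / np.std(o))
    beta = float(np.mean(e) / np.mean(o))
    kge = 1.0 - float(np.sqrt((rho - 1) ** 2 + (alpha - 1) ** 2 + (beta - 1) ** 2))
    return MetricReport(rho=rho, rmse=rmse, bias=bias, kge=kge, n=n)


def zonal_anomaly_series(grids_by_year: dict, zone_map: np.ndarray,
                         zone: str) -> pd.Series:
    """Inter-annual anomaly of the zonal-mean value over valid pixels.

    ``zone`` may be a full climate-zone code or a major-class prefix
    (e.g. ``"D"`` selects all continental sub-types).  For each year the
    zonal mean over valid (non-nodata) pixels is taken; anomalies are
    those means minus their all-year average, so they sum to zero by
    construction.  An empty zone raises.
    """
    if len(grids_by_year) < 2:
        raise ValueError("need at least two years of grids")
    zone_map = np.asarray(zone_map)
    sel = np.char.startswith(zone_map.astype(str), zone)
    if not sel.any():
        raise ValueError(f"zone {zone!r} selects no pixels")
    years = sorted(grids_by_year)
    means = []
    first = grids_by_year[years[0]]
    for yr in years:
        grid = grids_by_year[yr]
        if grid.values.shape != first.values.shape:
            raise ValueError("grids must be congruent across years")
        vals = grid.values[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"zone {zone!r} has no valid pixels in {yr}")
        means.append(float(np.mean(vals)))
    means = np.asarray(means)
    return pd.Series(means - means.mean(), index=pd.Index(years, name="year"))
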