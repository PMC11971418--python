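"""Maintenance respiration, growth respiration, and annual NPP.

Cropland autotrophic respiration follows the MOD17 growth-and-maintenance
paradigm restricted to leaves and fine roots.  Daily maintenance
respiration (MR) scales tissue carbon pools (from LAI and specific leaf
area) by base rates at 20 degC and Q10 temperature sensitivities; annual
growth respiration (GR) is a fixed fraction of annual NPP, which closes
the annual budget to

    NPP = max(0, (sum GPP - sum MR) / (1 + gr_fraction))

i.e. ``NPP = max(0, 0.8 * (sum GPP - sum MR))`` with the default
``gr_fraction = 0.25``.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np

from .params import RespirationConstants

__all__ = [
    "AnnualCarbonBudget",
    "q10_leaf",
    "leaf_mass",
    "daily_mr",
    "annual_npp",
]

#: kg C/m2/d -> g C/m2/d
KG_TO_G = 1000.0


@dataclass(frozen=True)
class AnnualCarbonBudget:
    """Annual carbon terms (g C/m2/yr) for one site-year or pixel-year.

    When ``npp > 0`` the budget closes exactly:
    ``gpp_sum - mr_sum - gr - npp = 0`` and ``gr = gr_fraction * npp``.
    """

    gpp_sum: float
    mr_sum: float
    gr: float
    npp: float
    n_days: int


def q10_leaf(ta, floor: float = 0.1):
    """Temperature sensitivity of leaf maintenance respiration.

    Linear in the daily mean temperature, ``Q10 = 3.22 - 0.046 * Ta``,
    floored at a small positive value (respiration sensitivity cannot be
    negative; the linear form would cross zero at Ta = 70 degC, far
    outside any cropland record).
    """
    ta = np.asarray(ta, dtype=float)
    q = np.maximum(3.22 - 0.046 * ta, floor)
    return q if q.ndim else float(q)


def leaf_mass(lai, sla: float):
    """Leaf carbon pool (kg C/m2) from LAI and specific leaf area."""
    if sla <= 0:
        raise ValueError(f"specific leaf area must be positive, got {sla}")
    lai = np.asarray(lai, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(lai < 0):
            raise ValueError("negative LAI")
    m = lai / sla
    return m if m.ndim else float(m)


def daily_mr(lai, ta, consts: RespirationConstants = RespirationConstants()):
    """Daily maintenance respiration of leaves + fine roots, g C/m2/d.

    Leaf and fine-root pools respire at their 20-degC base rates scaled
    by ``Q10 ** ((Ta - 20)/10)``; the fine-root pool is
    ``froot_leaf_ratio`` times the leaf pool.  Internally in kg C/m2/d,
    converted to g C/m2/d so it subtracts from GPP in the annual budget.
    """
    lm = leaf_mass(lai, consts.sla)
    ta = np.asarray(ta, dtype=float)
    exponent = (ta - 20.0) / 10.0
    leaf_r = lm * consts.leaf_mr_base * q10_leaf(ta, consts.q10_leaf_floor) ** exponent
    froot_r = (lm * consts.froot_leaf_ratio) * consts.froot_mr_base \
        * consts.q10_froot ** exponent
    mr = (leaf_r + froot_r) * KG_TO_G
    return mr if np.ndim(mr) else float(mr)


def _expected_days(year: int | None, n: int) -> int:
    if year is not None:
        expected = 366 if calendar.isleap(year) else 365
        if n != expected:
            raise ValueError(f"year {year} needs {expected} daily values, got {n}")
        return expected
    if n not in (365, 366):
        raise ValueError(f"need a whole calendar year (365/366 days), got {n}")
    return n


def annual_npp(gpp_daily, mr_daily,
               consts: RespirationConstants = RespirationConstants(),
               year: int | None = None) -> AnnualCarbonBudget:
    """Close the annual carbon budget for one calendar year of daily series.

    ``NPP = max(0, (sum GPP - sum MR) / (1 + gr_fraction))`` and
    ``GR = gr_fraction * NPP`` (zero when NPP is zero).  Both inputs are
    daily series in g C/m2/d covering a whole calendar year (365 or 366
    entries; pass ``year`` to check against the calendar).
    """
    gpp_daily = np.asarray(gpp_daily, dtype=float)
    mr_daily = np.asarray(mr_daily, dtype=float)
    if gpp_daily.shape != mr_daily.shape or gpp_daily.ndim != 1:
        raise ValueError("GPP and MR must be 1-D series of equal length")
    n = _expected_days(year, len(gpp_daily))
    gpp_sum = float(np.sum(gpp_daily))
    mr_sum = float(np.sum(mr_daily))
    npp = max(0.0, (gpp_sum - mr_sum) / (1.0 + consts.gr_fraction))
    gr = consts.gr_fraction * npp
    return AnnualCarbonBudget(gpp_sum=gpp_sum, mr_sum=mr_sum, gr=gr,
                              npp=npp, n_days=n)
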