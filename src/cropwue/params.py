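"""Parameter containers for the EF-LUE model and the respiration scheme.

The light-use-efficiency (LUE) model has three calibratable parameters —
the maximum light-use efficiency ``eps_max`` (g C/MJ), the optimum air
temperature ``t_opt`` (deg C) and the half-saturation vapour-pressure
deficit ``vpd0`` (kPa) — plus fixed temperature cutoffs and the PAR
fraction of shortwave irradiance.  Maintenance/growth respiration uses a
MOD17-style constant set (base rates at 20 deg C, specific leaf area,
fine-root/leaf carbon ratio, Q10 sensitivities, growth-respiration
fraction of NPP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LUEParameters",
    "RespirationConstants",
    "OptimizationSpec",
    "LAMBDA_V_MJ_KG",
    "WATTS_TO_MJ_DAY",
]

#: Latent heat of vaporization, MJ per kg of water (constant approximation).
LAMBDA_V_MJ_KG = 2.45

#: Conversion from a mean daily flux in W/m2 to a daily energy total in MJ/m2/d.
WATTS_TO_MJ_DAY = 0.0864


@dataclass(frozen=True)
class LUEParameters:
    """Parameters of the evaporative-fraction LUE model for daily GPP.

    Parameters
    ----------
    eps_max : float
        Maximum light-use efficiency in the absence of stress, g C/MJ.
    t_opt : float
        Optimum air temperature for photosynthesis, deg C.
    vpd0 : float
        Half-saturation vapour-pressure deficit, kPa.
    t_min, t_max : float
        Temperature cutoffs (deg C) outside which LUE is zero.
        Defaults 0 and 40.
    par_fraction : float
        PAR as a fraction of total shortwave irradiance (default 0.48).
    magnus_coef : float
        Coefficient in the Magnus/Tetens exponent of the saturation
        vapour-pressure curve.  Default 17.27 (the standard Tetens value);
        12.27 is selectable for compatibility with variant formulations.
    """

    eps_max: float
    t_opt: float
    vpd0: float
    t_min: float = 0.0
    t_max: float = 40.0
    par_fraction: float = 0.48
    magnus_coef: float = 17.27

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError(
                f"require t_min < t_opt < t_max, got "
                f"{self.t_min} / {self.t_opt} / {self.t_max}"
            )
        if self.eps_max <= 0:
            raise ValueError(f"eps_max must be positive, got {self.eps_max}")
        if self.vpd0 <= 0:
            raise ValueError(f"vpd0 must be positive, got {self.vpd0}")
        if not (0 < self.par_fraction <= 1):
            raise ValueError(f"par_fraction must be in (0, 1], got {self.par_fraction}")

    @property
    def triple(self) -> tuple[float, float, float]:
        """The calibratable (eps_max, t_opt, vpd0) triple."""
        return (self.eps_max, self.t_opt, self.vpd0)


@dataclass(frozen=True)
class RespirationConstants:
    """MOD17-style maintenance/growth respiration constants for cropland.

    ``leaf_mr_base`` and ``froot_mr_base`` are maintenance respiration per
    unit tissue carbon per day at 20 deg C (kg C/kg C/d); ``sla`` is the
    specific leaf area (m2 leaf per kg leaf C); ``froot_leaf_ratio`` the
    fine-root to leaf carbon ratio; ``q10_froot`` the (constant) Q10 of
    fine-root respiration; ``gr_fraction`` the annual growth respiration
    as a fraction of annual NPP.  Leaf Q10 is temperature-dependent and
    lives in :func:`cropwue.respiration.q10_leaf`.
    """

    leaf_mr_base: float = 0.0098
    froot_mr_base: float = 0.00819
    sla: float = 30.4
    froot_leaf_ratio: float = 2.0
    q10_froot: float = 2.0
    gr_fraction: float = 0.25
    q10_leaf_floor: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "leaf_mr_base",
            "froot_mr_base",
            "sla",
            "froot_leaf_ratio",
            "q10_froot",
            "q10_leaf_floor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.gr_fraction < 1):
            raise ValueError(f"gr_fraction must be in (0, 1), got {self.gr_fraction}")


@dataclass(frozen=True)
class OptimizationSpec:
    """Start point, box bounds and tolerances for the bounded least-squares fit.

    Defaults are the standard calibration setup: start (3.8, 28.0, 1.2),
    lower bounds (0, 0, 0) and upper bounds (24, 35, 3) for
    (eps_max, t_opt, vpd0), solved with the Trust Region Reflective
    algorithm by minimizing the sum of squared daily GPP residuals.
    """

    init: tuple[float, float, float] = (3.8, 28.0, 1.2)
    lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upper: tuple[float, float, float] = (24.0, 35.0, 3.0)
    ftol: float = 1e-8
    xtol: float = 1e-8
    max_nfev: int = 1000
    min_valid_days: int = 30

    def __post_init__(self) -> None:
        for lo, x0, hi in zip(self.lower, self.init, self.upper):
            if not (lo < x0 < hi):
                raise ValueError(
                    f"initial value {x0} not strictly inside bounds ({lo}, {hi})"
                )
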