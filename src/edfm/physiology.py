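"""Physiological half of the daily growth loop.

Thermal-time phenology (physiological development time, PDT), a
water-stress factor extending the WOFOST soil-moisture response with a
root osmotic-adjustment coefficient, a light-use-efficiency assimilate
supply with a Vcmax modifier, and sink-strength-proportional assimilate
allocation.

Units
-----
Temperatures in deg C, soil moisture as volumetric fraction (m3 m-3),
PAR as mol photons m-2 d-1, assimilate supply E as g CH2O per plant per
day, Vcmax in umol m-2 s-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AllocationError, InvalidArgumentError

__all__ = [
    "PhenologyParams",
    "WaterParams",
    "OrganState",
    "AssimilateSupply",
    "LightUseParams",
    "pdt_increment",
    "water_stress_factor",
    "daily_assimilation",
    "allocate",
    "update_vcmax",
]


@dataclass
class PhenologyParams:
    """Thermal-time clock parameters.

    One physiological day elapses per ``pdt_norm`` degree-days above
    ``t_base``; with the defaults (t_base=8, pdt_norm=17) a day at a
    mean temperature of 25 deg C advances PDT by exactly 1.
    """

    t_base: float = 8.0
    t_ref: float = 25.0
    pdt_norm: float = field(default=17.0)

    def __post_init__(self) -> None:
        if not self.t_ref > self.t_base:
            raise InvalidArgumentError(
                f"t_ref ({self.t_ref}) must exceed t_base ({self.t_base})"
            )
        if not self.pdt_norm > 0:
            raise InvalidArgumentError("pdt_norm must be positive")


@dataclass
class WaterParams:
    """Soil-water response parameters.

    ``psi_root`` is the root osmotic-adjustment coefficient; although it
    is quoted in MPa it enters the stress factor as the dimensionless
    modifier (1 + psi_root), so the default -0.3 caps the factor at 0.7.
    """

    theta_wp: float = 0.10
    theta_fc: float = 0.32
    gamma: float = 1.0
    psi_root: float = -0.3

    def __post_init__(self) -> None:
        if not 0 < self.theta_wp < self.theta_fc:
            raise InvalidArgumentError(
                "require 0 < theta_wp < theta_fc, got "
                f"theta_wp={self.theta_wp}, theta_fc={self.theta_fc}"
            )
        if not self.gamma > 0:
            raise InvalidArgumentError("gamma must be positive")
        if not 1.0 + self.psi_root > 0:
            raise InvalidArgumentError("1 + psi_root must be positive")


@dataclass
class OrganState:
    """One leaf or internode tracked by the simulator.

    ``size`` is leaf area (cm2) for leaves and length (cm) for
    internodes; ``sink_strength`` is the organ's relative priority for
    the day's assimilates.
    """

    id: str
    organ_type: str  # "leaf" | "internode"
    sink_strength: float = 0.0
    size: float = 0.0
    size_max: float = 1.0
    vcmax: float = 60.0
    carbon_received: float = 0.0
    # logistic potential-growth parameters for this organ
    k: float = 0.15
    pdt_mid: float = 20.0

    def __post_init__(self) -> None:
        if self.organ_type not in ("leaf", "internode"):
            raise InvalidArgumentError(f"unknown organ_type {self.organ_type!r}")
        if self.sink_strength < 0:
            raise InvalidArgumentError("sink_strength must be >= 0")
        if not 0 <= self.size <= self.size_max:
            raise InvalidArgumentError("require 0 <= size <= size_max")
        if not self.vcmax > 0:
            raise InvalidArgumentError("vcmax must be positive")


@dataclass
class AssimilateSupply:
    """Daily whole-plant assimilate yield E(t), g CH2O per plant."""

    e: float

    def __post_init__(self) -> None:
        if self.e < 0:
            raise InvalidArgumentError("assimilate supply must be >= 0")


@dataclass
class LightUseParams:
    """Light-use-efficiency supply model.

    ``lue`` converts intercepted photons to assimilate
    (g CH2O per mol photons); ``vcmax_ref`` is the capacity at which the
    Vcmax modifier saturates at 1.
    """

    lue: float = 1.0
    vcmax_ref: float = 60.0
    beta: float = 0.3  # exponent of the light-capture Vcmax feedback

    def __post_init__(self) -> None:
        if self.lue < 0 or self.vcmax_ref <= 0:
            raise InvalidArgumentError("lue >= 0 and vcmax_ref > 0 required")


def pdt_increment(t_mean: float, params: PhenologyParams) -> float:
    """Daily physiological-day increment from the accumulated-temperature model.

    ``max(0, t_mean - t_base) / pdt_norm``; zero below the base
    temperature, nonnegative always.
    """
    if not np.isfinite(t_mean):
        raise InvalidArgumentError("t_mean must be finite")
    return max(0.0, t_mean - params.t_base) / params.pdt_norm


def water_stress_factor(theta: float, params: WaterParams) -> float:
    """Water stress factor WSF = ((theta-wp)/(fc-wp))^gamma * (1+psi_root).

    theta is clamped into [theta_wp, theta_fc] first, so the factor is
    monotone nondecreasing in theta and bounded by 1 + psi_root.
    """
    theta_c = min(max(theta, params.theta_wp), params.theta_fc)
    frac = (theta_c - params.theta_wp) / (params.theta_fc - params.theta_wp)
    return frac**params.gamma * (1.0 + params.psi_root)


def daily_assimilation(
    intercepted_par: float,
    mean_vcmax: float,
    wsf: float,
    lue_params: LightUseParams,
) -> AssimilateSupply:
    """Daily assimilate supply E = lue * I * min(1, Vcmax/Vcmax_ref) * WSF.

    A light-use-efficiency stand-in for full leaf biochemistry: supply is
    proportional to intercepted PAR, down-regulated by photosynthetic
    capacity below the reference and by water stress. Any zero factor
    gives E = 0.
    """
    if intercepted_par < 0 or mean_vcmax < 0 or wsf < 0:
        raise InvalidArgumentError("assimilation inputs must be nonnegative")
    capacity = min(1.0, mean_vcmax / lue_params.vcmax_ref)
    return AssimilateSupply(lue_params.lue * intercepted_par * capacity * wsf)


def allocate(supply: AssimilateSupply, organs: list[OrganState]) -> np.ndarray:
    """Distribute E across organs proportionally to sink strength.

    Q_i = R_i / sum(R) * E. The last organ with positive sink strength
    absorbs the floating-point residual so that sum(Q) == E exactly.
    """
    if not organs:
        raise InvalidArgumentError("at least one organ required")
    r = np.array([o.sink_strength for o in organs], dtype=float)
    total = r.sum()
    if total <= 0:
        if supply.e > 0:
            raise AllocationError(
                "allocation undefined: all sink strengths are zero with E > 0"
            )
        return np.zeros(len(organs))
    q = r / total * supply.e
    pos = np.flatnonzero(r > 0)
    q[pos[-1]] += supply.e - q.sum()
    return q


def update_vcmax(
    organ: OrganState, light_capture_ratio: float, beta: float, vcmax_ref: float = 60.0
) -> float:
    """Light-capture feedback on photosynthetic capacity.

    Vcmax_new = Vcmax_ref * clamp(ratio, 0.2, 1.5)^beta; the clamp keeps
    a collapsing or exploding canopy from driving capacity to 0 or
    infinity, and ratio = 1 returns the reference exactly.
    """
    if light_capture_ratio < 0:
        raise InvalidArgumentError("light_capture_ratio must be >= 0")
    ratio = min(max(light_capture_ratio, 0.2), 1.5)
    new = vcmax_ref * ratio**beta
    organ.vcmax = new
    return new
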