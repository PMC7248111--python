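"""Pool-scale drying physics for sessile blood pools on non-porous surfaces.

A blood pool sits between the two classical evaporation regimes.  It is much
wider than the capillary length ``sqrt(gamma/(rho g))`` (a few millimetres for
blood), so gravity flattens it into a pancake of nearly uniform height, yet
desiccation starts at the triple line and a drying front recedes toward the
centre, so edge effects cannot be neglected as they are for an open stretch of
water.  The model used throughout this package captures that intermediate
character with three ingredients:

* a **shape factor** ``L* = A / (h P)`` relating the evaporating plan area to
  the pool height and perimeter — thin, stretched pools (large perimeter per
  unit area) evaporate faster than compact round ones of equal volume;
* the **Knudsen layer** thickness ``L_k = k T / (pi d^2 P_a)``, the thin
  vapour layer just above the liquid through which evaporative mass transfer
  occurs, used to convert between a transfer coefficient (m/s) and a
  diffusion coefficient (m^2/s);
* a single effective **diffusion coefficient** ``D`` for drying blood
  (plateau value ~1e-9 m^2/s at ~23 degC and 20% RH), from which the areal
  evaporation rate of a given pool follows as

  ``J* = D * M * P_w / (L_k * R * T * sqrt(L*))``   [kg m^-2 s^-1]

with ``M`` the molar mass of water, ``P_w`` the saturation vapour pressure at
the surface temperature, ``R`` the gas constant and ``T`` the temperature.

All quantities here are strict SI (kg, m, s, K, Pa, rad).  Unit conversion
from field-friendly units (g, mm, degC, %) happens at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .errors import ApproximationRangeError, InputError, ModelDomainError

__all__ = [
    "PhysicalConstants",
    "EnvironmentConditions",
    "FluidProperties",
    "PoolGeometry",
    "DEFAULT_CONSTANTS",
    "volume_from_mass",
    "height_from_volume_area",
    "shape_factor",
    "contact_angle",
    "saturation_vapour_pressure",
    "knudsen_layer",
    "evaporation_rate_from_diffusion",
    "diffusion_from_evaporation_rate",
    "mass_from_geometry",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (CODATA values by default).

    Attributes
    ----------
    boltzmann_k : float
        Boltzmann constant, J/K.
    gas_constant_R : float
        Universal gas constant, J/(mol K).
    gravity_g : float
        Standard gravitational acceleration, m/s^2.
    """

    boltzmann_k: float = 1.380649e-23
    gas_constant_R: float = 8.31446261815324
    gravity_g: float = 9.80665

    def __post_init__(self) -> None:
        for name in ("boltzmann_k", "gas_constant_R", "gravity_g"):
            if not getattr(self, name) > 0:
                raise InputError(f"PhysicalConstants.{name} must be > 0")


@dataclass(frozen=True)
class EnvironmentConditions:
    """Ambient conditions governing the drying physics.

    Attributes
    ----------
    temperature : float
        Air/surface temperature in kelvin (> 200 K).
    relative_humidity : float
        Relative humidity as a fraction in [0, 1].
    atmospheric_pressure : float
        Total pressure in Pa.
    """

    temperature: float
    relative_humidity: float = 0.20
    atmospheric_pressure: float = 101325.0

    def __post_init__(self) -> None:
        if not self.temperature > 200.0:
            raise InputError(f"temperature must be > 200 K, got {self.temperature}")
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise InputError(
                f"relative_humidity must lie in [0, 1], got {self.relative_humidity}"
            )
        if not self.atmospheric_pressure > 0:
            raise InputError("atmospheric_pressure must be > 0")


@dataclass(frozen=True)
class FluidProperties:
    """Whole-blood and water properties entering the drying model.

    Defaults are literature values for healthy whole blood and water vapour;
    the exact values used when the calibration constants were established are
    not known, so every field is configurable.

    Attributes
    ----------
    density_rho : float
        Whole-blood density, kg/m^3.
    surface_tension_gamma : float
        Blood/air surface tension, N/m.
    water_molar_mass_M : float
        Molar mass of water, kg/mol.
    water_molecular_diameter_d : float
        Effective molecular diameter of water, m (kinetic theory).
    haematocrit : float
        Red-cell volume fraction; carried as metadata (healthy adults span
        roughly 0.36-0.47), not used by the evaporation formulas.
    residual_mass_fraction : float
        Fraction of the initial pool mass left as dry biological deposit
        after all evaporable water has gone (~0.23 for whole blood).
    """

    density_rho: float = 1060.0
    surface_tension_gamma: float = 0.058
    water_molar_mass_M: float = 0.018015
    water_molecular_diameter_d: float = 2.75e-10
    haematocrit: float = 0.45
    residual_mass_fraction: float = 0.23

    def __post_init__(self) -> None:
        if not self.density_rho > 0:
            raise InputError("density_rho must be > 0")
        if not self.surface_tension_gamma > 0:
            raise InputError("surface_tension_gamma must be > 0")
        if not self.water_molar_mass_M > 0:
            raise InputError("water_molar_mass_M must be > 0")
        if not self.water_molecular_diameter_d > 0:
            raise InputError("water_molecular_diameter_d must be > 0")
        if not 0.0 <= self.haematocrit < 1.0:
            raise InputError("haematocrit must lie in [0, 1)")
        if not 0.0 < self.residual_mass_fraction < 1.0:
            raise InputError("residual_mass_fraction must lie in (0, 1)")


#: Isoperimetric slack tolerated on rasterised geometry (P^2 >= 4*pi*A*(1-tol)).
_ISOPERIMETRIC_TOL = 0.05


@dataclass(frozen=True)
class PoolGeometry:
    """Plan-view geometry of a single pool at formation time.

    Attributes
    ----------
    total_area : float
        Total (initial) plan area A_i, m^2.
    perimeter : float
        Pool perimeter P, m.
    height : float
        Mean pool height h, m.
    initial_mass : float
        Initial pool mass m_i, kg.
    """

    total_area: float
    perimeter: float
    height: float
    initial_mass: float

    def __post_init__(self) -> None:
        for name in ("total_area", "perimeter", "height", "initial_mass"):
            if not getattr(self, name) > 0:
                raise InputError(f"PoolGeometry.{name} must be > 0")
        # No closed plane curve has P^2 < 4*pi*A; allow small raster slack.
        if self.perimeter**2 < 4.0 * math.pi * self.total_area * (1.0 - _ISOPERIMETRIC_TOL):
            raise InputError(
                "geometry violates the isoperimetric inequality: "
                f"P^2 = {self.perimeter**2:.3e} < 4*pi*A = "
                f"{4.0 * math.pi * self.total_area:.3e}"
            )


DEFAULT_CONSTANTS = PhysicalConstants()


def volume_from_mass(mass: float, fluid: FluidProperties) -> float:
    """Pool volume from its mass, ``V = m / rho``.

    Parameters
    ----------
    mass : float
        Pool mass in kg, > 0.
    fluid : FluidProperties
        Supplies the blood density.
    """
    if not mass > 0:
        raise InputError(f"mass must be > 0, got {mass}")
    return mass / fluid.density_rho


def height_from_volume_area(volume: float, area: float) -> float:
    """Mean pool height from volume and plan area, ``h = V / A``.

    Valid in the gravity-flattened pancake limit where the height is nearly
    uniform across the pool.
    """
    if not area > 0:
        raise InputError(f"area must be > 0, got {area}")
    if volume < 0:
        raise InputError(f"volume must be >= 0, got {volume}")
    return volume / area


def shape_factor(geometry: PoolGeometry) -> float:
    """Dimensionless shape factor ``L* = A / (h P)``.

    Large ``L*`` means a compact pool (much area per unit of evaporating
    edge); small ``L*`` a thin, stretched one.  The areal evaporation rate
    scales as ``L*^(-1/2)``.
    """
    return geometry.total_area / (geometry.height * geometry.perimeter)


def contact_angle(
    geometry: PoolGeometry,
    fluid: FluidProperties,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Apparent contact angle of a gravity-flattened pool, in radians.

    For a puddle flattened by gravity the force balance at the edge gives
    ``1 - cos(theta) = rho * g * h^2 / (2 * gamma)`` with the pancake height
    ``h = m_i / (rho * A_i)``, hence

        ``theta = arccos(1 - g * m_i^2 / (2 * gamma * rho * A_i^2))``.

    Raises
    ------
    ApproximationRangeError
        If the arccos argument falls below -1: the implied height exceeds
        what a puddle can sustain, i.e. the pancake approximation is out of
        range.  The argument is never clamped.
    """
    x = (
        constants.gravity_g
        * geometry.initial_mass**2
        / (2.0 * fluid.surface_tension_gamma * fluid.density_rho * geometry.total_area**2)
    )
    arg = 1.0 - x
    if arg < -1.0:
        raise ApproximationRangeError(
            "puddle approximation out of range: arccos argument "
            f"{arg:.4f} < -1 (pool too heaped for its area)"
        )
    return math.acos(arg)


def saturation_vapour_pressure(temperature: float) -> float:
    """Saturation vapour pressure of water, Pa, by the Buck correlation.

    ``P_w(T) = 611.21 * exp((18.678 - t/234.5) * t / (257.14 + t))`` with
    ``t`` in degC.  Accurate to well under 0.1% over 0-100 degC, far below
    every other error source in the drying model.  Any function with the
    same signature can be passed to the rate formulas instead.

    Raises
    ------
    ModelDomainError
        For temperatures outside 273-373.15 K.
    """
    if not 273.0 <= temperature <= 373.15:
        raise ModelDomainError(
            f"saturation_vapour_pressure valid for 273-373.15 K, got {temperature}"
        )
    t = temperature - 273.15
    return 611.21 * math.exp((18.678 - t / 234.5) * t / (257.14 + t))


def knudsen_layer(
    env: EnvironmentConditions,
    fluid: FluidProperties,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Knudsen layer thickness ``L_k = k T / (pi d^2 P_a)``, m.

    The mean free path of a vapour molecule just above the liquid surface;
    used as the characteristic length converting the convective transfer
    coefficient into a diffusion coefficient.  ~1.7e-7 m at ambient
    conditions.
    """
    return (
        constants.boltzmann_k
        * env.temperature
        / (math.pi * fluid.water_molecular_diameter_d**2 * env.atmospheric_pressure)
    )


def evaporation_rate_from_diffusion(
    diffusion_coefficient: float,
    lstar: float,
    env: EnvironmentConditions,
    fluid: FluidProperties,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    use_humidity_deficit: bool = False,
    svp: Callable[[float], float] = saturation_vapour_pressure,
) -> float:
    """Areal evaporation rate ``J*`` of a pool from the diffusion coefficient.

    ``J* = D * M * P_w / (L_k * R * T * sqrt(L*))`` in kg m^-2 s^-1.

    Parameters
    ----------
    diffusion_coefficient : float
        Effective vapour diffusion coefficient D, m^2/s (> 0); ~1e-9 for
        drying blood at ~23 degC / 20% RH.
    lstar : float
        Shape factor of the pool (> 0).
    use_humidity_deficit : bool
        If True, multiply by ``(1 - RH)`` so the driving pressure is the
        vapour-pressure deficit rather than the full saturation pressure.
        Off by default: the calibrated model uses the saturation pressure
        as-is and folds ambient humidity into D.
    svp : callable
        Saturation vapour pressure strategy, Pa as a function of K.
    """
    if not diffusion_coefficient > 0:
        raise InputError("diffusion_coefficient must be > 0")
    if not lstar > 0:
        raise InputError("lstar must be > 0")
    p_w = svp(env.temperature)
    if use_humidity_deficit:
        p_w *= 1.0 - env.relative_humidity
    l_k = knudsen_layer(env, fluid, constants)
    return (
        diffusion_coefficient
        * fluid.water_molar_mass_M
        * p_w
        / (l_k * constants.gas_constant_R * env.temperature * math.sqrt(lstar))
    )


def diffusion_from_evaporation_rate(
    jstar: float,
    lstar: float,
    env: EnvironmentConditions,
    fluid: FluidProperties,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    use_humidity_deficit: bool = False,
    svp: Callable[[float], float] = saturation_vapour_pressure,
) -> float:
    """Diffusion coefficient from a measured areal evaporation rate.

    ``D = J* * R * T * L_k * sqrt(L*) / (M * P_w)`` — the exact algebraic
    inverse of :func:`evaporation_rate_from_diffusion`.  Weighting measured
    wet-area rates this way collapses pools of different sizes and shapes
    onto a common plateau, which is how the calibration constant D was
    established.
    """
    if jstar < 0:
        raise InputError("jstar must be >= 0")
    if not lstar > 0:
        raise InputError("lstar must be > 0")
    p_w = svp(env.temperature)
    if use_humidity_deficit:
        p_w *= 1.0 - env.relative_humidity
    l_k = knudsen_layer(env, fluid, constants)
    return (
        jstar
        * constants.gas_constant_R
        * env.temperature
        * l_k
        * math.sqrt(lstar)
        / (fluid.water_molar_mass_M * p_w)
    )


def mass_from_geometry(geometry: PoolGeometry, fluid: FluidProperties) -> float:
    """Initial pool mass from plan geometry, ``m_i = h * A * rho``."""
    return geometry.height * geometry.total_area * fluid.density_rho
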