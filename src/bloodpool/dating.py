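"""Time-since-deposition estimation for drying blood pools.

The forensic product of the package: given the total area ``A_i``, wet area
``A_x`` and perimeter ``P`` of a pool photographed while its drying front is
visible, plus a surface height prior and ambient conditions, estimate the
elapsed time since the pool was formed.

Two algebraically equivalent routes are provided:

* **chained** — compute each stage explicitly: ``h`` from the surface prior,
  ``m_i = h A_i rho``, ``L* = A_i/(h P)``,
  ``J* = D M P_w / (L_k R T sqrt(L*))``, ``m_x`` from the mass-area relation
  ``m/m_i = 1 - alpha (1 - A/A_i)^beta``, and finally
  ``delta_t = (m_i - m_x) / (J* A_i)``;
* **closed form** — the single expression obtained by composing the stages,

  ``t_x = alpha R k_B T^2 sqrt(A_i) sqrt(h) rho (1 - A_x/A_i)^beta
          / (M d^2 pi sqrt(P) D P_w P_a)``.

Uncertainty is propagated by seeded Monte Carlo over the height prior and
area/perimeter measurement noise; the point estimate is the median of the
draws (the mean is unstable under the sqrt(h) nonlinearity) and the interval
the central 90% by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate

from .errors import (
    CalibrationDomainError,
    FullyDriedError,
    InputError,
    StillWetError,
)
from .physics import (
    DEFAULT_CONSTANTS,
    EnvironmentConditions,
    FluidProperties,
    PhysicalConstants,
    PoolGeometry,
    evaporation_rate_from_diffusion,
    knudsen_layer,
    saturation_vapour_pressure,
)

__all__ = [
    "SurfacePrior",
    "CalibratedModel",
    "Snapshot",
    "AgeEstimate",
    "TILE_PRIOR",
    "SURFACE_PRIORS",
    "mass_from_wet_area",
    "elapsed_time_chained",
    "elapsed_time_closed_form",
    "estimate_age_with_uncertainty",
    "check_calibration_domain",
]


@dataclass(frozen=True)
class SurfacePrior:
    """Prior on pool height for a given substrate.

    Pool height cannot be measured from a plan-view photograph, so it is
    taken from repeat measurements on the same surface type.  The shipped
    ``tile`` prior (1.44 +/- 0.19 mm) comes from 30 pools on white tile;
    other surfaces need user-supplied priors.
    """

    surface_label: str
    height_mean: float  # m
    height_sd: float  # m

    def __post_init__(self) -> None:
        if not self.height_mean > 0:
            raise InputError("height_mean must be > 0")
        if self.height_sd < 0:
            raise InputError("height_sd must be >= 0")


@dataclass(frozen=True)
class CalibratedModel:
    """Calibration constants of the dating model.

    ``d_blood`` is the plateau diffusion coefficient of drying blood
    (1e-9 m^2/s, established at ~23 degC and 20% RH on non-porous surfaces);
    ``mass_area_alpha``/``mass_area_beta`` parameterise the empirical
    wet-area-to-mass relation (0.78, 0.16).
    """

    d_blood: float = 1e-9
    mass_area_alpha: float = 0.78
    mass_area_beta: float = 0.16

    def __post_init__(self) -> None:
        if not self.d_blood > 0:
            raise InputError("d_blood must be > 0")
        if not 0.0 < self.mass_area_alpha < 1.0:
            raise InputError("mass_area_alpha must lie in (0, 1)")
        if not self.mass_area_beta > 0:
            raise InputError("mass_area_beta must be > 0")


TILE_PRIOR = SurfacePrior("tile", height_mean=1.44e-3, height_sd=0.19e-3)

#: Priors shipped with the package; only tile is calibrated.
SURFACE_PRIORS: dict[str, SurfacePrior] = {"tile": TILE_PRIOR}

#: Validity window of the calibration constants (T in K, RH as fraction).
_CAL_T_RANGE = (295.15, 297.15)  # 22-24 degC
_CAL_RH_RANGE = (0.15, 0.25)


def check_calibration_domain(env: EnvironmentConditions, force: bool = False) -> list[str]:
    """Refuse (or warn, with force=True) outside the calibration conditions.

    D was established at ~23 degC / 20% RH; the plateau is condition
    specific, so estimates outside 22-24 degC or 15-25% RH are refused
    unless ``force`` is set, in which case warnings are returned instead.
    """
    problems = []
    if not _CAL_T_RANGE[0] <= env.temperature <= _CAL_T_RANGE[1]:
        problems.append(
            f"temperature {env.temperature - 273.15:.1f} degC outside the "
            "22-24 degC calibration range"
        )
    if not _CAL_RH_RANGE[0] <= env.relative_humidity <= _CAL_RH_RANGE[1]:
        problems.append(
            f"relative humidity {100 * env.relative_humidity:.0f}% outside the "
            "15-25% calibration range"
        )
    if problems and not force:
        raise CalibrationDomainError("; ".join(problems) + " (pass force=True to override)")
    return problems


def mass_from_wet_area(
    wet_area: float, total_area: float, initial_mass: float, model: CalibratedModel
) -> float:
    """Pool mass inferred from its wet area via the mass-area relation.

    ``m_x = m_i * (1 - alpha * (1 - A_x/A_i)^beta)``.
    """
    if wet_area < 0 or wet_area > total_area * (1 + 1e-12):
        raise InputError("wet_area must lie in [0, total_area]")
    u = max(0.0, 1.0 - wet_area / total_area)
    return initial_mass * (1.0 - model.mass_area_alpha * u**model.mass_area_beta)


def _validate_front(wet_area: float, total_area: float, perimeter: float) -> None:
    if not total_area > 0 or not perimeter > 0:
        raise InputError("total_area and perimeter must be > 0")
    if wet_area > total_area * (1 + 1e-12):
        raise InputError("wet_area exceeds total_area")
    if wet_area >= total_area:
        raise StillWetError(
            "pool still fully wet: no drying front to date; re-photograph later"
        )
    if wet_area <= 0:
        raise FullyDriedError("pool fully dried: the drying-front method no longer applies")


def elapsed_time_chained(
    wet_area: float,
    total_area: float,
    perimeter: float,
    surface: SurfacePrior,
    env: EnvironmentConditions,
    fluid: FluidProperties,
    model: CalibratedModel,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    flux_basis: Literal["total", "wet"] = "total",
    use_humidity_deficit: bool = False,
    height: float | None = None,
) -> float:
    """Elapsed time since formation, via the explicit stage-by-stage chain.

    With the default total-area flux basis this evaluates
    ``delta_t = (m_i - m_x) / (J* A_i)``.  The ``wet`` basis instead treats
    ``J*`` as a flux through the instantaneous wet area and integrates
    ``dt = dm / (J* A_wet(m))`` along the mass-area relation; it is provided
    for research use and is not the calibrated default.

    ``height`` overrides the prior mean (used for Monte-Carlo draws).
    """
    _validate_front(wet_area, total_area, perimeter)
    h = surface.height_mean if height is None else height
    if not h > 0:
        raise InputError("height must be > 0")
    m_i = h * total_area * fluid.density_rho
    geometry = PoolGeometry(
        total_area=total_area, perimeter=perimeter, height=h, initial_mass=m_i
    )
    lstar = geometry.total_area / (geometry.height * geometry.perimeter)
    jstar = evaporation_rate_from_diffusion(
        model.d_blood, lstar, env, fluid, constants, use_humidity_deficit
    )
    alpha, beta = model.mass_area_alpha, model.mass_area_beta
    u_x = 1.0 - wet_area / total_area
    if flux_basis == "total":
        m_x = mass_from_wet_area(wet_area, total_area, m_i, model)
        return (m_i - m_x) / (jstar * total_area)
    if flux_basis == "wet":
        # dt = dm / (J* A_wet(m)); substitute w = u^beta so the integrand is
        # smooth at the fully-wet end: dm = -m_i alpha dw, A_wet = A_i (1 - w^(1/beta)).
        w_x = u_x**beta

        def integrand(w: float) -> float:
            return 1.0 / (1.0 - w ** (1.0 / beta))

        val, _ = integrate.quad(integrand, 0.0, w_x, limit=200)
        return m_i * alpha * val / (jstar * total_area)
    raise InputError(f"unknown flux basis {flux_basis!r}")


def elapsed_time_closed_form(
    wet_area: float,
    total_area: float,
    perimeter: float,
    surface: SurfacePrior,
    env: EnvironmentConditions,
    fluid: FluidProperties,
    model: CalibratedModel,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    use_humidity_deficit: bool = False,
    height: float | None = None,
) -> float:
    """Elapsed time since formation, single closed-form expression.

    ``t_x = alpha R k_B T^2 sqrt(A_i) sqrt(h) rho (1 - A_x/A_i)^beta /
    (M d^2 pi sqrt(P) D P_w P_a)`` — the algebraic composition of the
    chained route (total-area flux basis); the two agree to rounding error.
    """
    _validate_front(wet_area, total_area, perimeter)
    h = surface.height_mean if height is None else height
    if not h > 0:
        raise InputError("height must be > 0")
    T = env.temperature
    p_w = saturation_vapour_pressure(T)
    if use_humidity_deficit:
        p_w *= 1.0 - env.relative_humidity
    u = 1.0 - wet_area / total_area
    return (
        model.mass_area_alpha
        * constants.gas_constant_R
        * constants.boltzmann_k
        * T**2
        * math.sqrt(total_area)
        * math.sqrt(h)
        * fluid.density_rho
        * u**model.mass_area_beta
    ) / (
        fluid.water_molar_mass_M
        * fluid.water_molecular_diameter_d**2
        * math.pi
        * math.sqrt(perimeter)
        * model.d_blood
        * p_w
        * env.atmospheric_pressure
    )


@dataclass(frozen=True)
class Snapshot:
    """One photographic measurement of a pool (SI units)."""

    wet_area: float
    total_area: float
    perimeter: float
    capture_time: float = 0.0  # s, on any common clock (used for multi-snapshot)


@dataclass
class AgeEstimate:
    """Elapsed time since pool formation with uncertainty and provenance.

    ``elapsed_time`` is the age of the pool at the latest snapshot's capture
    time; ``interval`` is the central ``coverage`` interval of the Monte
    Carlo draws; ``inputs_snapshot`` records every constant, parameter and
    flag that entered the computation (forensic provenance requirement).
    """

    elapsed_time: float
    interval: tuple[float, float]
    coverage: float
    method: Literal["closed_form", "chained"]
    n_draws: int
    inputs_snapshot: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.elapsed_time <= hi):
            raise InputError("point estimate must lie inside the interval")
        if self.elapsed_time < 0:
            raise InputError("elapsed_time must be >= 0")


def _closed_form_vec(
    wet_area: np.ndarray,
    total_area: np.ndarray,
    perimeter: np.ndarray,
    h: np.ndarray,
    env: EnvironmentConditions,
    fluid: FluidProperties,
    model: CalibratedModel,
    constants: PhysicalConstants,
    use_humidity_deficit: bool,
) -> np.ndarray:
    """Vectorised closed form; area ratios >= 1 are treated as age 0."""
    T = env.temperature
    p_w = saturation_vapour_pressure(T)
    if use_humidity_deficit:
        p_w *= 1.0 - env.relative_humidity
    u = np.clip(1.0 - wet_area / total_area, 0.0, 1.0)
    num = (
        model.mass_area_alpha
        * constants.gas_constant_R
        * constants.boltzmann_k
        * T**2
        * np.sqrt(total_area)
        * np.sqrt(h)
        * fluid.density_rho
        * u**model.mass_area_beta
    )
    den = (
        fluid.water_molar_mass_M
        * fluid.water_molecular_diameter_d**2
        * math.pi
        * np.sqrt(perimeter)
        * model.d_blood
        * p_w
        * env.atmospheric_pressure
    )
    return num / den


def estimate_age_with_uncertainty(
    snapshots: Sequence[Snapshot],
    surface: SurfacePrior,
    env: EnvironmentConditions,
    fluid: FluidProperties | None = None,
    model: CalibratedModel | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_draws: int = 2000,
    seed: int | None = 0,
    area_rel_sd: float = 0.02,
    coverage: float = 0.90,
    use_humidity_deficit: bool = False,
    force: bool = False,
) -> AgeEstimate:
    """Monte-Carlo age estimate from one or more drying-front snapshots.

    Each draw samples a pool height from the (positively truncated) surface
    prior and multiplicative Gaussian measurement noise of relative sd
    ``area_rel_sd`` on every measured area and perimeter, then evaluates the
    closed-form age per snapshot.  With several snapshots, each draw aligns
    them to a common formation time (capture time minus age) and takes the
    per-draw median formation time; repeated estimates as the pool dries
    therefore average down the uncertainty.  Point estimate: median of the
    draws; interval: central ``coverage`` fraction.

    With ``height_sd == 0`` and ``area_rel_sd == 0`` the draws are
    degenerate and the estimate equals the closed-form value exactly.
    """
    if len(snapshots) == 0:
        raise InputError("need at least one snapshot")
    if n_draws < 100:
        raise InputError("n_draws must be >= 100")
    fluid = fluid or FluidProperties()
    model = model or CalibratedModel()
    warnings = list(check_calibration_domain(env, force=force))

    for s in snapshots:
        _validate_front(s.wet_area, s.total_area, s.perimeter)

    rng = np.random.default_rng(seed)
    # Truncated-positive normal height draws.
    if surface.height_sd > 0:
        h = rng.normal(surface.height_mean, surface.height_sd, size=n_draws)
        bad = h <= 0
        while np.any(bad):  # resample the non-physical tail
            h[bad] = rng.normal(surface.height_mean, surface.height_sd, size=int(bad.sum()))
            bad = h <= 0
    else:
        h = np.full(n_draws, surface.height_mean)

    capture = np.array([s.capture_time for s in snapshots])
    ages = np.empty((len(snapshots), n_draws))
    for i, s in enumerate(snapshots):
        if area_rel_sd > 0:
            ax = s.wet_area * (1.0 + rng.normal(0.0, area_rel_sd, n_draws))
            ai = s.total_area * (1.0 + rng.normal(0.0, area_rel_sd, n_draws))
            pp = s.perimeter * (1.0 + rng.normal(0.0, area_rel_sd, n_draws))
            ax = np.clip(ax, 0.0, None)
            ai = np.clip(ai, 1e-12, None)
            pp = np.clip(pp, 1e-12, None)
        else:
            ax = np.full(n_draws, s.wet_area)
            ai = np.full(n_draws, s.total_area)
            pp = np.full(n_draws, s.perimeter)
        ages[i] = _closed_form_vec(
            ax, ai, pp, h, env, fluid, model, constants, use_humidity_deficit
        )

    if len(snapshots) == 1:
        age_draws = ages[0]
        t_ref = capture[0]
    else:
        t_ref = float(np.max(capture))
        formation = np.median(capture[:, None] - ages, axis=0)
        age_draws = t_ref - formation
    age_draws = np.clip(age_draws, 0.0, None)

    point = float(np.median(age_draws))
    tail = 0.5 * (1.0 - coverage)
    lo, hi = np.quantile(age_draws, [tail, 1.0 - tail])
    lo = min(float(lo), point)
    hi = max(float(hi), point)

    inputs = {
        "snapshots": [
            {
                "wet_area_m2": s.wet_area,
                "total_area_m2": s.total_area,
                "perimeter_m": s.perimeter,
                "capture_time_s": s.capture_time,
            }
            for s in snapshots
        ],
        "surface": {
            "label": surface.surface_label,
            "height_mean_m": surface.height_mean,
            "height_sd_m": surface.height_sd,
        },
        "environment": {
            "temperature_K": env.temperature,
            "relative_humidity": env.relative_humidity,
            "atmospheric_pressure_Pa": env.atmospheric_pressure,
        },
        "fluid": {
            "density_rho": fluid.density_rho,
            "surface_tension_gamma": fluid.surface_tension_gamma,
            "water_molar_mass_M": fluid.water_molar_mass_M,
            "water_molecular_diameter_d": fluid.water_molecular_diameter_d,
            "haematocrit": fluid.haematocrit,
            "residual_mass_fraction": fluid.residual_mass_fraction,
        },
        "model": {
            "d_blood_m2_s": model.d_blood,
            "mass_area_alpha": model.mass_area_alpha,
            "mass_area_beta": model.mass_area_beta,
        },
        "constants": {
            "boltzmann_k": constants.boltzmann_k,
            "gas_constant_R": constants.gas_constant_R,
            "gravity_g": constants.gravity_g,
        },
        "settings": {
            "n_draws": n_draws,
            "seed": seed,
            "area_rel_sd": area_rel_sd,
            "coverage": coverage,
            "use_humidity_deficit": use_humidity_deficit,
            "force": force,
        },
    }
    return AgeEstimate(
        elapsed_time=point,
        interval=(float(lo), float(hi)),
        coverage=coverage,
        method="closed_form",
        n_draws=n_draws,
        inputs_snapshot=inputs,
        warnings=tuple(warnings),
    )
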