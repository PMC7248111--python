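"""Forward drying simulator and photograph renderer.

Generates pools, drying records and photo sequences with the statistical
structure the analysis modules assume, so the whole pipeline is testable
without laboratory data.  The simulator composes the same model the
estimator inverts: a shape-factor-dependent areal flux
``J* = D M P_w / (L_k R T sqrt(L*))``, linear mass loss down to the residual
dry deposit, and a wet area that follows the inverted mass-area relation
``A_wet/A_i = 1 - ((1 - m/m_i)/alpha)^(1/beta)``.

Default scenario conditions mirror the calibration experiments: pools of
0.3-31 g on a non-porous tile at 23 degC and 20% relative humidity,
photographed every two minutes, with a ~23% residual deposit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .curves import DryingRecord
from .dating import TILE_PRIOR, CalibratedModel, SurfacePrior
from .errors import InputError
from .physics import (
    DEFAULT_CONSTANTS,
    EnvironmentConditions,
    FluidProperties,
    PhysicalConstants,
    PoolGeometry,
    evaporation_rate_from_diffusion,
    shape_factor,
)

__all__ = [
    "NoiseSpec",
    "PoolScenario",
    "ShapeSpec",
    "SimulationResult",
    "Frame",
    "REFERENCE_ENVIRONMENT",
    "generate_shape",
    "simulate_drying",
    "render_sequence",
    "cohort",
]

#: Conditions of the calibration experiments: 23 degC, 20% RH, 1 atm.
REFERENCE_ENVIRONMENT = EnvironmentConditions(
    temperature=296.15, relative_humidity=0.20, atmospheric_pressure=101325.0
)


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise levels for the simulated channels.

    ``area_rel_sd``: multiplicative relative sd on area observations (2%
    reflects repeat photographic measurements); ``mass_sd``: absolute sd in
    kg (1e-5 kg = the 0.01 g balance precision); ``height_sd``: sd of the
    true pool height around the surface-prior mean when drawing cohorts, m.
    """

    area_rel_sd: float = 0.02
    mass_sd: float = 1e-5
    height_sd: float = 0.0


@dataclass(frozen=True)
class PoolScenario:
    """Full specification of one synthetic pool; the seed fixes everything."""

    initial_mass: float  # kg
    shape_irregularity: float = 0.15
    environment: EnvironmentConditions = REFERENCE_ENVIRONMENT
    fluid: FluidProperties = field(default_factory=FluidProperties)
    model: CalibratedModel = field(default_factory=CalibratedModel)
    surface: SurfacePrior = TILE_PRIOR
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    flux_basis: Literal["total", "wet"] = "total"
    height: float | None = None  # true height; defaults to the surface prior mean

    def __post_init__(self) -> None:
        if not 1e-4 <= self.initial_mass <= 5e-2:
            raise InputError(
                "initial_mass must lie in [1e-4, 5e-2] kg (0.1-50 g), got "
                f"{self.initial_mass}"
            )
        if self.shape_irregularity < 0:
            raise InputError("shape_irregularity must be >= 0")
        if self.shape_irregularity > 0.6:
            raise InputError("shape_irregularity above 0.6 produces degenerate boundaries")

    @property
    def true_height(self) -> float:
        return self.surface.height_mean if self.height is None else self.height


@dataclass(frozen=True)
class ShapeSpec:
    """Exact polygon geometry of a generated pool boundary."""

    total_area: float
    perimeter: float
    boundary: np.ndarray  # (n, 2) closed-curve vertices, metres, centred on 0


def _polygon_area_perimeter(xy: np.ndarray) -> tuple[float, float]:
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(float(np.sum(x * y1 - x1 * y)))
    perim = float(np.sum(np.hypot(x1 - x, y1 - y)))
    return area, perim


def generate_shape(scenario: PoolScenario, n_vertices: int = 720) -> ShapeSpec:
    """Random pool boundary: a circle perturbed by low-order Fourier modes.

    The radius function ``r(phi) = r0 (1 + sum_k a_k cos(k phi + phi_k))``
    for modes k = 2..6 with amplitudes proportional to
    ``shape_irregularity`` stays star-shaped (hence simple) as long as it
    remains positive; the polygon is rescaled so its exact shoelace area
    equals the pancake area ``m_i / (rho h)``.  Zero irregularity gives a
    circle with P = 2 sqrt(pi A) to polygon tolerance.
    """
    target_area = scenario.initial_mass / (scenario.fluid.density_rho * scenario.true_height)
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 0]))
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    for _ in range(10):
        pert = np.zeros_like(phi)
        for k in range(2, 7):
            amp = scenario.shape_irregularity * rng.uniform(0.5, 1.0) / k
            pert += amp * np.cos(k * phi + rng.uniform(0.0, 2.0 * np.pi))
        r = 1.0 + pert
        if np.min(r) > 0.05:
            break
    else:
        raise InputError("could not generate a simple boundary at this irregularity")
    xy = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    area, _ = _polygon_area_perimeter(xy)
    xy *= np.sqrt(target_area / area)
    area, perim = _polygon_area_perimeter(xy)
    return ShapeSpec(total_area=area, perimeter=perim, boundary=xy)


def _wet_ratio_from_mass_ratio(
    mass_ratio: np.ndarray, model: CalibratedModel
) -> np.ndarray:
    """Inverted mass-area relation: A_wet/A_i from m/m_i, clipped to [0, 1]."""
    u = np.clip((1.0 - np.asarray(mass_ratio, float)) / model.mass_area_alpha, 0.0, 1.0)
    return np.clip(1.0 - u ** (1.0 / model.mass_area_beta), 0.0, 1.0)


@dataclass
class SimulationResult:
    """Noiseless ground truth plus a noisy observation record for one pool."""

    scenario: PoolScenario
    shape: ShapeSpec
    geometry: PoolGeometry
    jstar: float  # kg m^-2 s^-1, flux on the scenario's basis
    t_end: float  # s, time at which the mass reaches the residual plateau
    truth: DryingRecord
    record: DryingRecord

    def true_rate_series(self):
        """Exact analytic areal rate on the scenario's flux basis.

        By construction the flux is the constant ``jstar`` until the mass
        reaches the residual plateau and zero afterwards; this bypasses the
        finite-difference estimator and serves as its oracle.
        """
        from .curves import RateSeries, water_fraction_left

        m_res = self.scenario.fluid.residual_mass_fraction * self.scenario.initial_mass
        drying = self.truth.masses > m_res * (1 + 1e-12)
        rates = np.where(drying, self.jstar, 0.0)
        wf = water_fraction_left(self.truth, self.scenario.fluid)
        return RateSeries(
            times=self.truth.times.copy(),
            rates=rates,
            water_fraction=wf,
            area_basis=self.scenario.flux_basis,
        )


def simulate_drying(
    scenario: PoolScenario,
    dt: float = 120.0,
    t_max: float | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> SimulationResult:
    """Forward-simulate one drying pool sampled every ``dt`` seconds.

    Total-area basis (default, matching the dating estimator): the mass
    falls linearly, ``m(t) = m_i - J* A_i t``, until the residual deposit
    ``residual_mass_fraction * m_i`` is reached, then stays constant.  The
    total area is constant; the wet area follows the inverted mass-area
    relation.  Wet-area basis: ``dm/dt = -J* A_wet(m)`` is integrated by
    RK4 with fine substeps, so the wet-basis rate series is constant at
    ``J*`` by construction.

    The default cadence of 120 s matches two-minute time-lapse photography.
    Observation channels carry seeded Gaussian noise per the scenario's
    :class:`NoiseSpec`; the ``truth`` record is noiseless.
    """
    if not dt > 0:
        raise InputError("dt must be > 0")
    shape = generate_shape(scenario)
    h = scenario.true_height
    m_i = scenario.initial_mass
    fluid = scenario.fluid
    geometry = PoolGeometry(
        total_area=shape.total_area, perimeter=shape.perimeter, height=h, initial_mass=m_i
    )
    lstar = shape_factor(geometry)
    jstar = evaporation_rate_from_diffusion(
        scenario.model.d_blood, lstar, scenario.environment, fluid, constants
    )
    m_res = fluid.residual_mass_fraction * m_i
    a_i = shape.total_area

    if scenario.flux_basis == "total":
        t_end = (m_i - m_res) / (jstar * a_i)
        horizon = t_max if t_max is not None else 1.08 * t_end
        times = np.arange(0.0, horizon + 0.5 * dt, dt)
        masses = np.maximum(m_i - jstar * a_i * times, m_res)
    elif scenario.flux_basis == "wet":
        wet_of_m = lambda m: a_i * float(
            _wet_ratio_from_mass_ratio(np.array([m / m_i]), scenario.model)[0]
        )
        sub = max(1, int(np.ceil(dt / 5.0)))
        hstep = dt / sub
        t_list, m_list = [0.0], [m_i]
        t, m = 0.0, m_i
        hard_stop = t_max if t_max is not None else 1e9
        while m > m_res * (1 + 1e-12) and t < hard_stop:
            for _ in range(sub):
                f = lambda mm: -jstar * wet_of_m(max(mm, m_res))
                k1 = f(m)
                k2 = f(m + 0.5 * hstep * k1)
                k3 = f(m + 0.5 * hstep * k2)
                k4 = f(m + hstep * k3)
                m = m + hstep * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
                m = max(m, m_res)
            t += dt
            t_list.append(t)
            m_list.append(m)
        times = np.array(t_list)
        masses = np.array(m_list)
        t_end = float(times[-1])
    else:
        raise InputError(f"unknown flux basis {scenario.flux_basis!r}")

    wet = a_i * _wet_ratio_from_mass_ratio(masses / m_i, scenario.model)
    total = np.full_like(times, a_i)

    truth = DryingRecord(
        times=times.copy(),
        masses=masses.copy(),
        total_areas=total.copy(),
        wet_areas=wet.copy(),
        environment=scenario.environment,
        geometry=geometry,
        surface_label=scenario.surface.surface_label,
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 1]))
    noise = scenario.noise
    masses_obs = masses + rng.normal(0.0, noise.mass_sd, size=masses.shape)
    total_obs = total * (1.0 + rng.normal(0.0, noise.area_rel_sd, size=total.shape))
    wet_obs = wet * (1.0 + rng.normal(0.0, noise.area_rel_sd, size=wet.shape))
    total_obs = np.clip(total_obs, 1e-12, None)
    wet_obs = np.clip(wet_obs, 0.0, total_obs)
    masses_obs = np.clip(masses_obs, 0.0, None)
    record = DryingRecord(
        times=times.copy(),
        masses=masses_obs,
        total_areas=total_obs,
        wet_areas=wet_obs,
        environment=scenario.environment,
        geometry=geometry,
        surface_label=scenario.surface.surface_label,
    )
    return SimulationResult(
        scenario=scenario,
        shape=shape,
        geometry=geometry,
        jstar=jstar,
        t_end=t_end,
        truth=truth,
        record=record,
    )


@dataclass
class Frame:
    """One rendered photograph with its ground-truth masks."""

    time: float
    image: np.ndarray  # (H, W, 3) uint8
    pool_mask: np.ndarray  # bool
    wet_mask: np.ndarray  # bool, subset of pool_mask


# Renderer palette (RGB, 0-255): chosen so wet blood is a saturated red,
# dried blood a dark red-brown, cracks near-black, background neutral.
_BG = np.array([200, 200, 200], float)
_BAR = np.array([90, 90, 90], float)
_WET = np.array([178, 32, 40], float)
_DRY = np.array([60, 14, 16], float)
_CRACK = np.array([24, 9, 10], float)


def render_sequence(
    sim: SimulationResult,
    metres_per_pixel: float,
    image_size: tuple[int, int] = (256, 256),
    frame_indices: np.ndarray | None = None,
    cracks: bool = False,
    noise_sd: float = 3.0,
    seed: int | None = None,
) -> list[Frame]:
    """Render a photo sequence for a simulated pool, with ground-truth masks.

    Each frame shows the pool silhouette (from the generated boundary
    polygon) with a dried dark annulus between the rim and a wet red core.
    The core is obtained by thresholding the Euclidean distance transform of
    the pool mask — a uniform inward offset of the boundary, emulating a
    front that recedes toward the centre — with the threshold chosen so the
    core pixel count matches the simulated wet area to within one pixel.
    A neutral reference scale bar of 1 cm is drawn in the top-left corner.
    """
    from skimage.draw import polygon as draw_polygon

    if not metres_per_pixel > 0:
        raise InputError("metres_per_pixel must be > 0")
    hpx, wpx = image_size
    truth = sim.truth
    if frame_indices is None:
        frame_indices = np.arange(len(truth.times))
    rng = np.random.default_rng(sim.scenario.seed if seed is None else seed)

    centre = np.array([hpx / 2.0, wpx / 2.0])
    rows = centre[0] + sim.shape.boundary[:, 1] / metres_per_pixel
    cols = centre[1] + sim.shape.boundary[:, 0] / metres_per_pixel
    margin = 6.0
    if (
        rows.min() < margin
        or cols.min() < margin
        or rows.max() > hpx - margin
        or cols.max() > wpx - margin
    ):
        raise InputError(
            "pool does not fit in the image at this scale; decrease metres_per_pixel "
            "or enlarge image_size"
        )
    rr, cc = draw_polygon(rows, cols, shape=(hpx, wpx))
    pool_mask = np.zeros((hpx, wpx), bool)
    pool_mask[rr, cc] = True
    n_pool = int(pool_mask.sum())
    if n_pool == 0:
        raise InputError("rasterised pool is empty; scale too coarse")
    edt = ndimage.distance_transform_edt(pool_mask)
    pool_idx = np.flatnonzero(pool_mask.ravel())
    order = np.argsort(edt.ravel()[pool_idx], kind="stable")[::-1]  # deepest first

    bar_px = max(4, int(round(0.01 / metres_per_pixel)))
    bar = (slice(8, 13), slice(10, min(10 + bar_px, wpx - 10)))

    a_i = sim.geometry.total_area
    frames: list[Frame] = []
    crack_mask_full = None
    if cracks:
        crack_mask_full = _crack_texture(pool_mask, rng)
    for idx in frame_indices:
        ratio = float(truth.wet_areas[idx] / a_i)
        k = int(round(np.clip(ratio, 0.0, 1.0) * n_pool))
        wet_mask = np.zeros((hpx, wpx), bool)
        if k > 0:
            wet_mask.ravel()[pool_idx[order[:k]]] = True
        if wet_mask.sum() > n_pool:  # invariant breach, should be impossible
            raise RuntimeError("wet core larger than pool mask")
        img = np.empty((hpx, wpx, 3), float)
        img[:] = _BG
        img[bar] = _BAR
        dry_mask = pool_mask & ~wet_mask
        img[dry_mask] = _DRY
        if crack_mask_full is not None:
            img[dry_mask & crack_mask_full] = _CRACK
        img[wet_mask] = _WET
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, img.shape)
        frames.append(
            Frame(
                time=float(truth.times[idx]),
                image=np.clip(img, 0, 255).astype(np.uint8),
                pool_mask=pool_mask.copy(),
                wet_mask=wet_mask,
            )
        )
    return frames


def _crack_texture(pool_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random crack polylines (1-2 px wide) within the pool footprint."""
    h, w = pool_mask.shape
    out = np.zeros_like(pool_mask)
    ys, xs = np.nonzero(pool_mask)
    if len(ys) == 0:
        return out
    for _ in range(8):
        i = rng.integers(len(ys))
        y, x = float(ys[i]), float(xs[i])
        ang = rng.uniform(0, 2 * np.pi)
        for _step in range(200):
            yi, xi = int(round(y)), int(round(x))
            if not (0 <= yi < h and 0 <= xi < w) or not pool_mask[yi, xi]:
                break
            out[yi, xi] = True
            ang += rng.normal(0.0, 0.25)
            y += np.sin(ang)
            x += np.cos(ang)
    return ndimage.binary_dilation(out, iterations=1) & pool_mask


def cohort(
    preset: Literal["size_study", "shape_study"],
    seed: int = 0,
    base: PoolScenario | None = None,
) -> list[PoolScenario]:
    """Deterministic scenario cohorts mirroring the calibration experiments.

    ``size_study``: 5 pools spanning 0.30-31.37 g at fixed moderate
    irregularity.  ``shape_study``: 20 pools of ~5.24 g (within +/- 0.47 g)
    with irregularity swept from 0 to 0.4.  ``base`` overrides everything
    except mass, irregularity and seed.
    """
    template = base or PoolScenario(initial_mass=5.24e-3)
    ss = np.random.SeedSequence([int(seed), 2])
    rng = np.random.default_rng(ss)
    scenarios: list[PoolScenario] = []
    if preset == "size_study":
        masses_g = [0.30, 1.74, 5.41, 15.0, 31.37]
        for i, mg in enumerate(masses_g):
            scenarios.append(
                replace(
                    template,
                    initial_mass=mg * 1e-3,
                    shape_irregularity=0.10,
                    seed=int(seed) * 1000 + i,
                )
            )
    elif preset == "shape_study":
        irregularities = np.linspace(0.0, 0.4, 20)
        masses = 5.24e-3 + rng.uniform(-0.47e-3, 0.47e-3, size=20)
        for i in range(20):
            scenarios.append(
                replace(
                    template,
                    initial_mass=float(masses[i]),
                    shape_irregularity=float(irregularities[i]),
                    seed=int(seed) * 1000 + i,
                )
            )
    else:
        raise InputError(f"unknown preset {preset!r}")
    return scenarios
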