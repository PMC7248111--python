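"""Drying-curve analysis: rates, normalisation, plateau, empirical fits.

Takes time-stamped mass and/or area observations of a drying pool and turns
them into the quantities the dating model is calibrated on:

* areal evaporation-rate series on the total-area or wet-area basis;
* normalised drying curves (m/m_i vs t/t_f, A/A_i);
* the diffusion-coefficient series obtained by weighting wet-area rates by
  ``R T L_k sqrt(L*) / (M P_w)``, whose plateau defines the calibration
  constant D;
* the empirical mass-area relation ``m/m_i = 1 - alpha * (1 - A/A_i)^beta``
  and the shape-linear relation ``J*/L* = alpha * theta + beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, signal, stats

from .errors import EstimationError, InputError
from .physics import (
    DEFAULT_CONSTANTS,
    EnvironmentConditions,
    FluidProperties,
    PhysicalConstants,
    PoolGeometry,
    diffusion_from_evaporation_rate,
    shape_factor,
)

__all__ = [
    "DryingRecord",
    "RateSeries",
    "MassAreaFit",
    "ShapeLinearFit",
    "PlateauEstimate",
    "water_fraction_left",
    "evaporation_rate",
    "normalize_record",
    "weighted_rate_series",
    "estimate_plateau",
    "fit_mass_area",
    "fit_shape_linear",
    "mass_area_model",
    "DEFAULT_PLATEAU_WINDOW",
]

#: Water-fraction window over which the weighted rate series is averaged.
#: Excludes the pre-coagulation dip at the start and the tail where wet-area
#: measurements are biased.
DEFAULT_PLATEAU_WINDOW = (0.35, 0.85)

#: Relative mass rise (w.r.t. the observed mass range) tolerated before a
#: record is flagged as non-monotone.
_MASS_RISE_TOL = 0.02


def _as_channel(values, n: int, name: str) -> np.ndarray | None:
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise InputError(f"{name} must have the same length as times ({n}), got {arr.shape}")
    return arr


@dataclass
class DryingRecord:
    """Time-stamped observations of one drying pool.

    At least one of ``masses`` / ``wet_areas`` must be present; times must be
    strictly increasing.  A mass channel rising by more than ~2% of its range
    mid-series is flagged (not rejected) as ``non-monotone-mass``.
    """

    times: np.ndarray
    masses: np.ndarray | None = None
    total_areas: np.ndarray | None = None
    wet_areas: np.ndarray | None = None
    environment: EnvironmentConditions | None = None
    geometry: PoolGeometry | None = None
    surface_label: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise InputError("times must be a non-empty 1-D array")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.argmin(np.diff(self.times))) + 1
            raise InputError(f"times must be strictly increasing (violation at row {bad})")
        n = len(self.times)
        self.masses = _as_channel(self.masses, n, "masses")
        self.total_areas = _as_channel(self.total_areas, n, "total_areas")
        self.wet_areas = _as_channel(self.wet_areas, n, "wet_areas")
        if self.masses is None and self.wet_areas is None:
            raise InputError("record needs at least one of masses / wet_areas")
        if self.wet_areas is not None and self.total_areas is not None:
            slack = 1e-9 * np.maximum(self.total_areas, 1e-300)
            if np.any(self.wet_areas > self.total_areas + slack):
                raise InputError("wet_areas must not exceed total_areas")
        flags = list(self.flags)
        if self.masses is not None and len(self.masses) > 1:
            rng = float(np.max(self.masses) - np.min(self.masses))
            if rng > 0 and float(np.max(np.diff(self.masses))) > _MASS_RISE_TOL * rng:
                flags.append("non-monotone-mass")
        self.flags = tuple(dict.fromkeys(flags))

    @property
    def initial_mass(self) -> float:
        if self.geometry is not None:
            return self.geometry.initial_mass
        if self.masses is not None:
            return float(self.masses[0])
        raise InputError("record has neither geometry nor a mass channel")


@dataclass
class RateSeries:
    """Areal evaporation-rate series J*(t) on a declared area basis."""

    times: np.ndarray
    rates: np.ndarray
    water_fraction: np.ndarray
    area_basis: Literal["total", "wet"]


@dataclass(frozen=True)
class MassAreaFit:
    """Parameters of ``m/m_i = 1 - alpha * (1 - A/A_i)^beta``."""

    alpha: float
    beta: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise EstimationError(f"mass-area alpha out of (0,1): {self.alpha}")
        if not self.beta > 0:
            raise EstimationError(f"mass-area beta must be > 0: {self.beta}")


@dataclass(frozen=True)
class ShapeLinearFit:
    """Parameters of the shape-linear relation ``J*/L* = slope*theta + intercept``."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class PlateauEstimate:
    """Robust plateau value of a (weighted) rate series."""

    value: float
    spread: float  # median absolute deviation
    n_points: int
    window: tuple[float, float]


def water_fraction_left(record: DryingRecord, fluid: FluidProperties) -> np.ndarray:
    """Fraction of evaporable water remaining, per observation.

    ``(m(t) - m_res) / (m_i - m_res)`` with ``m_res`` the residual dry
    deposit ``residual_mass_fraction * m_i``, clipped to [0, 1].  1 at
    formation, 0 once only the biological deposit remains.
    """
    if record.masses is None:
        raise InputError("water_fraction_left requires a mass channel")
    m_i = record.initial_mass
    m_res = fluid.residual_mass_fraction * m_i
    if not m_i > m_res:
        raise InputError("initial mass must exceed the residual deposit mass")
    frac = (record.masses - m_res) / (m_i - m_res)
    return np.clip(frac, 0.0, 1.0)


def evaporation_rate(
    record: DryingRecord,
    basis: Literal["total", "wet"] = "total",
    fluid: FluidProperties | None = None,
    smooth_window: int | None = None,
) -> RateSeries:
    """Areal evaporation rate from finite differences of the mass channel.

    Centred differences on the raw (possibly irregular) time grid, divided by
    the basis area interpolated at each evaluation time.  The total basis
    falls back to the constant initial area from ``record.geometry`` when no
    total-area channel was recorded.  For a two-point record a single forward
    difference at the interval midpoint is returned.

    Parameters
    ----------
    smooth_window : int, optional
        Odd window length for Savitzky-Golay smoothing (order 2) of the mass
        channel before differencing.  Off by default.
    """
    if record.masses is None:
        raise InputError("evaporation_rate requires a mass channel")
    t = record.times
    if len(t) < 2:
        raise InputError("evaporation_rate needs at least two observations")
    fluid = fluid or FluidProperties()
    m = record.masses
    if smooth_window is not None:
        if smooth_window % 2 == 0 or smooth_window < 3:
            raise InputError("smooth_window must be an odd integer >= 3")
        w = min(smooth_window, len(m) if len(m) % 2 == 1 else len(m) - 1)
        if w >= 3:
            m = signal.savgol_filter(m, w, 2)

    if len(t) == 2:
        t_eval = np.array([0.5 * (t[0] + t[1])])
        dmdt = np.array([(m[0] - m[1]) / (t[1] - t[0])])
    else:
        t_eval = t[1:-1]
        dmdt = (m[:-2] - m[2:]) / (t[2:] - t[:-2])

    if basis == "wet":
        if record.wet_areas is None:
            raise InputError("wet basis requires a wet_areas channel")
        area = np.interp(t_eval, t, record.wet_areas)
    elif basis == "total":
        if record.total_areas is not None:
            area = np.interp(t_eval, t, record.total_areas)
        elif record.geometry is not None:
            area = np.full_like(t_eval, record.geometry.total_area)
        else:
            raise InputError("total basis requires total_areas or record.geometry")
    else:
        raise InputError(f"unknown area basis {basis!r}")
    if np.any(area <= 0):
        raise InputError("basis area must be strictly positive at all evaluation times")

    wf_all = water_fraction_left(record, fluid)
    wf = np.interp(t_eval, t, wf_all)
    return RateSeries(times=t_eval, rates=dmdt / area, water_fraction=wf, area_basis=basis)


def normalize_record(record: DryingRecord) -> dict[str, np.ndarray]:
    """Normalised drying curves: t/t_f, m/m_i, and area ratios.

    Returns whichever of the channels ``time``, ``mass``, ``total_area``,
    ``wet_area`` the record supports, each scaled into [0, 1] by its natural
    reference (final time, initial mass, initial total area).  Records that
    differ only by overall scale normalise to identical curves.
    """
    out: dict[str, np.ndarray] = {}
    t_f = float(record.times[-1])
    if not t_f > 0:
        raise InputError("final observation time must be > 0 for normalisation")
    out["time"] = record.times / t_f
    if record.masses is not None:
        out["mass"] = record.masses / record.initial_mass
    a_ref = None
    if record.total_areas is not None:
        a_ref = float(record.total_areas[0])
        out["total_area"] = record.total_areas / a_ref
    elif record.geometry is not None:
        a_ref = record.geometry.total_area
    if record.wet_areas is not None:
        ref = a_ref if a_ref is not None else float(record.wet_areas[0])
        out["wet_area"] = record.wet_areas / ref
    return out


def weighted_rate_series(
    rate: RateSeries,
    geometry: PoolGeometry,
    env: EnvironmentConditions,
    fluid: FluidProperties,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Diffusion-coefficient series from a wet-basis rate series.

    Applies ``D = J* R T L_k sqrt(L*) / (M P_w)`` pointwise.  Pools of
    different sizes and shapes drying in the same conditions collapse onto a
    common plateau in this representation; its level is the calibration
    constant D.
    """
    if rate.area_basis != "wet":
        raise InputError("weighted_rate_series requires a wet-basis rate series")
    lstar = shape_factor(geometry)
    rates = np.clip(rate.rates, 0.0, None)
    return np.array(
        [
            diffusion_from_evaporation_rate(j, lstar, env, fluid, constants)
            for j in rates
        ]
    )


def estimate_plateau(
    values: Sequence[float],
    water_fraction: Sequence[float],
    window: tuple[float, float] = DEFAULT_PLATEAU_WINDOW,
) -> PlateauEstimate:
    """Robust plateau level of a series over a water-fraction window.

    Median of the values whose water fraction lies inside ``window`` (default
    [0.35, 0.85], excluding the pre-coagulation dip and the biased tail);
    spread is the median absolute deviation.  Median/MAD rather than
    mean/std because tail excursions are asymmetric.
    """
    values = np.asarray(values, dtype=float)
    wf = np.asarray(water_fraction, dtype=float)
    if values.shape != wf.shape:
        raise InputError("values and water_fraction must have the same shape")
    lo, hi = window
    mask = (wf >= lo) & (wf <= hi)
    n = int(mask.sum())
    if n == 0:
        raise EstimationError(f"no points with water fraction in [{lo}, {hi}]")
    if n < 5:
        raise EstimationError(f"only {n} points inside the plateau window; need >= 5")
    sel = values[mask]
    med = float(np.median(sel))
    mad = float(np.median(np.abs(sel - med)))
    return PlateauEstimate(value=med, spread=mad, n_points=n, window=(lo, hi))


def mass_area_model(area_ratio: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """``m/m_i = 1 - alpha * (1 - A/A_i)^beta`` (anchored at (1, 1))."""
    return 1.0 - alpha * np.power(np.clip(1.0 - np.asarray(area_ratio, float), 0.0, None), beta)


def fit_mass_area(
    area_ratio: Sequence[float],
    mass_ratio: Sequence[float],
    p0: tuple[float, float] = (0.8, 0.2),
) -> MassAreaFit:
    """Fit the normalised mass-area relation by bounded nonlinear least squares.

    Fits ``m/m_i = 1 - alpha * (1 - A/A_i)^beta`` with alpha in (0, 1) and
    beta in (0, 2], starting from (0.8, 0.2).  Requires at least 5 pairs
    spanning an area-ratio range of at least 0.3.
    """
    a = np.asarray(area_ratio, dtype=float)
    m = np.asarray(mass_ratio, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise InputError("area_ratio and mass_ratio must be 1-D arrays of equal length")
    if len(a) < 5:
        raise InputError(f"need at least 5 pairs, got {len(a)}")
    if np.ptp(a) < 0.3:
        raise InputError(
            f"area-ratio span {np.ptp(a):.3f} < 0.3; fit would be ill-conditioned"
        )
    # measurement noise can push normalised ratios slightly past the ends
    if np.any(a < -0.05) or np.any(a > 1.05):
        raise InputError("area ratios must lie in [0, 1] (up to 5% measurement noise)")
    a = np.clip(a, 0.0, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            mass_area_model,
            a,
            m,
            p0=p0,
            bounds=([1e-9, 1e-9], [1.0 - 1e-9, 2.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise EstimationError(f"mass-area fit did not converge: {exc}") from exc
    resid = m - mass_area_model(a, *popt)
    return MassAreaFit(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def fit_shape_linear(
    theta: Sequence[float],
    jstar: Sequence[float],
    lstar: Sequence[float],
) -> ShapeLinearFit:
    """Ordinary least squares of ``J*/L*`` on the contact angle theta.

    ``theta`` in radians, ``jstar`` the per-pool average areal rate
    (conventionally averaged after 50% of the initial mass has evaporated so
    the slow final stage does not bias the mean), ``lstar`` the shape factor.
    """
    th = np.asarray(theta, dtype=float)
    j = np.asarray(jstar, dtype=float)
    l = np.asarray(lstar, dtype=float)
    if not (th.shape == j.shape == l.shape) or th.ndim != 1:
        raise InputError("theta, jstar, lstar must be 1-D arrays of equal length")
    if len(th) < 3:
        raise InputError(f"need at least 3 pools, got {len(th)}")
    if np.ptp(th) <= 1e-12 * max(1.0, float(np.max(np.abs(th)))):
        raise EstimationError("degenerate design: all contact angles equal")
    y = j / l
    res = stats.linregress(th, y)
    return ShapeLinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
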