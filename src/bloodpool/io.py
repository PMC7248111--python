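"""Shared I/O: CSV records, YAML configuration, JSON provenance reports.

Field units at this boundary are the convenient ones (g, mm^2, degC, %);
everything is converted to strict SI on the way in and back on the way out.

CSV schema (one row per observation): ``time_s`` plus any of ``mass_g``,
``total_area_mm2``, ``wet_area_mm2``.  Metadata travels in a YAML sidecar
with keys ``temperature_C``, ``rh_percent``, ``pressure_pa``, ``surface``,
``hct_percent``, ``initial_mass_g``, ``height_mm``, ``perimeter_mm``,
``initial_area_mm2``; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .curves import DryingRecord
from .dating import AgeEstimate
from .errors import InputError
from .physics import EnvironmentConditions, FluidProperties, PhysicalConstants, PoolGeometry

__all__ = [
    "read_drying_csv",
    "write_drying_csv",
    "read_metadata",
    "RunConfig",
    "SCHEMA_VERSION",
    "age_estimate_report",
    "age_estimate_from_report",
    "report_to_json",
]

SCHEMA_VERSION = "bloodpool-report/1"

_CSV_COLUMNS = ("time_s", "mass_g", "total_area_mm2", "wet_area_mm2")
_META_KEYS = (
    "temperature_C",
    "rh_percent",
    "pressure_pa",
    "surface",
    "hct_percent",
    "initial_mass_g",
    "height_mm",
    "perimeter_mm",
    "initial_area_mm2",
)


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15


def read_metadata(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML metadata sidecar."""
    with open(path) as fh:
        meta = yaml.safe_load(fh) or {}
    if not isinstance(meta, dict):
        raise InputError(f"metadata file {path} must contain a mapping")
    unknown = set(meta) - set(_META_KEYS)
    if unknown:
        raise InputError(f"unknown metadata keys in {path}: {sorted(unknown)}")
    return meta


def _environment_from_meta(meta: dict[str, Any]) -> EnvironmentConditions | None:
    if "temperature_C" not in meta:
        return None
    return EnvironmentConditions(
        temperature=celsius_to_kelvin(float(meta["temperature_C"])),
        relative_humidity=float(meta.get("rh_percent", 20.0)) / 100.0,
        atmospheric_pressure=float(meta.get("pressure_pa", 101325.0)),
    )


def _geometry_from_meta(meta: dict[str, Any], df: pd.DataFrame) -> PoolGeometry | None:
    if not {"height_mm", "perimeter_mm"} <= set(meta):
        return None
    if "initial_area_mm2" in meta:
        area = float(meta["initial_area_mm2"]) * 1e-6
    elif "total_area_mm2" in df.columns:
        area = float(df["total_area_mm2"].iloc[0]) * 1e-6
    else:
        return None
    height = float(meta["height_mm"]) * 1e-3
    if "initial_mass_g" in meta:
        mass = float(meta["initial_mass_g"]) * 1e-3
    elif "mass_g" in df.columns:
        mass = float(df["mass_g"].iloc[0]) * 1e-3
    else:
        mass = height * area * 1060.0
    return PoolGeometry(
        total_area=area,
        perimeter=float(meta["perimeter_mm"]) * 1e-3,
        height=height,
        initial_mass=mass,
    )


def read_drying_csv(
    path: str | Path, metadata: str | Path | dict[str, Any] | None = None
) -> DryingRecord:
    """Read a drying record from CSV (+ optional metadata sidecar) into SI.

    Raises :class:`InputError` naming the offending column/row for missing
    columns, non-numeric cells and non-monotone times.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty CSV file") from exc
    if df.empty:
        raise InputError(f"{path}: no observation rows")
    unknown = set(df.columns) - set(_CSV_COLUMNS)
    if unknown:
        raise InputError(f"{path}: unknown columns {sorted(unknown)}")
    if "time_s" not in df.columns:
        raise InputError(f"{path}: required column 'time_s' missing")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(f"{path}: non-numeric value in column '{col}', row {row}")
        df[col] = pd.to_numeric(df[col])

    meta: dict[str, Any] = {}
    if isinstance(metadata, (str, Path)):
        meta = read_metadata(metadata)
    elif isinstance(metadata, dict):
        unknown = set(metadata) - set(_META_KEYS)
        if unknown:
            raise InputError(f"unknown metadata keys: {sorted(unknown)}")
        meta = metadata

    times = df["time_s"].to_numpy(float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        row = int(np.argmin(np.diff(times))) + 1
        raise InputError(f"{path}: time_s not strictly increasing at row {row}")

    def col(name: str, scale: float) -> np.ndarray | None:
        if name in df.columns:
            return df[name].to_numpy(float) * scale
        return None

    return DryingRecord(
        times=times,
        masses=col("mass_g", 1e-3),
        total_areas=col("total_area_mm2", 1e-6),
        wet_areas=col("wet_area_mm2", 1e-6),
        environment=_environment_from_meta(meta),
        geometry=_geometry_from_meta(meta, df),
        surface_label=str(meta.get("surface", "")),
    )


def write_drying_csv(record: DryingRecord, path: str | Path) -> Path:
    """Write a record back to the CSV schema (g / mm^2 units)."""
    path = Path(path)
    data: dict[str, np.ndarray] = {"time_s": record.times}
    if record.masses is not None:
        data["mass_g"] = record.masses * 1e3
    if record.total_areas is not None:
        data["total_area_mm2"] = record.total_areas * 1e6
    if record.wet_areas is not None:
        data["wet_area_mm2"] = record.wet_areas * 1e6
    pd.DataFrame(data).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Run configuration


_ENV_KEYS = ("temperature_C", "rh_percent", "pressure_pa")


@dataclasses.dataclass
class RunConfig:
    """Declarative overrides for constants, fluid properties and environment.

    Serialises losslessly to/from YAML; unknown keys anywhere are rejected
    so a typo cannot silently fall back to a default.
    """

    constants: dict[str, float] = dataclasses.field(default_factory=dict)
    fluid: dict[str, float] = dataclasses.field(default_factory=dict)
    environment: dict[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        valid_const = {f.name for f in dataclasses.fields(PhysicalConstants)}
        valid_fluid = {f.name for f in dataclasses.fields(FluidProperties)}
        for section, valid in (
            ("constants", valid_const),
            ("fluid", valid_fluid),
            ("environment", set(_ENV_KEYS)),
        ):
            unknown = set(getattr(self, section)) - valid
            if unknown:
                raise InputError(f"unknown {section} keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def make_constants(self) -> PhysicalConstants:
        return PhysicalConstants(**self.constants)

    def make_fluid(self) -> FluidProperties:
        return FluidProperties(**self.fluid)

    def make_environment(self, default_temp_c: float = 23.0) -> EnvironmentConditions:
        env = dict(self.environment)
        return EnvironmentConditions(
            temperature=celsius_to_kelvin(float(env.get("temperature_C", default_temp_c))),
            relative_humidity=float(env.get("rh_percent", 20.0)) / 100.0,
            atmospheric_pressure=float(env.get("pressure_pa", 101325.0)),
        )


# ---------------------------------------------------------------------------
# JSON reports


def _seconds_to_hms(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def age_estimate_report(estimate: AgeEstimate) -> dict[str, Any]:
    """Schema-versioned provenance report for an age estimate.

    Every constant, parameter and flag that entered the computation is
    echoed into the report so the estimate can be audited and recomputed.
    """
    lo, hi = estimate.interval
    return {
        "schema": SCHEMA_VERSION,
        "age_s": estimate.elapsed_time,
        "age_hms": _seconds_to_hms(estimate.elapsed_time),
        "interval_s": [lo, hi],
        "interval_hms": [_seconds_to_hms(lo), _seconds_to_hms(hi)],
        "coverage": estimate.coverage,
        "method": estimate.method,
        "n_draws": estimate.n_draws,
        "inputs": estimate.inputs_snapshot,
        "warnings": list(estimate.warnings),
    }


def age_estimate_from_report(report: dict[str, Any]) -> AgeEstimate:
    """Rebuild an :class:`AgeEstimate` from its JSON report."""
    if report.get("schema") != SCHEMA_VERSION:
        raise InputError(f"unsupported report schema {report.get('schema')!r}")
    return AgeEstimate(
        elapsed_time=float(report["age_s"]),
        interval=(float(report["interval_s"][0]), float(report["interval_s"][1])),
        coverage=float(report["coverage"]),
        method=report["method"],
        n_draws=int(report["n_draws"]),
        inputs_snapshot=report["inputs"],
        warnings=tuple(report.get("warnings", ())),
    )


def report_to_json(obj: dict[str, Any]) -> str:
    """Deterministic JSON encoding (sorted keys, fixed layout)."""
    return json.dumps(obj, sort_keys=True, indent=2)
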