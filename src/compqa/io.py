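"""File formats and run configuration.

Plain-text formats only:

* slab measurement sets as CSV with named columns
  ``thickness_cm, depth_cm, field_size_cm, ratio`` (ratio = I/I0, converted
  to log-ratios on read);
* dose planes and compensator thickness maps as ASCII grids with a short
  ``key value`` header (rows, cols, spacing_mm, origin_mm, optional
  extras) followed by whitespace-separated rows;
* a YAML run configuration validated against a fixed schema (unknown keys
  rejected).

Numbers are written with 17 significant digits, so round-trips are exact
to double precision.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .commissioning import (
    DEFAULT_MSF_GRID,
    DEFAULT_RHO_GRID,
    SlabMeasurementSet,
    SlabRecord,
)
from .gamma import DEFAULT_CRITERIA_LEVELS, DosePlane, GammaCriteria
from .physics import DEFAULT_KAPPA, SlabSpec
from .synthetic import CompensatorMap, NoiseSpec, PlanSpec

__all__ = [
    "ParseError",
    "RunConfig",
    "read_slab_csv",
    "write_slab_csv",
    "read_dose_plane",
    "write_dose_plane",
    "read_compensator_map",
    "write_compensator_map",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file failed validation; the message names the offending row/key."""


# ---------------------------------------------------------------------------
# slab CSV

_SLAB_COLUMNS = ("thickness_cm", "depth_cm", "field_size_cm", "ratio")


def read_slab_csv(path) -> SlabMeasurementSet:
    """Read slab transmission readings; ratios become ln(I/I0)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _SLAB_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header line
        vals = {}
        for col in _SLAB_COLUMNS:
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {rownum}: non-numeric value "
                    f"{row[col]!r} in column {col}"
                ) from None
            if not np.isfinite(vals[col]):
                raise ParseError(f"{path}: row {rownum}: non-finite {col}")
        if vals["ratio"] <= 0:
            raise ParseError(f"{path}: row {rownum}: ratio must be positive")
        try:
            spec = SlabSpec(vals["thickness_cm"], vals["depth_cm"], vals["field_size_cm"])
            records.append(SlabRecord(spec, float(np.log(vals["ratio"]))))
        except ValueError as exc:
            raise ParseError(f"{path}: row {rownum}: {exc}") from None
    try:
        return SlabMeasurementSet(records, provenance=path.name)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_slab_csv(measured: SlabMeasurementSet, path) -> None:
    """Write a measurement set as CSV (log-ratios back to plain ratios)."""
    rows = [
        {
            "thickness_cm": r.spec.thickness,
            "depth_cm": r.spec.depth,
            "field_size_cm": r.spec.field_size,
            "ratio": float(np.exp(r.log_ratio)),
        }
        for r in measured.records
    ]
    pd.DataFrame(rows, columns=list(_SLAB_COLUMNS)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# ASCII grids

def _write_grid(path, values: np.ndarray, spacing, origin, extra: dict | None) -> None:
    values = np.asarray(values, dtype=float)
    sy, sx = (spacing, spacing) if np.ndim(spacing) == 0 else spacing
    oy, ox = origin
    buf = _io.StringIO()
    buf.write(f"rows {values.shape[0]}\n")
    buf.write(f"cols {values.shape[1]}\n")
    buf.write(f"spacing_mm {_FLOAT_FMT % sy} {_FLOAT_FMT % sx}\n")
    buf.write(f"origin_mm {_FLOAT_FMT % oy} {_FLOAT_FMT % ox}\n")
    for key, val in (extra or {}).items():
        buf.write(f"{key} {_FLOAT_FMT % val}\n")
    for row in values:
        buf.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def _read_grid(path) -> tuple[np.ndarray, tuple, tuple, dict]:
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, list[float]] = {}
    body_start = None
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        try:
            float(parts[0])
            body_start = i
            break
        except ValueError:
            try:
                header[parts[0]] = [float(v) for v in parts[1:]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 1}: non-numeric header value in {line!r}"
                ) from None
    for key in ("rows", "cols", "spacing_mm", "origin_mm"):
        if key not in header:
            raise ParseError(f"{path}: missing header line {key!r}")
    nrows, ncols = int(header["rows"][0]), int(header["cols"][0])
    if body_start is None:
        raise ParseError(f"{path}: no data rows found")
    body = [ln.split() for ln in lines[body_start:] if ln.strip()]
    if len(body) != nrows or any(len(r) != ncols for r in body):
        raise ParseError(
            f"{path}: body is {len(body)} row(s) of "
            f"{[len(r) for r in body[:1]] or ['?']} value(s), "
            f"header says {nrows} x {ncols}"
        )
    try:
        values = np.array(body, dtype=float)
    except ValueError:
        raise ParseError(f"{path}: non-numeric value in grid body") from None
    spacing = tuple(header["spacing_mm"])
    origin = tuple(header["origin_mm"])
    extra = {
        k: v[0]
        for k, v in header.items()
        if k not in ("rows", "cols", "spacing_mm", "origin_mm")
    }
    return values, spacing, origin, extra


def write_dose_plane(plane: DosePlane, path) -> None:
    _write_grid(path, plane.values, plane.spacing, plane.origin, None)


def read_dose_plane(path) -> DosePlane:
    values, spacing, origin, _ = _read_grid(path)
    try:
        return DosePlane(values, spacing=spacing, origin=origin)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_compensator_map(comp: CompensatorMap, path) -> None:
    # thickness stored in cm; spacing header stays in mm
    _write_grid(
        path,
        comp.thickness,
        comp.spacing,
        (0.0, 0.0),
        {"base_thickness_cm": comp.base_thickness},
    )


def read_compensator_map(path) -> CompensatorMap:
    values, spacing, _, extra = _read_grid(path)
    if "base_thickness_cm" not in extra:
        raise ParseError(f"{path}: missing header line 'base_thickness_cm'")
    if spacing[0] != spacing[1]:
        raise ParseError(f"{path}: compensator maps must have isotropic spacing")
    try:
        return CompensatorMap(values, spacing[0], extra["base_thickness_cm"])
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# run configuration

def _grid_from_spec(spec, name: str) -> np.ndarray:
    if isinstance(spec, dict):
        unknown = set(spec) - {"start", "stop", "step"}
        if unknown:
            raise ParseError(f"config: unknown key(s) {sorted(unknown)} in {name}")
        try:
            grid = np.round(
                np.arange(spec["start"], spec["stop"] + 1e-9, spec["step"]), 10
            )
        except KeyError as exc:
            raise ParseError(f"config: {name} needs start/stop/step") from None
    else:
        grid = np.asarray(spec, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ParseError(f"config: {name} must be strictly increasing")
    return grid


@dataclass
class RunConfig:
    """Resolved configuration for the commissioning workflows."""

    kappa: float = DEFAULT_KAPPA
    rho_grid: np.ndarray = field(default_factory=lambda: DEFAULT_RHO_GRID.copy())
    msf_grid: np.ndarray = field(default_factory=lambda: DEFAULT_MSF_GRID.copy())
    criteria: tuple[GammaCriteria, ...] = DEFAULT_CRITERIA_LEVELS
    low_dose_threshold: float = 10.0
    normalization: str = "local"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    plan: PlanSpec = field(default_factory=PlanSpec)
    truth_rho: float = 7.8
    truth_msf: float = 0.1
    seed: int = 0

    _TOP_KEYS = {
        "kappa", "rho_grid", "msf_grid", "criteria", "low_dose_threshold",
        "normalization", "noise", "plan", "truth_rho", "truth_msf", "seed",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - cls._TOP_KEYS
        if unknown:
            raise ParseError(f"config: unknown key(s) {sorted(unknown)}")
        kw: dict = {}
        for key in ("kappa", "low_dose_threshold", "truth_rho", "truth_msf"):
            if key in data:
                kw[key] = float(data[key])
        if "seed" in data:
            kw["seed"] = int(data["seed"])
        if "normalization" in data:
            kw["normalization"] = str(data["normalization"])
        if "rho_grid" in data:
            kw["rho_grid"] = _grid_from_spec(data["rho_grid"], "rho_grid")
        if "msf_grid" in data:
            kw["msf_grid"] = _grid_from_spec(data["msf_grid"], "msf_grid")
        if "criteria" in data:
            levels = []
            for entry in data["criteria"]:
                dd, dta = float(entry[0]), float(entry[1])
                levels.append(
                    GammaCriteria(
                        dd, dta,
                        low_dose_threshold=float(
                            data.get("low_dose_threshold", 10.0)
                        ),
                        normalization=str(data.get("normalization", "local")),
                    )
                )
            kw["criteria"] = tuple(levels)
        if "noise" in data:
            nd = dict(data["noise"])
            unknown = set(nd) - {"relative_sd", "hardening_coeff", "seed"}
            if unknown:
                raise ParseError(f"config: unknown key(s) {sorted(unknown)} in noise")
            kw["noise"] = NoiseSpec(**nd)
        if "plan" in data:
            pdict = dict(data["plan"])
            valid = {
                "n_fields", "field_size", "diode_spacing", "comp_spacing",
                "calc_spacing", "roughness", "base_thickness", "max_thickness",
            }
            unknown = set(pdict) - valid
            if unknown:
                raise ParseError(f"config: unknown key(s) {sorted(unknown)} in plan")
            kw["plan"] = PlanSpec(**pdict)
        try:
            cfg = cls(**kw)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"config: {exc}") from None
        # re-derive criteria threshold/normalization when only those changed
        if "criteria" not in data and (
            "low_dose_threshold" in data or "normalization" in data
        ):
            cfg.criteria = tuple(
                GammaCriteria(
                    c.dose_diff, c.dta,
                    low_dose_threshold=cfg.low_dose_threshold,
                    normalization=cfg.normalization,
                )
                for c in cfg.criteria
            )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        """JSON-serializable echo of the resolved configuration."""
        return {
            "kappa": self.kappa,
            "rho_grid": [float(v) for v in self.rho_grid],
            "msf_grid": [float(v) for v in self.msf_grid],
            "criteria": [[c.dose_diff, c.dta] for c in self.criteria],
            "low_dose_threshold": self.low_dose_threshold,
            "normalization": self.normalization,
            "noise": {
                "relative_sd": self.noise.relative_sd,
                "hardening_coeff": self.noise.hardening_coeff,
                "seed": self.noise.seed,
            },
            "plan": {
                "n_fields": self.plan.n_fields,
                "field_size": self.plan.field_size,
                "diode_spacing": self.plan.diode_spacing,
                "comp_spacing": self.plan.comp_spacing,
                "calc_spacing": self.plan.calc_spacing,
                "roughness": self.plan.roughness,
                "base_thickness": self.plan.base_thickness,
                "max_thickness": self.plan.max_thickness,
            },
            "truth_rho": self.truth_rho,
            "truth_msf": self.truth_msf,
            "seed": self.seed,
        }
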