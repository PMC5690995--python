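"""Chi-square commissioning of (rho, MSF) against slab-attenuation data.

The commissioning procedure sweeps one parameter at a time on a grid:

1. hold rho fixed and sweep MSF, recording the chi-square of modeled vs
   measured log-attenuation ratios;
2. repeat for every rho on its grid and keep, for each rho, the minimum
   chi-square over MSF ("minimum-of-minima" curve);
3. the argmin of that curve is the commissioned rho for one measurement
   condition (depth, field size); the aggregate rho is the unweighted mean
   of the per-condition optima, and the final MSF is the argmin of one last
   MSF sweep at the aggregate rho over the pooled data.

The objective is chi2 = sum_i (p_i - x_i)^2 / |x_i| over slabs of nonzero
thickness, with x_i the measured and p_i the modeled ln(I/I0).  The
absolute value keeps the objective non-negative for attenuation data,
where the log-ratios are themselves negative.  Zero-thickness (open-field)
records carry the normalization and are excluded from the sum.

An exhaustive simultaneous 2D grid search is provided as a cross-check
mode; the sequential sweep is the primary procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .physics import DEFAULT_KAPPA, BeamModel, SlabSpec, predicted_log_ratios

__all__ = [
    "DEFAULT_RHO_GRID",
    "DEFAULT_MSF_GRID",
    "SlabRecord",
    "SlabMeasurementSet",
    "SweepResult",
    "CommissioningResult",
    "chi2",
    "sweep",
    "min_chi2_curve",
    "aggregate_optimum",
    "commission_slabs",
    "grid_search_2d",
]

#: Default density grid, g/cm^3: brackets plausible brass densities at the
#: resolution used for reporting.
DEFAULT_RHO_GRID = np.round(np.arange(7.0, 9.0 + 1e-9, 0.1), 10)

#: Default modified-scatter-factor grid, 1/cm, with a near-zero point
#: included so the "essentially no scatter" model is on the grid.
DEFAULT_MSF_GRID = np.unique(
    np.concatenate([[0.0001], np.round(np.arange(0.0, 0.5 + 1e-9, 0.05), 10)])
)


@dataclass(frozen=True)
class SlabRecord:
    """One measured slab point: its spec and the measured ln(I/I0)."""

    spec: SlabSpec
    log_ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_ratio):
            raise ValueError("log_ratio must be finite")
        if self.spec.thickness > 0 and self.log_ratio >= 0:
            raise ValueError(
                f"log_ratio must be negative for thickness {self.spec.thickness} cm, "
                f"got {self.log_ratio}"
            )


@dataclass(frozen=True)
class SlabMeasurementSet:
    """Measured log-attenuation ratios indexed by thickness and condition.

    Open-field normalization is implicit: each ``log_ratio`` is already
    ln(I/I0).  Each thickness may appear at most once per (depth,
    field_size) condition.
    """

    records: tuple[SlabRecord, ...]
    provenance: str = ""

    def __init__(self, records: Iterable[SlabRecord], provenance: str = ""):
        records = tuple(records)
        seen = set()
        for r in records:
            key = (r.spec.thickness, r.spec.condition)
            if key in seen:
                raise ValueError(
                    f"duplicate record for thickness {r.spec.thickness} cm under "
                    f"condition (depth, field_size) = {r.spec.condition}"
                )
            seen.add(key)
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.records)

    def conditions(self) -> list[tuple[float, float]]:
        """Sorted unique (depth, field_size) conditions present in the set."""
        return sorted({r.spec.condition for r in self.records})

    def subset(self, condition: tuple[float, float]) -> "SlabMeasurementSet":
        """Records belonging to one (depth, field_size) condition."""
        recs = [r for r in self.records if r.spec.condition == condition]
        return SlabMeasurementSet(recs, provenance=self.provenance)

    def fit_data(self) -> tuple[list[SlabSpec], np.ndarray]:
        """(slabs, measured log-ratios) with zero-thickness rows excluded."""
        recs = [r for r in self.records if r.spec.thickness > 0]
        if not recs:
            raise ValueError("measurement set has no nonzero-thickness records")
        slabs = [r.spec for r in recs]
        x = np.array([r.log_ratio for r in recs], dtype=float)
        return slabs, x


@dataclass(frozen=True)
class SweepResult:
    """A 1D parameter sweep: grid, objective and its minimizer.

    For minimum-of-minima curves (objective = min over the partner
    parameter) ``best_partner`` holds the minimizing partner value at each
    grid point.  Ties in the argmin resolve to the smallest grid value.
    """

    parameter: str
    grid: np.ndarray
    objective: np.ndarray
    argmin_value: float
    argmin_objective: float
    best_partner: np.ndarray | None = None
    condition: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        obj = np.asarray(self.objective, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be a strictly increasing 1D vector")
        if obj.shape != grid.shape:
            raise ValueError("objective must match the grid in length")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "objective", obj)


@dataclass(frozen=True)
class CommissioningResult:
    """Outcome of the full sequential-sweep commissioning.

    ``curves`` maps each (depth, field_size) condition to its
    minimum-of-minima chi-square curve over rho; ``rho_overall`` is the
    unweighted mean of the per-condition optimal rho values,
    ``rho_by_depth`` the same mean within each depth stratum, and
    ``msf_opt`` the argmin of a final MSF sweep at ``rho_overall`` over
    the pooled data.
    """

    curves: dict[tuple[float, float], SweepResult]
    per_condition_rho: dict[tuple[float, float], float]
    rho_by_depth: dict[float, float]
    rho_overall: float
    msf_sweep: SweepResult | None = None
    msf_opt: float | None = None

    def __post_init__(self) -> None:
        optima = list(self.per_condition_rho.values())
        if not (min(optima) - 1e-12 <= self.rho_overall <= max(optima) + 1e-12):
            raise ValueError("aggregate rho must lie within the per-condition optima")


def chi2(predicted, measured) -> float:
    """Goodness-of-fit sum_i (p_i - x_i)^2 / |x_i|.

    Zero iff predicted equals measured elementwise.  Measured entries must
    be nonzero: open-field rows are normalization only and must be removed
    before calling.
    """
    p = np.asarray(predicted, dtype=float)
    x = np.asarray(measured, dtype=float)
    if p.shape != x.shape or p.ndim != 1:
        raise ValueError("predicted and measured must be 1D vectors of equal length")
    if p.size == 0:
        raise ValueError("vectors must be non-empty")
    if np.any(x == 0):
        raise ValueError("measured values must be nonzero (exclude open-field rows)")
    return float(np.sum((p - x) ** 2 / np.abs(x)))


def _argmin_first(grid: np.ndarray, objective: np.ndarray) -> int:
    # np.argmin returns the first minimum; grids are increasing, so the
    # smallest parameter value wins exact ties.
    return int(np.argmin(objective))


def sweep(
    measured: SlabMeasurementSet,
    fixed: tuple[str, float],
    grid: Sequence[float],
    template: BeamModel | None = None,
) -> SweepResult:
    """Sweep one parameter of the model while holding the other fixed.

    ``fixed`` names the held parameter ("rho" or "msf") and its value; the
    grid applies to the other one.  ``template`` supplies kappa (and is
    otherwise overridden).
    """
    name, value = fixed
    if name not in ("rho", "msf"):
        raise ValueError(f"fixed parameter must be 'rho' or 'msf', got {name!r}")
    free = "msf" if name == "rho" else "rho"
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing vector")
    kappa = template.kappa if template is not None else DEFAULT_KAPPA
    slabs, x = measured.fit_data()
    obj = np.empty(grid.size)
    for j, g in enumerate(grid):
        params = {name: value, free: float(g), "kappa": kappa}
        model = BeamModel(**params)
        obj[j] = chi2(predicted_log_ratios(slabs, model), x)
    i = _argmin_first(grid, obj)
    return SweepResult(
        parameter=free,
        grid=grid,
        objective=obj,
        argmin_value=float(grid[i]),
        argmin_objective=float(obj[i]),
    )


def min_chi2_curve(
    measured: SlabMeasurementSet,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    msf_grid: Sequence[float] = DEFAULT_MSF_GRID,
    kappa: float = DEFAULT_KAPPA,
) -> SweepResult:
    """Minimum-of-minima curve: for each rho, the best chi2 over the MSF grid.

    The curve's argmin is the commissioned density for this measurement
    set (typically one depth/field-size condition).
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    msf_grid = np.asarray(msf_grid, dtype=float)
    template = BeamModel(rho=1.0, kappa=kappa)
    obj = np.empty(rho_grid.size)
    best_msf = np.empty(rho_grid.size)
    for i, rho in enumerate(rho_grid):
        s = sweep(measured, ("rho", float(rho)), msf_grid, template)
        obj[i] = s.argmin_objective
        best_msf[i] = s.argmin_value
    i = _argmin_first(rho_grid, obj)
    conds = measured.conditions()
    return SweepResult(
        parameter="rho",
        grid=rho_grid,
        objective=obj,
        argmin_value=float(rho_grid[i]),
        argmin_objective=float(obj[i]),
        best_partner=best_msf,
        condition=conds[0] if len(conds) == 1 else None,
    )


def aggregate_optimum(
    curves: dict[tuple[float, float], SweepResult],
    measured: SlabMeasurementSet | None = None,
    msf_grid: Sequence[float] = DEFAULT_MSF_GRID,
    kappa: float = DEFAULT_KAPPA,
) -> CommissioningResult:
    """Combine per-condition curves into the commissioned (rho, MSF).

    The aggregate density is the unweighted arithmetic mean of the
    per-condition curve argmins, reported overall and per depth stratum.
    If the pooled measurement set is given, the final MSF is the argmin of
    one last sweep at the aggregate rho.
    """
    if not curves:
        raise ValueError("at least one curve is required")
    per_condition = {cond: c.argmin_value for cond, c in curves.items()}
    rho_overall = float(np.mean(list(per_condition.values())))
    depths = sorted({cond[0] for cond in per_condition})
    rho_by_depth = {
        d: float(np.mean([v for (dd, _), v in per_condition.items() if dd == d]))
        for d in depths
    }
    msf_sweep_result = None
    msf_opt = None
    if measured is not None:
        template = BeamModel(rho=1.0, kappa=kappa)
        msf_sweep_result = sweep(measured, ("rho", rho_overall), msf_grid, template)
        msf_opt = msf_sweep_result.argmin_value
    return CommissioningResult(
        curves=dict(curves),
        per_condition_rho=per_condition,
        rho_by_depth=rho_by_depth,
        rho_overall=rho_overall,
        msf_sweep=msf_sweep_result,
        msf_opt=msf_opt,
    )


def commission_slabs(
    measured: SlabMeasurementSet,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    msf_grid: Sequence[float] = DEFAULT_MSF_GRID,
    kappa: float = DEFAULT_KAPPA,
) -> CommissioningResult:
    """Full sequential-sweep workflow over all measurement conditions."""
    curves = {
        cond: min_chi2_curve(measured.subset(cond), rho_grid, msf_grid, kappa)
        for cond in measured.conditions()
    }
    return aggregate_optimum(curves, measured, msf_grid, kappa)


def grid_search_2d(
    measured: SlabMeasurementSet,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    msf_grid: Sequence[float] = DEFAULT_MSF_GRID,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Exhaustive simultaneous (rho, msf) evaluation — cross-check mode.

    Returns the full chi-square surface, shape (len(rho_grid),
    len(msf_grid)), and the (rho, msf) at its minimum (smallest rho, then
    smallest msf, on ties).
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    msf_grid = np.asarray(msf_grid, dtype=float)
    slabs, x = measured.fit_data()
    surface = np.empty((rho_grid.size, msf_grid.size))
    for i, rho in enumerate(rho_grid):
        for j, msf in enumerate(msf_grid):
            model = BeamModel(rho=float(rho), msf=float(msf), kappa=kappa)
            surface[i, j] = chi2(predicted_log_ratios(slabs, model), x)
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    return surface, (float(rho_grid[i]), float(msf_grid[j]))
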