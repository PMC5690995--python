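"""2D gamma-index comparison of measured and calculated dose planes.

The gamma index combines a percent dose difference and a distance to
agreement (DTA) into one number per measured point:

    gamma(r_m) = min over r_c of sqrt( |r_c - r_m|^2 / dta^2
                                       + delta(r_m, r_c)^2 / dose_diff^2 )

where the minimum runs over positions r_c in the calculated plane and
delta is the percent dose difference between the calculated dose at r_c
and the measured dose at r_m.  With *local* normalization delta is taken
relative to the measured dose at r_m; with *global* ("Van Dyk")
normalization, relative to the measured-plane maximum.  A point passes
when gamma <= 1; the failing-point count over a plane (or a set of
fields) is the QA metric minimized during commissioning.

Implementation: the calculated plane is interpolated bilinearly onto a
fine search lattice with step dta/10 per axis; the candidate set for each
measured point is that lattice plus the measured position itself, so two
identical planes always give gamma exactly 0.  The search starts within a
radius of 3*dta and doubles the radius until the minimum found is
*certified* — every candidate outside the radius would incur a distance
penalty alone larger than the current minimum — or until the value is
certified to exceed the reporting cap.  A returned value below the cap is
therefore the exact minimum over the full candidate set; ``cap=None``
disables capping and always returns that exact minimum.

Measured points below ``low_dose_threshold`` percent of the measured
plane's maximum are excluded from evaluation (NaN in the gamma map), the
usual way diodes outside the field are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .physics import BeamModel

__all__ = [
    "DEFAULT_CRITERIA_LEVELS",
    "DosePlane",
    "GammaCriteria",
    "GammaResult",
    "ParameterScan",
    "gamma_index",
    "count_failing",
    "failing_vs_parameter",
    "search_lattice_axis",
]


def _as_pair(value) -> tuple[float, float]:
    if np.ndim(value) == 0:
        return (float(value), float(value))
    y, x = value
    return (float(y), float(x))


@dataclass(frozen=True)
class DosePlane:
    """A regular 2D dose grid with physical geometry.

    ``values[i, j]`` sits at physical position (mm)
    ``(origin[0] + i * spacing[0], origin[1] + j * spacing[1])`` in (y, x)
    order.  ``spacing`` may be a scalar (isotropic) or a (dy, dx) pair.
    Doses are relative or absolute; the gamma computation is ratio-based
    and indifferent to the unit.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("dose values must be finite and non-negative")
        spacing = _as_pair(self.spacing)
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_pair(self.origin))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) axis coordinates in mm."""
        ny, nx = self.values.shape
        y = self.origin[0] + self.spacing[0] * np.arange(ny)
        x = self.origin[1] + self.spacing[1] * np.arange(nx)
        return y, x

    def extent(self) -> tuple[float, float, float, float]:
        """(ymin, ymax, xmin, xmax) of the grid nodes, mm."""
        y, x = self.axis_coords()
        return float(y[0]), float(y[-1]), float(x[0]), float(x[-1])


@dataclass(frozen=True)
class GammaCriteria:
    """Stringency of a gamma comparison.

    ``dose_diff`` in percent, ``dta`` in mm, ``low_dose_threshold`` in
    percent of the measured-plane maximum, ``normalization`` either
    "local" (percent difference relative to the local measured dose) or
    "global" (relative to the measured-plane maximum, the Van Dyk
    convention).
    """

    dose_diff: float
    dta: float
    low_dose_threshold: float = 10.0
    normalization: str = "local"

    def __post_init__(self) -> None:
        if not (self.dose_diff > 0):
            raise ValueError("dose_diff must be positive (percent)")
        if not (self.dta > 0):
            raise ValueError("dta must be positive (mm)")
        if not (0.0 <= self.low_dose_threshold < 100.0):
            raise ValueError("low_dose_threshold must lie in [0, 100) percent")
        if self.normalization not in ("local", "global"):
            raise ValueError("normalization must be 'local' or 'global'")

    @property
    def label(self) -> str:
        return f"{self.dose_diff:g}%/{self.dta:g}mm"


#: The criteria ladder used for commissioning, strict to loose.
DEFAULT_CRITERIA_LEVELS = (
    GammaCriteria(3.0, 3.0),
    GammaCriteria(2.0, 2.0),
    GammaCriteria(1.5, 1.5),
    GammaCriteria(1.0, 1.0),
)


@dataclass(frozen=True)
class GammaResult:
    """Per-point gamma map and pass/fail bookkeeping for one plane pair."""

    gamma_map: np.ndarray  # NaN at excluded (below-threshold) points
    n_evaluated: int
    n_failing: int
    criteria: GammaCriteria

    @property
    def pass_rate(self) -> float:
        """Percent of evaluated points with gamma <= 1."""
        return 100.0 * (1.0 - self.n_failing / self.n_evaluated)


def search_lattice_axis(lo: float, hi: float, step: float) -> np.ndarray:
    """Search positions along one axis: lo, lo+step, ... plus hi itself."""
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    coords = lo + step * np.arange(n)
    if coords[-1] < hi - 1e-9:
        coords = np.append(coords, hi)
    return coords


def gamma_index(
    measured: DosePlane,
    calculated: DosePlane,
    criteria: GammaCriteria,
    *,
    search_step_fraction: float = 0.1,
    search_radius_factor: float = 3.0,
    cap: float | None = 2.0,
) -> GammaResult:
    """Gamma map of a measured plane against a calculated plane.

    Parameters
    ----------
    measured, calculated
        Reference (e.g. diode-array) and evaluated (e.g. planning-system)
        planes; they may have different spacings but must overlap
        spatially.
    criteria
        Dose-difference/DTA stringency, threshold and normalization.
    search_step_fraction
        Search-lattice step as a fraction of the DTA (default dta/10).
    search_radius_factor
        Initial search radius in units of the DTA; the radius doubles
        until the minimum is certified, so this only affects speed.
    cap
        Reporting cap for gamma values (must exceed 1 so failing counts
        are unaffected); ``None`` reports the exact minimum everywhere.
    """
    if cap is not None and cap <= 1.0:
        raise ValueError("cap must exceed 1 (or be None) so failing counts are exact")
    mvals = measured.values
    max_m = float(mvals.max())
    if max_m <= 0:
        raise ValueError("measured plane maximum must be positive")

    my0, my1, mx0, mx1 = measured.extent()
    cy0, cy1, cx0, cx1 = calculated.extent()
    if my1 < cy0 or cy1 < my0 or mx1 < cx0 or cx1 < mx0:
        raise ValueError("measured and calculated planes do not overlap spatially")

    thr = criteria.low_dose_threshold / 100.0 * max_m
    eval_mask = mvals >= thr
    if criteria.normalization == "local":
        # zero measured dose gives no local denominator; only reachable
        # with a zero threshold
        eval_mask &= mvals > 0
    if not eval_mask.any():
        raise ValueError("all measured points fall below the low-dose threshold")

    dta = criteria.dta
    dd = criteria.dose_diff
    step = search_step_fraction * dta

    cy, cx = calculated.axis_coords()
    interp = RegularGridInterpolator(
        (cy, cx), calculated.values, method="linear", bounds_error=False,
        fill_value=np.nan,
    )
    ys = search_lattice_axis(cy0, cy1, step)
    xs = search_lattice_axis(cx0, cx1, step)
    YY, XX = np.meshgrid(ys, xs, indexing="ij")
    lattice_dose = interp(np.column_stack([YY.ravel(), XX.ravel()])).reshape(YY.shape)
    corners = ((cy0, cx0), (cy0, cx1), (cy1, cx0), (cy1, cx1))

    my, mx = measured.axis_coords()
    gamma_map = np.full(mvals.shape, np.nan)
    n_failing = 0
    for i, j in zip(*np.nonzero(eval_mask)):
        ym, xm, dm = float(my[i]), float(mx[j]), float(mvals[i, j])
        denom = dm if criteria.normalization == "local" else max_m
        # direct candidate: calculated dose at the measured position itself
        best2 = np.inf
        if cy0 <= ym <= cy1 and cx0 <= xm <= cx1:
            dc = float(interp([[ym, xm]])[0])
            best2 = ((dc - dm) / denom * 100.0 / dd) ** 2

        # once the radius reaches every plane corner the circle holds the
        # whole candidate set and the minimum is exact by construction
        max_reach = max(math.hypot(ym - py, xm - px) for py, px in corners)
        radius = search_radius_factor * dta
        while True:
            covers_plane = radius >= max_reach
            iy0, iy1 = np.searchsorted(ys, [ym - radius, ym + radius + 1e-12])
            ix0, ix1 = np.searchsorted(xs, [xm - radius, xm + radius + 1e-12])
            dy = ys[iy0:iy1] - ym
            dx = xs[ix0:ix1] - xm
            r2 = dy[:, None] ** 2 + dx[None, :] ** 2
            within = r2 <= radius * radius
            if within.any():
                dsub = lattice_dose[iy0:iy1, ix0:ix1][within]
                g2 = r2[within] / dta**2 + ((dsub - dm) / denom * 100.0 / dd) ** 2
                g2min = min(best2, float(g2.min()))
            else:
                g2min = best2
            g = math.sqrt(g2min)
            if g <= radius / dta + 1e-12 or covers_plane:
                gamma = g  # certified exact over the full candidate set
                break
            if cap is not None and radius / dta >= cap:
                gamma = cap  # certified: true gamma exceeds the cap
                break
            radius = min(2.0 * radius, max_reach)
        if cap is not None:
            gamma = min(gamma, cap)
        gamma_map[i, j] = gamma
        if gamma > 1.0:
            n_failing += 1

    return GammaResult(
        gamma_map=gamma_map,
        n_evaluated=int(eval_mask.sum()),
        n_failing=n_failing,
        criteria=criteria,
    )


def count_failing(results: Iterable[GammaResult]) -> int:
    """Total failing points over a set of fields (e.g. a seven-field plan)."""
    results = list(results)
    if not results:
        raise ValueError("at least one GammaResult is required")
    return int(sum(r.n_failing for r in results))


@dataclass(frozen=True)
class ParameterScan:
    """Failing-point counts over a parameter grid at several criteria levels.

    ``counts[k, j]`` is the total failing-point count (summed over fields)
    at criteria level k and parameter grid value j.  ``argmin`` maps each
    criteria label to the grid value minimizing its count (smallest value
    on ties).
    """

    parameter: str
    grid: np.ndarray
    criteria_levels: tuple[GammaCriteria, ...]
    counts: np.ndarray
    argmin: dict[str, float]


def failing_vs_parameter(
    fields: Sequence[tuple[object, DosePlane]],
    calculate: Callable[[object, BeamModel], DosePlane],
    parameter: tuple[str, Sequence[float]],
    fixed: tuple[str, float],
    criteria_levels: Sequence[GammaCriteria] = DEFAULT_CRITERIA_LEVELS,
    *,
    kappa: float | None = None,
    gamma_kwargs: dict | None = None,
) -> ParameterScan:
    """Failing-point count vs one beam-model parameter, per criteria level.

    For each grid value the calculated plane of every field is recomputed
    with the surrogate (via ``calculate(field_object, model)``) and
    compared against that field's measured plane; failing points are
    summed over fields.  ``parameter`` is ("rho" | "msf", grid); ``fixed``
    holds the other parameter constant.
    """
    name, grid = parameter
    fixed_name, fixed_value = fixed
    if {name, fixed_name} != {"rho", "msf"}:
        raise ValueError("parameter and fixed must name 'rho' and 'msf'")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing vector")
    if not fields:
        raise ValueError("at least one field is required")
    criteria_levels = tuple(criteria_levels)
    gamma_kwargs = gamma_kwargs or {}

    counts = np.zeros((len(criteria_levels), grid.size), dtype=int)
    for j, value in enumerate(grid):
        params = {name: float(value), fixed_name: float(fixed_value)}
        if kappa is not None:
            params["kappa"] = kappa
        model = BeamModel(**params)
        calc_planes = [calculate(comp, model) for comp, _ in fields]
        for k, crit in enumerate(criteria_levels):
            results = [
                gamma_index(meas, calc, crit, **gamma_kwargs)
                for (_, meas), calc in zip(fields, calc_planes)
            ]
            counts[k, j] = count_failing(results)

    argmin = {
        crit.label: float(grid[int(np.argmin(counts[k]))])
        for k, crit in enumerate(criteria_levels)
    }
    return ParameterScan(
        parameter=name,
        grid=grid,
        criteria_levels=criteria_levels,
        counts=counts,
        argmin=argmin,
    )
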