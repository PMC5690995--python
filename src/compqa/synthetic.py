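"""Synthetic study generator: slab readings and compensator dose planes.

Emulates the two measurement campaigns a compensator commissioning needs,
from a known ground-truth beam model, so every downstream stage can be
exercised and validated without access to a linac:

* ion-chamber transmission readings through brass slabs (1/3/5 cm by
  default) at several depths in water (2.5/10/20 cm) and square field
  sizes (5/10/20 cm), with multiplicative Gaussian reading noise and an
  optional quadratic-in-thickness beam-hardening term on the
  log-attenuation;
* a multi-field IMRT study: randomly modulated compensator thickness
  maps ("hills and valleys" over a minimum base thickness), the dose
  plane each produces under the transmission surrogate, and a noisy
  diode-array sampling of that plane.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .commissioning import SlabMeasurementSet, SlabRecord
from .gamma import DosePlane
from .physics import BeamModel, SlabSpec, transmission

__all__ = [
    "DEFAULT_THICKNESSES",
    "DEFAULT_DEPTHS",
    "DEFAULT_FIELD_SIZES",
    "NoiseSpec",
    "PlanSpec",
    "CompensatorMap",
    "generate_slab_measurements",
    "generate_compensator_map",
    "simulate_dose_plane",
    "sample_diode_array",
    "generate_study",
]

#: Slab thicknesses, cm (0 is the open-field normalization reading).
DEFAULT_THICKNESSES = (0.0, 1.0, 3.0, 5.0)
#: Measurement depths in water, cm (dmax, 10, 20 for a 10 MV beam).
DEFAULT_DEPTHS = (2.5, 10.0, 20.0)
#: Square field sizes, cm.
DEFAULT_FIELD_SIZES = (5.0, 10.0, 20.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model.

    ``relative_sd`` is the standard deviation of multiplicative Gaussian
    noise on readings (ion-chamber and diode repeatability scales with
    signal).  ``hardening_coeff`` adds a quadratic-in-thickness
    perturbation ``-c * t^2`` to the log-attenuation, a stand-in for
    beam-hardening/scatter departures from pure exponential behavior.
    """

    relative_sd: float = 0.0
    hardening_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")


@dataclass(frozen=True)
class PlanSpec:
    """Geometry and modulation of a synthetic compensator IMRT study."""

    n_fields: int = 7
    field_size: float = 25.0        # cm, side of the square plane
    diode_spacing: float = 7.0      # mm, detector pitch
    comp_spacing: float = 5.0       # mm, compensator thickness-map grid
    calc_spacing: float = 2.0       # mm, calculated dose grid
    roughness: float = 0.5          # 0 = flat compensator, 1 = full range
    base_thickness: float = 0.6     # cm, minimum milled thickness
    max_thickness: float = 5.0      # cm

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        for name in ("field_size", "diode_spacing", "comp_spacing", "calc_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.roughness <= 1.0):
            raise ValueError("roughness must lie in [0, 1]")
        if self.base_thickness < 0 or self.max_thickness < self.base_thickness:
            raise ValueError("need 0 <= base_thickness <= max_thickness")


@dataclass(frozen=True)
class CompensatorMap:
    """A milled brass thickness map t(x, y) on a regular grid.

    ``thickness`` in cm, ``spacing`` in mm; the map never goes below
    ``base_thickness`` (fabrication keeps a minimum base, 0.6 cm by
    default).
    """

    thickness: np.ndarray
    spacing: float
    base_thickness: float = 0.6

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness, dtype=float)
        if t.ndim != 2:
            raise ValueError("thickness must be a 2D array")
        if not np.all(np.isfinite(t)):
            raise ValueError("thickness must be finite")
        if self.base_thickness < 0:
            raise ValueError("base_thickness must be >= 0")
        if np.any(t < self.base_thickness - 1e-12):
            raise ValueError("thickness must be >= base_thickness everywhere")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "thickness", t)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.thickness.shape
        return self.spacing * np.arange(ny), self.spacing * np.arange(nx)


def generate_slab_measurements(
    truth: BeamModel,
    thicknesses=DEFAULT_THICKNESSES,
    depths=DEFAULT_DEPTHS,
    field_sizes=DEFAULT_FIELD_SIZES,
    noise: NoiseSpec = NoiseSpec(),
    condition_kappa_jitter: float = 0.0,
) -> SlabMeasurementSet:
    """Noisy slab transmission readings from a ground-truth model.

    Each record's log-ratio is ``ln[T(t) * (1 + eps)] - c * t^2`` with
    ``eps ~ N(0, relative_sd^2)`` drawn per reading and ``c`` the
    hardening coefficient.  ``condition_kappa_jitter`` optionally perturbs
    the effective kappa per (depth, field size) condition by a uniform
    factor in ±jitter, emulating the small spread of per-condition optima
    a real beam shows across depths and field sizes.
    """
    thicknesses = np.asarray(thicknesses, dtype=float)
    if not np.any(thicknesses > 0):
        raise ValueError("need at least one nonzero thickness")
    rng = np.random.default_rng(noise.seed)
    records = []
    for depth in depths:
        for fs in field_sizes:
            kappa_c = truth.kappa
            if condition_kappa_jitter > 0:
                kappa_c *= 1.0 + condition_kappa_jitter * rng.uniform(-1.0, 1.0)
            model_c = truth.replace(kappa=kappa_c)
            for t in thicknesses:
                ratio = transmission(float(t), model_c)
                if noise.relative_sd > 0:
                    ratio *= 1.0 + rng.normal(0.0, noise.relative_sd)
                if ratio <= 0:
                    raise RuntimeError("noise drove a reading non-positive")
                x = np.log(ratio) - noise.hardening_coeff * t**2
                records.append(
                    SlabRecord(SlabSpec(float(t), float(depth), float(fs)), float(x))
                )
    return SlabMeasurementSet(records, provenance=f"synthetic(seed={noise.seed})")


def generate_compensator_map(spec: PlanSpec, seed: int) -> CompensatorMap:
    """A random smooth compensator: low-frequency waves plus local bumps.

    The modulation is normalized to [0, 1] and scaled by ``roughness``
    over the available thickness range, so the spatial gradients grow
    proportionally with roughness and the map stays within
    [base_thickness, max_thickness] by construction (and is clipped below
    at the base as a safeguard).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.field_size * 10.0 / spec.comp_spacing)) + 1
    u = np.linspace(0.0, 1.0, n)
    U, V = np.meshgrid(u, u, indexing="ij")

    m = np.zeros((n, n))
    for _ in range(4):  # low-frequency cosine components
        p, q = rng.integers(1, 4, size=2)
        amp = rng.uniform(0.3, 1.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        m += amp * np.cos(2.0 * np.pi * (p * U + q * V) + phase)
    for _ in range(3):  # localized hills
        cy, cx = rng.uniform(0.15, 0.85, size=2)
        width = rng.uniform(0.08, 0.2)
        amp = rng.uniform(0.5, 1.5)
        m += amp * np.exp(-(((U - cy) ** 2 + (V - cx) ** 2) / (2.0 * width**2)))

    if spec.roughness > 0:
        span = m.max() - m.min()
        m_norm = (m - m.min()) / span if span > 0 else np.zeros_like(m)
        extra = spec.roughness * (spec.max_thickness - spec.base_thickness) * m_norm
    else:
        extra = np.zeros_like(m)
    thickness = np.maximum(spec.base_thickness + extra, spec.base_thickness)
    return CompensatorMap(thickness, spec.comp_spacing, spec.base_thickness)


def simulate_dose_plane(
    comp: CompensatorMap,
    model: BeamModel,
    grid_spacing: float,
    open_field=None,
) -> DosePlane:
    """Dose plane under the transmission surrogate: open field x T(t(x, y)).

    The thickness map is interpolated bilinearly onto the requested dose
    grid (same physical extent, origin at the map corner).  ``open_field``
    is the unmodulated plane: a scalar, a 2D callable of (y, x) in mm, or
    None for a flat unit plane.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    cy, cx = comp.axis_coords()
    interp = RegularGridInterpolator((cy, cx), comp.thickness, method="linear")
    ny = int(np.floor(cy[-1] / grid_spacing + 1e-9)) + 1
    nx = int(np.floor(cx[-1] / grid_spacing + 1e-9)) + 1
    gy = grid_spacing * np.arange(ny)
    gx = grid_spacing * np.arange(nx)
    YY, XX = np.meshgrid(gy, gx, indexing="ij")
    t = interp(np.column_stack([YY.ravel(), XX.ravel()])).reshape(YY.shape)

    if open_field is None:
        of = 1.0
    elif callable(open_field):
        of = np.asarray(open_field(YY, XX), dtype=float)
    else:
        of = float(open_field)
    dose = of * transmission(t, model)
    return DosePlane(dose, spacing=grid_spacing, origin=(0.0, 0.0))


def sample_diode_array(
    plane: DosePlane,
    diode_spacing: float,
    noise: NoiseSpec = NoiseSpec(),
    n_diodes: tuple[int, int] | None = None,
) -> DosePlane:
    """Sample a dose plane on a coarser diode grid with reading noise.

    Diodes sit on a regular grid starting at the plane origin with the
    given pitch (mm); by default as many diodes as fit within the plane.
    Passing ``n_diodes`` explicitly raises if the requested grid extends
    beyond the plane.
    """
    if diode_spacing < min(plane.spacing):
        raise ValueError("diode spacing must be >= the plane grid spacing")
    py, px = plane.axis_coords()
    if n_diodes is None:
        nd_y = int(np.floor((py[-1] - py[0]) / diode_spacing + 1e-9)) + 1
        nd_x = int(np.floor((px[-1] - px[0]) / diode_spacing + 1e-9)) + 1
    else:
        nd_y, nd_x = n_diodes
        if (
            py[0] + (nd_y - 1) * diode_spacing > py[-1] + 1e-9
            or px[0] + (nd_x - 1) * diode_spacing > px[-1] + 1e-9
        ):
            raise ValueError("diode grid extends beyond the dose plane")
    dy = py[0] + diode_spacing * np.arange(nd_y)
    dx = px[0] + diode_spacing * np.arange(nd_x)
    interp = RegularGridInterpolator((py, px), plane.values, method="linear")
    YY, XX = np.meshgrid(dy, dx, indexing="ij")
    vals = interp(np.column_stack([YY.ravel(), XX.ravel()])).reshape(YY.shape)
    if noise.relative_sd > 0:
        rng = np.random.default_rng(noise.seed)
        vals = vals * (1.0 + rng.normal(0.0, noise.relative_sd, size=vals.shape))
    vals = np.clip(vals, 0.0, None)
    return DosePlane(vals, spacing=diode_spacing, origin=(py[0], px[0]))


def generate_study(
    spec: PlanSpec,
    truth: BeamModel,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> list[tuple[CompensatorMap, DosePlane]]:
    """A complete multi-field study: (compensator, measured diode plane) pairs.

    Each field gets its own compensator and an independently seeded diode
    measurement of the dose plane the ground-truth model produces.
    """
    ss = np.random.SeedSequence(seed)
    field_seeds = ss.spawn(spec.n_fields)
    out = []
    for fs in field_seeds:
        comp_seed, meas_seed = (int(s) & 0x7FFFFFFF for s in fs.generate_state(2))
        comp = generate_compensator_map(spec, int(comp_seed))
        truth_plane = simulate_dose_plane(comp, truth, spec.calc_spacing)
        field_noise = NoiseSpec(
            relative_sd=noise.relative_sd,
            hardening_coeff=noise.hardening_coeff,
            seed=int(meas_seed),
        )
        measured = sample_diode_array(truth_plane, spec.diode_spacing, field_noise)
        out.append((comp, measured))
    return out
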