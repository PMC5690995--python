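"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from compqa import (
    BeamModel,
    DosePlane,
    NoiseSpec,
    PlanSpec,
    generate_slab_measurements,
    generate_study,
)
from compqa.gamma import search_lattice_axis

TRUTH_RHO = 7.8
TRUTH_MSF = 0.1


@pytest.fixture(scope="session")
def truth_model() -> BeamModel:
    """The ground-truth beam model used across recovery tests."""
    return BeamModel(rho=TRUTH_RHO, msf=TRUTH_MSF)


@pytest.fixture(scope="session")
def noise_free_slabs(truth_model):
    """Noise-free slab readings: 4 thicknesses x 3 depths x 3 field sizes."""
    return generate_slab_measurements(truth_model, noise=NoiseSpec())


@pytest.fixture(scope="session")
def small_plan_spec() -> PlanSpec:
    """A desk-scale study geometry: 10x10 cm fields on a 7 mm diode pitch."""
    return PlanSpec(n_fields=2, field_size=10.0)


@pytest.fixture(scope="session")
def small_study(truth_model, small_plan_spec):
    """Two noise-free fields measured at the ground truth."""
    return generate_study(small_plan_spec, truth_model, NoiseSpec(), seed=11)


# ---------------------------------------------------------------------------
# independent oracles

def bilinear(values: np.ndarray, ys: np.ndarray, xs: np.ndarray,
             y: float, x: float) -> float:
    """Hand-rolled bilinear interpolation on a regular grid."""
    i = int(np.clip(np.searchsorted(ys, y, side="right") - 1, 0, ys.size - 2))
    j = int(np.clip(np.searchsorted(xs, x, side="right") - 1, 0, xs.size - 2))
    ty = (y - ys[i]) / (ys[i + 1] - ys[i])
    tx = (x - xs[j]) / (xs[j + 1] - xs[j])
    return float(
        values[i, j] * (1 - ty) * (1 - tx)
        + values[i + 1, j] * ty * (1 - tx)
        + values[i, j + 1] * (1 - ty) * tx
        + values[i + 1, j + 1] * ty * tx
    )


def brute_force_gamma(measured: DosePlane, calculated: DosePlane, criteria,
                      step_fraction: float = 0.1) -> np.ndarray:
    """Exhaustive gamma over the full fine search lattice, no truncation.

    Loops measured points one at a time and scans every lattice position
    (plus the measured position itself), using its own bilinear
    interpolation.  Deliberately simple; the reference the fast
    implementation is checked against.
    """
    mvals = measured.values
    max_m = mvals.max()
    thr = criteria.low_dose_threshold / 100.0 * max_m
    cy, cx = calculated.axis_coords()
    step = step_fraction * criteria.dta
    ys = search_lattice_axis(cy[0], cy[-1], step)
    xs = search_lattice_axis(cx[0], cx[-1], step)
    # evaluate every lattice dose once (vectorized for tolerable runtime,
    # still exhaustive: every candidate is visited)
    lat_dose = np.array(
        [[bilinear(calculated.values, cy, cx, y, x) for x in xs] for y in ys]
    )
    YY, XX = np.meshgrid(ys, xs, indexing="ij")

    my, mx = measured.axis_coords()
    out = np.full(mvals.shape, np.nan)
    for i in range(mvals.shape[0]):
        for j in range(mvals.shape[1]):
            dm = mvals[i, j]
            if dm < thr or (criteria.normalization == "local" and dm == 0):
                continue
            ym, xm = my[i], mx[j]
            denom = dm if criteria.normalization == "local" else max_m
            dist2 = ((YY - ym) ** 2 + (XX - xm) ** 2) / criteria.dta**2
            dd2 = ((lat_dose - dm) / denom * 100.0 / criteria.dose_diff) ** 2
            best = float(np.min(dist2 + dd2))
            if cy[0] <= ym <= cy[-1] and cx[0] <= xm <= cx[-1]:
                dc = bilinear(calculated.values, cy, cx, ym, xm)
                best = min(best, ((dc - dm) / denom * 100.0 / criteria.dose_diff) ** 2)
            out[i, j] = math.sqrt(best)
    return out


def smooth_random_plane(rng: np.random.Generator, n: int = 15,
                        spacing: float = 3.0) -> DosePlane:
    """A smooth random dose-like plane: cosine modulation around unity."""
    u = np.linspace(0.0, 1.0, n)
    U, V = np.meshgrid(u, u, indexing="ij")
    vals = np.ones((n, n))
    for _ in range(3):
        p, q = rng.integers(1, 4, size=2)
        vals += rng.uniform(0.05, 0.25) * np.cos(
            2 * np.pi * (p * U + q * V) + rng.uniform(0, 2 * np.pi)
        )
    return DosePlane(np.clip(vals, 0.3, None), spacing=spacing)
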