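"""Compensator transmission model.

A brass compensator placed in a megavoltage photon beam attenuates the
primary fluence exponentially with path length and adds forward scatter
roughly proportional to that path length.  Model-based planning systems
expose this as two commissionable parameters: the material density ``rho``
(g/cm^3) entering the exponential through a fixed mass-attenuation
coefficient ``kappa`` (cm^2/g), and a *modified scatter factor* ``MSF``
(1/cm) that multiplies the fluence by ``1 + MSF * t`` for a primary-ray
path length ``t`` through the modifier.  The central-axis transmission
surrogate used throughout this package is therefore

    T(t) = (1 + MSF * t) * exp(-kappa * rho * t)

With MSF ~ 0 the log-transmission ln T is exactly linear in thickness;
a large MSF bends it visibly.  Depth in water and field size do not enter
the formula; they are carried as measurement-condition labels so the
commissioning stage can stratify by them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEFAULT_KAPPA",
    "BeamModel",
    "SlabSpec",
    "transmission",
    "log_attenuation",
    "predicted_log_ratios",
]

#: Default mass attenuation coefficient of brass at ~10 MV effective energy,
#: cm^2/g.  Configurable; the effective linear attenuation coefficient of the
#: exponential term is kappa * rho.
DEFAULT_KAPPA = 0.037


@dataclass(frozen=True)
class BeamModel:
    """The two commissionable compensator parameters plus the fixed constant.

    Parameters
    ----------
    rho
        Brass density, g/cm^3.  Must be positive.
    msf
        Modified scatter factor, 1/cm, in [0, 1].
    kappa
        Mass attenuation coefficient, cm^2/g.  A fixed physics constant of
        the surrogate, not swept during commissioning.
    """

    rho: float
    msf: float = 0.0
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if not (self.rho > 0):
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not (0.0 <= self.msf <= 1.0):
            raise ValueError(f"msf must lie in [0, 1] 1/cm, got {self.msf}")
        if not (self.kappa > 0):
            raise ValueError(f"kappa must be positive, got {self.kappa}")

    def replace(self, **changes) -> "BeamModel":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)


@dataclass(frozen=True, order=True)
class SlabSpec:
    """A slab-attenuation measurement point: thickness and its conditions.

    ``thickness`` is the brass slab thickness in cm (0 denotes the open
    field / normalization reading); ``depth`` is the measurement depth in
    water in cm; ``field_size`` the side of the square field in cm.
    """

    thickness: float
    depth: float
    field_size: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"thickness must be >= 0 cm, got {self.thickness}")
        if not (self.depth > 0):
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not (self.field_size > 0):
            raise ValueError(f"field_size must be positive, got {self.field_size}")

    @property
    def condition(self) -> tuple[float, float]:
        """The (depth, field_size) measurement condition label."""
        return (self.depth, self.field_size)


def transmission(thickness, model: BeamModel):
    """Central-axis transmission I/I0 through ``thickness`` cm of brass.

    Accepts a scalar or ndarray thickness; returns the same shape.
    Raises ``ValueError`` for any negative thickness.
    """
    t = np.asarray(thickness, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    out = (1.0 + model.msf * t) * np.exp(-model.kappa * model.rho * t)
    if np.isscalar(thickness) or np.ndim(thickness) == 0:
        return float(out)
    return out


def log_attenuation(transmission):
    """Natural log of a transmission ratio; negative for attenuation < 1."""
    tr = np.asarray(transmission, dtype=float)
    if np.any(tr <= 0):
        raise ValueError("transmission must be positive")
    out = np.log(tr)
    if np.ndim(transmission) == 0:
        return float(out)
    return out


def predicted_log_ratios(slabs, model: BeamModel) -> np.ndarray:
    """Modeled ln(I/I0) for each slab, order preserving.

    Vectorizes the transmission model over a slab set to produce the
    predicted values entering the chi-square objective.
    """
    slabs = list(slabs)
    if not slabs:
        raise ValueError("slab list must be non-empty")
    t = np.array([s.thickness for s in slabs], dtype=float)
    return log_attenuation(transmission(t, model))
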