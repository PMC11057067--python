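"""Geometry and energetics of a single thin-walled spherical lung unit.

The alveolar unit is idealised as a hollow, thin-walled sphere held open by a
static distending pressure ``P`` (cmH2O).  For a sphere of radius ``R`` (cm),

* volume  ``V = 4/3 * pi * R**3``  (mL, since 1 cm^3 == 1 mL),
* area    ``A = 4 * pi * R**2``    (cm^2),
* wall tension by the Laplace relation ``T = P*R/2`` (cmH2O*cm).

Two tension conventions are exposed.  ``laplace_half`` is the classical
thin-sphere Laplace tension ``T = PR/2``; with it the shell identity is
``T*A = (3/2) * P*V``.  ``energy_third`` uses ``T = PR/3``, the unique
convention under which the stored elastic energy bookkeeping ``T*A = P*V``
holds exactly.  Both appear in the clinical literature on alveolar
mechanics and they differ by a constant factor 3/2; callers pick one
explicitly and the package never mixes them silently.

Tidal inflation is modelled with a linear pressure-volume relationship
(constant compliance ``C = dV/dP``), static conditions only: no flow
resistance, no hysteresis, no tidal opening/closure.
"""

from __future__ import annotations

import enum
import math
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .exceptions import DomainError

__all__ = [
    "TensionConvention",
    "SphereState",
    "VentilationCycle",
    "CMH2O_L_TO_J",
    "radius_from_volume",
    "volume_from_radius",
    "area_from_radius",
    "sphere_state",
    "tidal_volume_linear",
    "EnergyPerCycle",
    "elastic_energy_per_cycle",
]

#: Energy conversion: 1 cmH2O * 1 L = 0.0980665 J (exact, from g = 9.80665 m/s^2).
CMH2O_L_TO_J = 0.0980665

_REL_TOL = 1e-9


class TensionConvention(str, enum.Enum):
    """How wall tension is derived from pressure and radius."""

    #: Laplace law for a thin-walled sphere, T = P*R/2.
    LAPLACE_HALF = "laplace_half"
    #: Energy-consistent convention, T = P*R/3, for which T*A == P*V exactly.
    ENERGY_THIRD = "energy_third"


def radius_from_volume(volume: float) -> float:
    """Radius (cm) of a sphere of the given volume (mL): ``(3V / 4pi)**(1/3)``."""
    if volume < 0:
        raise DomainError(f"sphere volume must be non-negative, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_from_radius(radius: float) -> float:
    """Volume (mL) of a sphere of the given radius (cm): ``4/3 pi R^3``."""
    if radius < 0:
        raise DomainError(f"sphere radius must be non-negative, got {radius}")
    return 4.0 / 3.0 * math.pi * radius**3


def area_from_radius(radius: float) -> float:
    """Surface area (cm^2) of a sphere of the given radius (cm): ``4 pi R^2``."""
    if radius < 0:
        raise DomainError(f"sphere radius must be non-negative, got {radius}")
    return 4.0 * math.pi * radius**2


class SphereState(BaseModel):
    """Static state of one thin-walled spherical unit.

    Fields are mutually redundant by construction (volume, area and tension
    all follow from pressure and radius); the model validates the geometric
    identities at 1e-9 relative tolerance so a hand-built inconsistent state
    is rejected.

    Units: pressure cmH2O, radius cm, volume mL, area cm^2,
    tension cmH2O*cm.
    """

    model_config = ConfigDict(frozen=True)

    pressure: float
    radius: float
    volume: float
    area: float
    tension: float
    tension_convention: TensionConvention = TensionConvention.LAPLACE_HALF

    @model_validator(mode="after")
    def _check_invariants(self) -> "SphereState":
        if self.pressure < 0:
            raise DomainError(f"pressure must be non-negative, got {self.pressure}")
        if self.radius < 0:
            raise DomainError(f"radius must be non-negative, got {self.radius}")
        for name, got, want in (
            ("volume", self.volume, volume_from_radius(self.radius)),
            ("area", self.area, area_from_radius(self.radius)),
            ("tension", self.tension, _tension(self.pressure, self.radius, self.tension_convention)),
        ):
            if not math.isclose(got, want, rel_tol=_REL_TOL, abs_tol=1e-12):
                raise DomainError(
                    f"inconsistent SphereState: {name}={got} but radius/pressure imply {want}"
                )
        return self


def _tension(pressure: float, radius: float, convention: TensionConvention) -> float:
    divisor = 2.0 if convention is TensionConvention.LAPLACE_HALF else 3.0
    return pressure * radius / divisor


def sphere_state(
    pressure: float,
    volume: float,
    convention: TensionConvention = TensionConvention.LAPLACE_HALF,
) -> SphereState:
    """Build a consistent :class:`SphereState` from pressure (cmH2O) and volume (mL).

    Under ``energy_third`` the returned state satisfies ``tension * area ==
    pressure * volume`` exactly (to 1e-9); under the default ``laplace_half``
    the same product is ``(3/2) * pressure * volume``.
    """
    if pressure < 0:
        raise DomainError(f"pressure must be non-negative, got {pressure}")
    radius = radius_from_volume(volume)  # raises on negative volume
    return SphereState(
        pressure=pressure,
        radius=radius,
        volume=volume,
        area=area_from_radius(radius),
        tension=_tension(pressure, radius, convention),
        tension_convention=convention,
    )


class VentilationCycle(BaseModel):
    """One tidal cycle of positive-pressure ventilation.

    peep and driving_pressure in cmH2O, tidal_volume in litres, frequency in
    breaths/min.  ``frequency`` may be omitted when only per-cycle energy is
    needed; power computations require it to be positive.
    """

    model_config = ConfigDict(frozen=True)

    peep: float
    driving_pressure: float
    tidal_volume: float
    frequency: Optional[float] = None

    @model_validator(mode="after")
    def _check_nonnegative(self) -> "VentilationCycle":
        for name in ("peep", "driving_pressure", "tidal_volume"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.frequency is not None and self.frequency < 0:
            raise DomainError(f"frequency must be non-negative, got {self.frequency}")
        return self


def tidal_volume_linear(compliance: float, delta_p: float) -> float:
    """Tidal volume increment (mL) on a linear PV curve: ``C * dP``.

    compliance in mL/cmH2O (must be positive), delta_p in cmH2O.
    """
    if compliance <= 0:
        raise DomainError(f"compliance must be positive, got {compliance}")
    if delta_p < 0:
        raise DomainError(f"delta_p must be non-negative, got {delta_p}")
    return compliance * delta_p


class EnergyPerCycle(NamedTuple):
    """Inflation energy of one cycle, in both unit systems."""

    cmh2o_l: float
    joules: float


def elastic_energy_per_cycle(cycle: VentilationCycle) -> EnergyPerCycle:
    """Elastic inflation energy per breath.

    On a linear PV curve the inflation from PEEP to PEEP + dP stores

        ``E = dV * (PEEP + dP/2)``   [cmH2O*L]

    — the trapezoid under V(P) between the two pressures, i.e. the triangular
    tidal elastic energy ``dP*dV/2`` plus the PEEP-related rectangle
    ``PEEP*dV``.  Only static elastic energy is counted; resistive (flow)
    energy is excluded by the static model.  Returns the energy in cmH2O*L
    and in joules (1 cmH2O*L = 0.0980665 J).
    """
    e_cmh2o_l = cycle.tidal_volume * (cycle.peep + cycle.driving_pressure / 2.0)
    return EnergyPerCycle(cmh2o_l=e_cmh2o_l, joules=e_cmh2o_l * CMH2O_L_TO_J)
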