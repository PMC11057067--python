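"""Stress, strain and energy amplification at a compliance interface.

Where a flexible surface element (compliance ``C1``, mL/cmH2O) abuts a
stiffer one (``C2``) on the shell of a lung unit, the same applied pressure
increment inflates the two elements unequally.  Treating each element as
part of a hypothetical independent sphere inflated by the same pressure,
``dV1/dV2 = C1/C2``, and the sphere geometry gives

* tension (stress) multiplier   ``(C1/C2)**(1/3)``  (= R1/R2),
* area (strain) multiplier      ``(C1/C2)**(2/3)``  (= A1/A2),
* stored elastic-energy ratio   ``C1/C2``           (their product).

These are the risk amplifiers acting at "stress riser" interfaces in a
mechanically heterogeneous (e.g. ARDS) lung.  The classical histology-based
estimate for the fully-distended : collapsed configuration is a 10:1 volume
ratio, whose boundary *pressure* amplification scales as the 2/3 power of
the volume ratio (:func:`mead_pressure_amplifier`); that convention shares
an exponent with the strain multiplier here, and both are exposed without
being harmonised.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator

from .core_mechanics import (
    SphereState,
    TensionConvention,
    radius_from_volume,
    sphere_state,
    tidal_volume_linear,
)
from .exceptions import DomainError, PlausibilityWarning, UsageError

__all__ = [
    "InterfacePair",
    "AmplifierSet",
    "InterfaceState",
    "amplifiers",
    "interface_state",
    "mead_pressure_amplifier",
    "DEFAULT_PLAUSIBILITY_BAND",
]

#: Compliance-ratio band considered clinically plausible, from the 10:1
#: histological volume range between a fully distended and a collapsed unit.
DEFAULT_PLAUSIBILITY_BAND: Tuple[float, float] = (1.0, 10.0)


class InterfacePair(BaseModel):
    """Two adjoining surface elements of differing compliance.

    ``c1`` is conventionally the more flexible element and ``c2`` the less
    flexible one, but any positive pair is accepted; multipliers are then
    reported for the pair as given (see :func:`amplifiers` ``orient``).
    ``delta_p`` (cmH2O) is only required for absolute tensions/areas via
    :func:`interface_state`.
    """

    model_config = ConfigDict(frozen=True)

    c1: float
    c2: float
    delta_p: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "InterfacePair":
        if self.c1 <= 0 or self.c2 <= 0:
            raise DomainError(
                f"compliances must be positive, got c1={self.c1}, c2={self.c2}"
            )
        if self.delta_p is not None and self.delta_p < 0:
            raise DomainError(f"delta_p must be non-negative, got {self.delta_p}")
        return self

    @property
    def ratio(self) -> float:
        """Compliance ratio C1/C2."""
        return self.c1 / self.c2


class AmplifierSet(BaseModel):
    """The three interface risk multipliers for one compliance pair.

    Invariant: ``stress_multiplier * strain_multiplier == energy_ratio``
    (checked at 1e-12 relative), and all three equal 1 iff C1 == C2.
    """

    model_config = ConfigDict(frozen=True)

    stress_multiplier: float
    strain_multiplier: float
    energy_ratio: float

    @model_validator(mode="after")
    def _check_product(self) -> "AmplifierSet":
        prod = self.stress_multiplier * self.strain_multiplier
        if not math.isclose(prod, self.energy_ratio, rel_tol=1e-12):
            raise DomainError(
                f"stress*strain = {prod} does not equal energy_ratio = {self.energy_ratio}"
            )
        return self

    @classmethod
    def from_ratio(cls, ratio: float) -> "AmplifierSet":
        if ratio <= 0:
            raise DomainError(f"compliance ratio must be positive, got {ratio}")
        stress = ratio ** (1.0 / 3.0)
        strain = ratio ** (2.0 / 3.0)
        return cls(
            stress_multiplier=stress,
            strain_multiplier=strain,
            energy_ratio=stress * strain,
        )


def amplifiers(
    pair: InterfacePair,
    orient: str = "as_given",
    plausibility_band: Tuple[float, float] = DEFAULT_PLAUSIBILITY_BAND,
) -> AmplifierSet:
    """Interface multipliers for a compliance pair.

    Parameters
    ----------
    pair
        The two compliances; only their ratio matters (scale invariant).
    orient
        ``"as_given"`` reports multipliers for C1/C2 exactly as supplied
        (reciprocal pairs give reciprocal multipliers); ``"flexible_first"``
        swaps the pair if needed so all multipliers are >= 1.
    plausibility_band
        Ratios (oriented so >= 1) outside this band trigger a
        :class:`~lungstress.exceptions.PlausibilityWarning`, never an error.
    """
    if orient not in ("as_given", "flexible_first"):
        raise UsageError(f"orient must be 'as_given' or 'flexible_first', got {orient!r}")
    ratio = pair.ratio
    if orient == "flexible_first" and ratio < 1.0:
        ratio = 1.0 / ratio
    oriented = max(ratio, 1.0 / ratio)
    lo, hi = plausibility_band
    if not (lo <= oriented <= hi):
        warnings.warn(
            f"compliance ratio {oriented:.3g} outside plausibility band [{lo}, {hi}]",
            PlausibilityWarning,
            stacklevel=2,
        )
    return AmplifierSet.from_ratio(ratio)


class InterfaceState(BaseModel):
    """The two hypothetical spheres behind an interface, at the same pressure.

    ``tension_ratio`` equals R1/R2 (the stress multiplier) and ``area_ratio``
    equals (R1/R2)^2 (the strain multiplier).
    """

    model_config = ConfigDict(frozen=True)

    flexible: SphereState
    stiff: SphereState
    tension_ratio: float
    area_ratio: float


def interface_state(
    pair: InterfacePair,
    convention: TensionConvention = TensionConvention.LAPLACE_HALF,
    baseline_volumes: Optional[Tuple[float, float]] = None,
) -> InterfaceState:
    """Materialise the two hypothetical spheres for a pair at pressure ``delta_p``.

    Each element, considered independently at the shared pressure increment,
    occupies the volume ``Ci * delta_p`` (mL); radii, areas and tensions
    follow from the sphere geometry.  ``baseline_volumes``, when given as
    ``(V0_1, V0_2)`` in mL, are added to the tidal increments before taking
    radii — an extension beyond the pure tidal-increment model, useful when
    resting volumes are known.

    Raises :class:`~lungstress.exceptions.UsageError` if the pair carries no
    ``delta_p``.
    """
    if pair.delta_p is None or pair.delta_p <= 0:
        raise UsageError("interface_state requires a positive delta_p on the pair")
    v1 = tidal_volume_linear(pair.c1, pair.delta_p)
    v2 = tidal_volume_linear(pair.c2, pair.delta_p)
    if baseline_volumes is not None:
        v01, v02 = baseline_volumes
        if v01 < 0 or v02 < 0:
            raise DomainError("baseline volumes must be non-negative")
        v1 += v01
        v2 += v02
    s1 = sphere_state(pair.delta_p, v1, convention)
    s2 = sphere_state(pair.delta_p, v2, convention)
    return InterfaceState(
        flexible=s1,
        stiff=s2,
        tension_ratio=s1.tension / s2.tension,
        area_ratio=s1.area / s2.area,
    )


def mead_pressure_amplifier(volume_ratio: float) -> float:
    """Classical boundary pressure-stress amplification for a volume ratio.

    For an expanded unit adjoining a collapsed one with distended:collapsed
    volume ratio ``v`` (>= 1), the boundary pressure stress scales as
    ``v**(2/3)``.  At the histological extreme of 10:1 this gives ~4.64,
    consistent with the traditional "about fourfold" estimate.  Note the
    shared 2/3 exponent with the strain multiplier: ``mead_pressure_amplifier(r)
    == amplifiers(r, 1).strain_multiplier`` for any r >= 1.  This is the
    comparison benchmark for the interface stress multiplier
    ``(C1/C2)**(1/3)``, which is a different (tension-based) convention.
    """
    if volume_ratio < 1.0:
        raise DomainError(
            f"volume_ratio must be >= 1 (orient the larger volume as numerator), got {volume_ratio}"
        )
    return volume_ratio ** (2.0 / 3.0)


def _radius_ratio_numeric(pair: InterfacePair) -> float:
    """Radius ratio of the two hypothetical spheres via explicit volume inversion.

    Retained as the numerically transparent route (volume -> radius -> ratio)
    used by the closed-form cross-checks.
    """
    if pair.delta_p is None or pair.delta_p <= 0:
        raise UsageError("requires a positive delta_p on the pair")
    r1 = radius_from_volume(pair.c1 * pair.delta_p)
    r2 = radius_from_volume(pair.c2 * pair.delta_p)
    return r1 / r2
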