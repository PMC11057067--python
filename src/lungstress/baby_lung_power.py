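"""Power concentration in the ventilated "baby lung".

In ARDS only a fraction of the lung remains aerated and receives the whole
tidal volume.  Under the convention that respiratory-system compliance
scales with the number of open units, the relative size of that baby lung
is ``C_obs / C_pred`` — observed compliance at optimised PEEP over the
compliance predicted for the same patient when healthy — and the relative
risk factor of power concentration is its reciprocal ``C_pred / C_obs``.

Total mechanical power is the clinical definition: breathing frequency
times the elastic inflation energy per cycle (J/min).  Specific power is
total power normalised to the baby-lung fraction: the same minute energy
delivered into a lung a quarter of its predicted size is concentrated
fourfold.
"""

from __future__ import annotations

import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .core_mechanics import VentilationCycle, elastic_energy_per_cycle
from .exceptions import DomainError, PlausibilityWarning

__all__ = [
    "PatientMechanics",
    "baby_lung_fraction",
    "power_concentration_factor",
    "total_power",
    "specific_power",
    "c_pred_default",
]


class PatientMechanics(BaseModel):
    """Ventilator settings plus observed and predicted respiratory compliance.

    ``c_obs`` is the compliance actually measured during ventilation at
    optimised PEEP, ``c_pred`` the predicted healthy value (both mL/cmH2O).
    An observed compliance above predicted is physically odd but not
    impossible to record; it warns rather than errors.
    """

    model_config = ConfigDict(frozen=True)

    c_obs: float
    c_pred: float
    cycle: VentilationCycle

    @model_validator(mode="after")
    def _check(self) -> "PatientMechanics":
        if self.c_obs <= 0 or self.c_pred <= 0:
            raise DomainError(
                f"compliances must be positive, got c_obs={self.c_obs}, c_pred={self.c_pred}"
            )
        if self.c_obs > self.c_pred:
            warnings.warn(
                f"observed compliance {self.c_obs} exceeds predicted {self.c_pred}; "
                "baby-lung fraction will exceed 1",
                PlausibilityWarning,
                stacklevel=2,
            )
        return self


def baby_lung_fraction(pm: PatientMechanics) -> float:
    """Relative size of the ventilated baby lung, ``C_obs / C_pred``."""
    return pm.c_obs / pm.c_pred


def power_concentration_factor(pm: PatientMechanics) -> float:
    """Relative risk factor of power concentration, ``C_pred / C_obs``.

    Reciprocal of :func:`baby_lung_fraction`; strictly decreasing in c_obs.
    """
    return pm.c_pred / pm.c_obs


def total_power(cycle: VentilationCycle) -> float:
    """Total mechanical power in J/min: frequency x elastic energy per cycle."""
    if cycle.frequency is None or cycle.frequency <= 0:
        raise DomainError("total_power requires a positive breathing frequency")
    return cycle.frequency * elastic_energy_per_cycle(cycle).joules


def specific_power(pm: PatientMechanics, aerated_volume_l: Optional[float] = None) -> float:
    """Power concentrated into the aerated compartment.

    By default this is total power divided by the dimensionless baby-lung
    fraction (equivalently, multiplied by ``C_pred/C_obs``), so the units
    stay J/min.  If ``aerated_volume_l`` (litres of aerated lung) is
    supplied, the normalisation is per litre instead and the result is in
    J/min/L.
    """
    power = total_power(pm.cycle)
    if aerated_volume_l is not None:
        if aerated_volume_l <= 0:
            raise DomainError(f"aerated volume must be positive, got {aerated_volume_l}")
        return power / aerated_volume_l
    return power * power_concentration_factor(pm)


def c_pred_default(predicted_body_weight_kg: float) -> float:
    """Convenience predicted compliance: 1.0 mL/cmH2O per kg of predicted body weight.

    A deliberately simple package convention for when no patient-specific
    predicted value is available; override with a measured or
    published-formula value whenever one exists.
    """
    if predicted_body_weight_kg <= 0:
        raise DomainError(
            f"predicted body weight must be positive, got {predicted_body_weight_kg}"
        )
    return 1.0 * predicted_body_weight_kg
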