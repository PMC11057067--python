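"""Oxygen contents, venous admixture, true shunt and the lung partition.

Venous admixture Qva/Qt — the virtual fraction of cardiac output behaving
as if it never met alveolar gas — is computed from the oxygen contents of
pulmonary capillary, arterial and mixed venous blood:

    ``Qva/Qt = (CcO2 - CaO2) / (CcO2 - CvO2)``.

At ambient FiO2 it mixes contributions from true shunt (perfused,
completely unventilated units) and from open but poorly ventilated
(low V/Q) units.  Re-measuring at FiO2 = 1.0 removes the hypoxic
contribution of low V/Q units, so the pure-oxygen admixture estimates true
shunt.  The difference (the *refined* estimate) — or the whole ambient
admixture under the *simplified* reading that every abnormally perfused
unit is a stress point — is used as the proportion of high-risk
compliance interfaces experienced by the aerated baby lung.

Contents follow the standard formula ``1.34 * Hb * SO2 + 0.0031 * PO2``
(mL O2/dL); capillary blood is assumed fully saturated at the alveolar O2
tension from the alveolar gas equation ``PAO2 = FiO2*(Pb - 47) - PaCO2/0.8``.
"""

from __future__ import annotations

import enum
import math
import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .exceptions import DomainError, InconsistencyError, PlausibilityWarning, UsageError

__all__ = [
    "HB_O2_CAPACITY",
    "O2_SOLUBILITY",
    "WATER_VAPOR_PRESSURE",
    "RESPIRATORY_QUOTIENT",
    "InterfaceMode",
    "BloodGasPanel",
    "OxygenContents",
    "LungPartition",
    "o2_content",
    "alveolar_po2",
    "oxygen_contents",
    "venous_admixture",
    "true_shunt_fraction",
    "high_risk_interface_fraction",
    "lung_partition",
]

#: mL O2 carried per gram of fully saturated hemoglobin.
HB_O2_CAPACITY = 1.34
#: mL O2 dissolved per dL blood per mmHg of O2 tension.
O2_SOLUBILITY = 0.0031
#: Saturated water vapor pressure at body temperature, mmHg.
WATER_VAPOR_PRESSURE = 47.0
#: Assumed respiratory exchange ratio in the alveolar gas equation.
RESPIRATORY_QUOTIENT = 0.8


class InterfaceMode(str, enum.Enum):
    """How the high-risk interface fraction is derived from gas exchange."""

    #: admixture minus true shunt: only low V/Q units count as stress points.
    REFINED = "refined"
    #: the whole venous admixture counts (no pure-O2 measurement needed).
    SIMPLIFIED = "simplified"


def _fractionalise(value: float, name: str) -> float:
    # Saturations quoted as percentages (e.g. 95) are auto-detected and scaled.
    if value > 1.5:
        warnings.warn(
            f"{name}={value} looks like a percentage; dividing by 100",
            PlausibilityWarning,
            stacklevel=4,
        )
        value = value / 100.0
    return value


class BloodGasPanel(BaseModel):
    """One set of simultaneous blood-gas measurements.

    hb g/dL; sao2/svo2 fractional saturations in [0, 1] (percentages > 1.5
    are auto-converted with a warning); pao2/pvo2 mmHg; fio2 inspired O2
    fraction in (0, 1]; paco2 mmHg feeds the alveolar gas equation;
    capillary saturation ``sco2_assumed`` defaults to 1.0 and capillary PO2,
    unless supplied as ``pc_o2``, is taken as the alveolar PO2.
    """

    model_config = ConfigDict(frozen=True)

    hb: float
    sao2: float
    svo2: float
    pao2: float
    pvo2: float
    fio2: float
    paco2: float = 40.0
    barometric_pressure: float = 760.0
    sco2_assumed: float = 1.0
    pc_o2: Optional[float] = None

    @field_validator("sao2", "svo2", "sco2_assumed", mode="before")
    @classmethod
    def _saturation_units(cls, v: float, info) -> float:
        return _fractionalise(float(v), info.field_name)

    @model_validator(mode="after")
    def _check(self) -> "BloodGasPanel":
        if self.hb <= 0:
            raise DomainError(f"hemoglobin must be positive, got {self.hb}")
        for name in ("sao2", "svo2", "sco2_assumed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in ("pao2", "pvo2", "paco2"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 < self.fio2 <= 1.0:
            raise DomainError(f"fio2 must be in (0, 1], got {self.fio2}")
        return self

    @property
    def alveolar_po2(self) -> float:
        """Ideal alveolar O2 tension for this panel (mmHg)."""
        return alveolar_po2(self.fio2, self.barometric_pressure, self.paco2)

    @property
    def capillary_po2(self) -> float:
        return self.pc_o2 if self.pc_o2 is not None else self.alveolar_po2


class OxygenContents(BaseModel):
    """Capillary, arterial and mixed-venous O2 contents (mL O2/dL).

    A physically coherent panel must have ``cv_o2 <= ca_o2 <= cc_o2``;
    violations are rejected with a diagnostic, since they make the admixture
    fraction meaningless.
    """

    model_config = ConfigDict(frozen=True)

    cc_o2: float
    ca_o2: float
    cv_o2: float

    def __init__(self, **data) -> None:
        super().__init__(**data)
        # raised directly (not wrapped) so callers can catch InconsistencyError
        tol = 1e-9
        if self.cv_o2 > self.ca_o2 + tol or self.ca_o2 > self.cc_o2 + tol:
            raise InconsistencyError(
                "oxygen contents must satisfy CvO2 <= CaO2 <= CcO2, got "
                f"Cv={self.cv_o2}, Ca={self.ca_o2}, Cc={self.cc_o2}"
            )


class LungPartition(BaseModel):
    """Partition of total predicted lung volume into functional compartments.

    ``f_normal`` — ventilated baby lung (C_obs/C_pred); ``f_low_vq`` — open
    but poorly ventilated; ``f_shunt`` — true shunt.  The three must not sum
    above 1.
    """

    model_config = ConfigDict(frozen=True)

    f_normal: float
    f_low_vq: float
    f_shunt: float

    def __init__(self, **data) -> None:
        super().__init__(**data)
        for name in ("f_normal", "f_low_vq", "f_shunt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        total = self.f_normal + self.f_low_vq + self.f_shunt
        if total > 1.0 + 1e-9:
            raise InconsistencyError(
                f"lung partition exceeds the whole lung: f_normal={self.f_normal} "
                f"+ f_low_vq={self.f_low_vq} + f_shunt={self.f_shunt} = {total} > 1"
            )

    @property
    def total(self) -> float:
        return self.f_normal + self.f_low_vq + self.f_shunt


def o2_content(hb: float, saturation: float, po2: float) -> float:
    """Blood O2 content (mL O2/dL): ``1.34*Hb*SO2 + 0.0031*PO2``."""
    if hb < 0:
        raise DomainError(f"hemoglobin must be non-negative, got {hb}")
    saturation = _fractionalise(saturation, "saturation")
    if not 0.0 <= saturation <= 1.0:
        raise DomainError(f"saturation must be a fraction in [0, 1], got {saturation}")
    if po2 < 0:
        raise DomainError(f"PO2 must be non-negative, got {po2}")
    return HB_O2_CAPACITY * hb * saturation + O2_SOLUBILITY * po2


def alveolar_po2(
    fio2: float, barometric_pressure: float = 760.0, paco2: float = 40.0
) -> float:
    """Ideal alveolar O2 tension: ``FiO2*(Pb - 47) - PaCO2/0.8`` (mmHg)."""
    pao2 = fio2 * (barometric_pressure - WATER_VAPOR_PRESSURE) - paco2 / RESPIRATORY_QUOTIENT
    if pao2 < 0:
        raise DomainError(
            f"alveolar PO2 computes negative ({pao2:.1f} mmHg); check fio2/paco2"
        )
    return pao2


def oxygen_contents(panel: BloodGasPanel) -> OxygenContents:
    """The three O2 contents of a panel (capillary from the alveolar gas equation)."""
    return OxygenContents(
        cc_o2=o2_content(panel.hb, panel.sco2_assumed, panel.capillary_po2),
        ca_o2=o2_content(panel.hb, panel.sao2, panel.pao2),
        cv_o2=o2_content(panel.hb, panel.svo2, panel.pvo2),
    )


def venous_admixture(contents: OxygenContents) -> float:
    """Venous admixture fraction ``(CcO2 - CaO2) / (CcO2 - CvO2)``.

    The content ordering guarantees a value in [0, 1]; floating-point
    round-off within 1e-9 of the boundaries is clipped.
    """
    denom = contents.cc_o2 - contents.cv_o2
    if denom <= 0:
        raise DomainError(
            "degenerate panel: capillary content must exceed venous content "
            f"(Cc={contents.cc_o2}, Cv={contents.cv_o2})"
        )
    qva = (contents.cc_o2 - contents.ca_o2) / denom
    return min(max(qva, 0.0), 1.0)


def true_shunt_fraction(panel_at_fio2_1: BloodGasPanel) -> float:
    """Venous admixture on a pure-oxygen panel, estimating true shunt.

    Requires ``fio2 == 1.0``: only then does the measurement exclude the
    hypoxic contribution of low V/Q units.
    """
    if not math.isclose(panel_at_fio2_1.fio2, 1.0):
        raise UsageError(
            f"true shunt requires a panel measured at FiO2 = 1.0, got {panel_at_fio2_1.fio2}"
        )
    return venous_admixture(oxygen_contents(panel_at_fio2_1))


def high_risk_interface_fraction(
    admixture: float, shunt: float = 0.0, mode: InterfaceMode = InterfaceMode.REFINED
) -> float:
    """Proportion of high-risk compliance interfaces, from gas exchange.

    ``refined``: ambient admixture minus true shunt — the low V/Q units
    only.  ``simplified``: the whole ambient admixture, for when no
    pure-oxygen measurement is available.  Refined mode rejects a shunt
    exceeding the admixture (a negative interface fraction is physically
    meaningless and flags incoherent measurements).
    """
    mode = InterfaceMode(mode)
    for name, v in (("admixture", admixture), ("shunt", shunt)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must be a fraction in [0, 1], got {v}")
    if mode is InterfaceMode.SIMPLIFIED:
        return admixture
    if shunt > admixture + 1e-9:
        raise InconsistencyError(
            f"true shunt ({shunt}) exceeds venous admixture ({admixture}); "
            "the refined interface fraction would be negative"
        )
    return max(admixture - shunt, 0.0)


def lung_partition(
    c_obs: float, c_pred: float, shunt: float, low_vq: float
) -> LungPartition:
    """Partition of predicted lung volume: baby lung, low V/Q, true shunt.

    ``f_normal = c_obs/c_pred``; shunt and low_vq pass through.  Raises
    :class:`~lungstress.exceptions.InconsistencyError` (naming all three
    addends) if the fractions sum above 1.
    """
    if c_obs <= 0 or c_pred <= 0:
        raise DomainError(
            f"compliances must be positive, got c_obs={c_obs}, c_pred={c_pred}"
        )
    return LungPartition(f_normal=c_obs / c_pred, f_low_vq=low_vq, f_shunt=shunt)
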