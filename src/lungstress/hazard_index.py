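"""The multi-component VILI hazard report and an optional composite score.

The report assembles, for one patient, the five risk amplifiers of the
conceptual model:

=====================  =================  =========================
component              baseline variable  hazard multiplier
=====================  =================  =========================
stress                 tension            (C1/C2)^(1/3)
strain                 area               (C1/C2)^(2/3)
surface energy         tension x area     C1/C2
baby lung size         compliance         C_obs/C_pred
high-risk interfaces   venous admixture   Qva/Qt (minus true shunt)
=====================  =================  =========================

plus the derived specific power (J/min concentrated into the baby lung).
Components can move in opposite directions under an intervention (e.g.
raising PEEP recruits units but raises per-cycle energy); the report keeps
them separate — no netting.

``composite_score`` multiplies a configurable subset into one number.  The
default — specific power x stress multiplier x interface fraction — is a
package convention for ranking scenarios, not a validated clinical index.
"""

from __future__ import annotations

import math
import warnings
from typing import Any, Dict, Mapping, Optional, Union

from pydantic import BaseModel, ConfigDict, model_validator

from .baby_lung_power import (
    PatientMechanics,
    baby_lung_fraction,
    specific_power,
    total_power,
)
from .exceptions import ConfigError, DomainError, LungStressError, PlausibilityWarning
from .gas_exchange import InterfaceMode, OxygenContents, high_risk_interface_fraction, venous_admixture
from .interface_amplification import AmplifierSet, InterfacePair, amplifiers

__all__ = ["HazardReport", "build_hazard_report", "composite_score", "DEFAULT_WEIGHTS"]

#: Default composite exponents: specific power x stress multiplier x interface fraction.
DEFAULT_WEIGHTS: Dict[str, float] = {
    "specific_power": 1.0,
    "stress_multiplier": 1.0,
    "strain_multiplier": 0.0,
    "surface_energy_ratio": 0.0,
    "baby_lung_fraction": 0.0,
    "interface_fraction": 1.0,
}


class HazardReport(BaseModel):
    """One patient's multi-component VILI hazard profile.

    All multipliers are dimensionless; ``specific_power`` and
    ``total_power`` are in J/min.  ``interface_fraction`` is expressed as a
    fraction of total predicted lung volume;
    ``interface_fraction_of_baby_lung`` renormalises it to the aerated baby
    lung (divides by the baby-lung fraction, capped at 1) — both readings
    are reported because the gas-exchange estimate does not itself fix the
    denominator.  ``provenance`` records the inputs each component came from.
    """

    model_config = ConfigDict(frozen=True)

    stress_multiplier: float
    strain_multiplier: float
    surface_energy_ratio: float
    baby_lung_fraction: float
    interface_fraction: float
    specific_power: float
    total_power: float
    interface_fraction_of_baby_lung: float
    provenance: Dict[str, Any] = {}

    @model_validator(mode="after")
    def _check(self) -> "HazardReport":
        prod = self.stress_multiplier * self.strain_multiplier
        if not math.isclose(prod, self.surface_energy_ratio, rel_tol=1e-12):
            raise DomainError(
                f"stress*strain = {prod} does not match surface_energy_ratio "
                f"= {self.surface_energy_ratio}"
            )
        for name in (
            "stress_multiplier",
            "strain_multiplier",
            "surface_energy_ratio",
            "baby_lung_fraction",
            "interface_fraction",
            "specific_power",
            "total_power",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.interface_fraction > 1.0:
            raise DomainError(
                f"interface_fraction must be in [0, 1], got {self.interface_fraction}"
            )
        if self.baby_lung_fraction > 1.0:
            warnings.warn(
                f"baby-lung fraction {self.baby_lung_fraction} exceeds 1",
                PlausibilityWarning,
                stacklevel=2,
            )
        return self


def _component(name: str):
    """Re-raise module errors annotated with the failing hazard component."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (LungStressError, ValueError)):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def build_hazard_report(
    pm: PatientMechanics,
    pair: InterfacePair,
    admixture: Union[float, OxygenContents],
    shunt: float = 0.0,
    mode: InterfaceMode = InterfaceMode.REFINED,
    damage_threshold: Optional[float] = None,
) -> HazardReport:
    """Assemble the hazard report from per-module computations.

    ``admixture`` may be given directly as a fraction or as an
    :class:`~lungstress.gas_exchange.OxygenContents` from which it is
    computed.  ``damage_threshold`` (cmH2O), when supplied, only flags in the
    provenance whether end-inspiratory pressure (PEEP + dP) reaches it — no
    recommendation is derived.  Errors from any component propagate with the
    component name prepended.
    """
    with _component("interface_amplification"):
        amp: AmplifierSet = amplifiers(pair)
    with _component("baby_lung"):
        blf = baby_lung_fraction(pm)
    with _component("power"):
        tp = total_power(pm.cycle)
        sp = specific_power(pm)
    with _component("gas_exchange"):
        if isinstance(admixture, OxygenContents):
            qva = venous_admixture(admixture)
        else:
            qva = float(admixture)
        frac = high_risk_interface_fraction(qva, shunt, mode)
    frac_baby = min(frac / blf, 1.0) if blf > 0 else 0.0

    provenance: Dict[str, Any] = {
        "c_obs": pm.c_obs,
        "c_pred": pm.c_pred,
        "cycle": pm.cycle.model_dump(),
        "c1": pair.c1,
        "c2": pair.c2,
        "admixture": qva,
        "shunt": shunt,
        "mode": InterfaceMode(mode).value,
    }
    if damage_threshold is not None:
        end_insp = pm.cycle.peep + pm.cycle.driving_pressure
        provenance["damage_threshold"] = damage_threshold
        provenance["end_inspiratory_pressure"] = end_insp
        provenance["pressure_exceeds_threshold"] = bool(end_insp >= damage_threshold)

    return HazardReport(
        stress_multiplier=amp.stress_multiplier,
        strain_multiplier=amp.strain_multiplier,
        surface_energy_ratio=amp.energy_ratio,
        baby_lung_fraction=blf,
        interface_fraction=frac,
        specific_power=sp,
        total_power=tp,
        interface_fraction_of_baby_lung=frac_baby,
        provenance=provenance,
    )


def rebuild_from_provenance(report: HazardReport) -> HazardReport:
    """Recompute a report from its own recorded inputs (reproducibility check)."""
    prov = report.provenance
    pm = PatientMechanics(
        c_obs=prov["c_obs"],
        c_pred=prov["c_pred"],
        cycle=prov["cycle"],
    )
    pair = InterfacePair(c1=prov["c1"], c2=prov["c2"])
    kwargs = {}
    if "damage_threshold" in prov:
        kwargs["damage_threshold"] = prov["damage_threshold"]
    return build_hazard_report(
        pm, pair, prov["admixture"], prov["shunt"], InterfaceMode(prov["mode"]), **kwargs
    )


def composite_score(
    report: HazardReport, weights: Optional[Mapping[str, float]] = None
) -> float:
    """One-number summary: product of components raised to exponent weights.

    ``weights`` maps component names (keys of :data:`DEFAULT_WEIGHTS`) to
    non-negative exponents; a weight of zero drops the component.  The
    default keeps specific power, the stress multiplier and the interface
    fraction.  This composition is a package convention — the underlying
    model presents the components separately and prescribes no single index.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights is not None:
        unknown = set(weights) - set(w)
        if unknown:
            raise ConfigError(f"unknown composite-score components: {sorted(unknown)}")
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ConfigError(f"composite-score weights must be non-negative, got {w}")
    score = 1.0
    for name, exponent in w.items():
        if exponent == 0.0:
            continue
        score *= getattr(report, name) ** exponent
    return score
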