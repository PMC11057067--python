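"""The full multi-component hazard report for one worked patient.

Combines the interface amplifiers, baby-lung power concentration and
gas-exchange interface prevalence into the five-component profile, plus
the (package-convention) composite score.
"""

from lungstress import (
    InterfacePair,
    PatientMechanics,
    VentilationCycle,
    build_hazard_report,
    composite_score,
)

pm = PatientMechanics(
    c_obs=20.0,
    c_pred=80.0,
    cycle=VentilationCycle(peep=5.0, driving_pressure=10.0, tidal_volume=0.4, frequency=20.0),
)
report = build_hazard_report(
    pm, InterfacePair(c1=10.0, c2=1.0), admixture=0.40, shunt=0.25, damage_threshold=25.0
)

print(f"stress multiplier         : {report.stress_multiplier:.4f}")
print(f"strain multiplier         : {report.strain_multiplier:.4f}")
print(f"surface energy ratio      : {report.surface_energy_ratio:.1f}")
print(f"baby-lung fraction        : {report.baby_lung_fraction:.2f}")
print(f"interface fraction        : {report.interface_fraction:.2f} of predicted lung "
      f"({report.interface_fraction_of_baby_lung:.2f} of the baby lung)")
print(f"total power               : {report.total_power:.3f} J/min")
print(f"specific power            : {report.specific_power:.2f} J/min")
print(f"pressure threshold flag   : {report.provenance['pressure_exceeds_threshold']}")
print(f"composite score (default) : {composite_score(report):.3f}")
print()
print("Each row is one hazard component; they are reported separately because")
print("an intervention (e.g. raising PEEP) can move them in opposite directions.")
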