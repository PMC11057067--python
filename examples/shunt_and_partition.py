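"""Venous admixture, true shunt and the high-risk interface fraction.

Blood-gas panels at ambient FiO2 and at pure oxygen separate the venous
admixture into true shunt (unventilated, exempt from inflation injury) and
low-V/Q units (open, poorly ventilated — the locus of interfacial stress
amplification).  The lung partition then places baby lung, low-V/Q and
shunt fractions side by side.
"""

from lungstress import (
    BloodGasPanel,
    InterfaceMode,
    high_risk_interface_fraction,
    lung_partition,
    oxygen_contents,
    true_shunt_fraction,
    venous_admixture,
)

ambient = BloodGasPanel(hb=12.0, sao2=0.92, svo2=0.70, pao2=70.0, pvo2=40.0, fio2=0.6)
pure_o2 = BloodGasPanel(hb=12.0, sao2=0.98, svo2=0.70, pao2=150.0, pvo2=40.0, fio2=1.0)

contents = oxygen_contents(ambient)
print(f"O2 contents (Cc, Ca, Cv) : {contents.cc_o2:.2f}, {contents.ca_o2:.2f}, "
      f"{contents.cv_o2:.2f} mL/dL")

qva = venous_admixture(contents)
shunt = true_shunt_fraction(pure_o2)
refined = high_risk_interface_fraction(qva, shunt, InterfaceMode.REFINED)
simplified = high_risk_interface_fraction(qva, mode=InterfaceMode.SIMPLIFIED)

print(f"venous admixture Qva/Qt  : {qva:.3f}")
print(f"true shunt (FiO2 = 1.0)  : {shunt:.3f}")
print(f"interface fraction       : {refined:.3f} (refined) / {simplified:.3f} (simplified)")

part = lung_partition(c_obs=25.0, c_pred=80.0, shunt=shunt, low_vq=refined)
print(f"lung partition           : baby lung {part.f_normal:.2f}, "
      f"low V/Q {part.f_low_vq:.2f}, shunt {part.f_shunt:.2f} "
      f"(sum {part.total:.2f} of predicted lung)")
print()
print("The refined estimate counts only low-V/Q units as stress-focusing")
print("interfaces; the simplified one treats the whole admixture that way.")
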