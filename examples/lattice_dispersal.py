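"""Lattice simulation: interface prevalence from segregated to dispersed.

Generates 20x20 lung-unit lattices with 30% abnormal units at increasing
dispersal, counts heterogeneous interfaces, summarises the per-edge stress
multipliers, and then recovers the dispersal parameter of a fresh field
from its spatial statistics.
"""

import numpy as np

from lungstress import (
    SimulationConfig,
    amplifier_distribution,
    estimate_dispersal,
    generate_field,
    heterogeneous_interface_fraction,
)

print("dispersal  interface fraction (mean over 20 seeds)")
for d in (0.0, 0.25, 0.5, 0.75, 1.0):
    fracs = [
        heterogeneous_interface_fraction(
            generate_field(
                SimulationConfig(nx=20, ny=20, abnormal_fraction=0.3, dispersal=d, seed=s)
            )
        )
        for s in range(20)
    ]
    print(f"   {d:4.2f}      {np.mean(fracs):.3f}")

cfg = SimulationConfig(nx=50, ny=50, abnormal_fraction=0.3, dispersal=0.6, seed=99)
field = generate_field(cfg)
summary = amplifier_distribution(field, threshold=1.5)
print(f"\n50x50 field at dispersal 0.6: {summary.n_edges} heterogeneous edges")
print(f"stress multiplier mean/median/max : {summary.mean:.2f} / {summary.median:.2f} "
      f"/ {summary.max:.2f}")
print(f"fraction of edges >= 1.5x         : {summary.exceedance_fraction:.2f}")
print(f"recovered dispersal               : {estimate_dispersal(field, cfg):.3f} (truth 0.6)")
print()
print("Scattering the same number of abnormal units multiplies the number of")
print("stress-focusing interfaces several-fold relative to a segregated block.")
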