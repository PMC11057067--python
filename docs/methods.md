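# Methods

## Model and assumptions

`lungstress` models each lung unit as a hollow, thin-walled sphere under
static inflation: time-invariant conditions, open architecture (no tidal
opening/closure), a linear pressure–volume relationship, and shape
preserved during expansion. These assumptions make every quantity a closed
form of bedside variables; none of the modules attempt dynamics,
viscoelasticity, gravitational gradients of transpulmonary pressure, or
mechanical interdependence between units.

### Sphere mechanics and the two tension conventions

For a sphere, `V = 4/3·π·R³`, `A = 4·π·R²`, and the Laplace wall tension is
`T = P·R/2`. A second convention, `T = P·R/3`, is also exposed
(`TensionConvention.ENERGY_THIRD`): it is the unique choice under which the
shell energy bookkeeping `T·A = P·V` holds exactly, whereas the Laplace
convention gives `T·A = (3/2)·P·V`. The two conventions are mutually
inconsistent by that constant factor 3/2, and both the Laplace tension and
the energy identity circulate in the alveolar-mechanics literature without
reconciliation — so the package exposes the pair explicitly (default
`laplace_half`) and audits the 3/2 ratio in its tests rather than hiding
it. All amplifier *ratios* are independent of
the choice, since the constant cancels.

### Interface amplifiers

Two surface elements of compliances `C1 ≥ C2` exposed to the same pressure
increment behave like independent spheres of volume `Ci·ΔP`, giving radius
ratio `(C1/C2)^(1/3)`. Tension is proportional to radius at equal pressure,
area to radius squared, so:

* stress (tension) multiplier `(C1/C2)^(1/3)`,
* strain (area) multiplier `(C1/C2)^(2/3)`,
* stored-energy ratio — their product — `C1/C2`.

Baseline (resting) volumes are ignored by default because the model is
built entirely on tidal increments; an optional `baseline_volumes` argument
adds `V0,i` before taking radii, as a documented extension. Compliance
ratios outside [1, 10] (the histological distended:collapsed volume range)
warn but never error. The classical boundary *pressure* amplification
`(V1/V2)^(2/3)` is provided for comparison (`mead_pressure_amplifier`); it
shares the 2/3 exponent with the strain multiplier, which the API notes
openly, and at the 10:1 extreme evaluates to 4.64 — consistent with the
traditional "about fourfold" estimate. The tension-based stress multiplier
at the same ratio is 2.15; the two conventions answer different questions
and are deliberately not harmonised.

### Energy and power

The inflation energy per cycle on the linear PV curve is the integral of
volume over pressure from PEEP to PEEP+ΔP:

    E = ΔV·(PEEP + ΔP/2)   [cmH2O·L],   1 cmH2O·L = 0.0980665 J.

Only static elastic energy is counted — resistive (flow) energy is outside
the static model. Total power is `f·E` (J/min). Specific power divides by
the dimensionless baby-lung fraction `C_obs/C_pred` (units stay J/min);
normalisation per litre of aerated volume is available when that volume is
measured, because the model itself does not fix which denominator is
intended. `c_pred_default` (1.0 mL/cmH2O per kg predicted body weight) is a
deliberately simple package convention, always overridable.

### Gas exchange

O2 content is `1.34·Hb·SO2 + 0.0031·PO2` (mL/dL); capillary blood is
assumed fully saturated at the alveolar tension from
`PAO2 = FiO2·(Pb − 47) − PaCO2/0.8`. Venous admixture is
`(CcO2−CaO2)/(CcO2−CvO2)`; measured again at FiO2 = 1.0 it estimates true
shunt. The *refined* high-risk interface fraction is admixture − shunt
(low-V/Q units only); the *simplified* one is the whole admixture. The
choice is an explicit enum, and a shunt exceeding the admixture raises an
inconsistency error rather than returning a negative fraction. Because the
gas-exchange estimate does not fix its denominator, the hazard report
carries both readings: the fraction of total predicted lung and the same
number renormalised to the aerated baby lung (divided by `C_obs/C_pred`,
capped at 1). Saturations supplied as percentages (> 1.5) are divided by
100 with a warning; no other unit inference is attempted.

### Hazard report and composite score

`build_hazard_report` assembles the five multipliers plus total and
specific power, records all inputs in a provenance map (reports can be
rebuilt bit-identically from it), and propagates any component failure with
the component named. Components are never netted against each other: an
intervention such as raising PEEP can raise per-cycle energy while
recruiting units (raising `C_obs`, lowering admixture), and the report
shows both directions. An optional `damage_threshold` (cmH2O) only flags
whether end-inspiratory pressure reaches it. `composite_score` multiplies
components raised to configurable non-negative exponents; the default
(specific power × stress multiplier × interface fraction) is a package
convention for ranking scenarios and is not part of the underlying model.

## The lattice simulator

The simulator realises the two spatial extremes of interface prevalence on
an `nx × ny` lattice with 4-neighbour (von Neumann) adjacency and
non-periodic boundaries — the simplest geometry in which interfaces can be
enumerated exactly (`nx·(ny−1) + ny·(nx−1)` edges). Dispersal 0 packs the
abnormal fraction into a contiguous block of whole columns from the left
edge; dispersal 1 places labels by a uniform random permutation.

For intermediate dispersal `d`, `round(d·k)` of the `k` abnormal units are
relocated — each a seeded label swap with a uniformly chosen open position
(including just-vacated block cells, so `d → 1` converges to uniform
placement). Relocation was chosen over uniform pairwise shuffling of all
cells after measuring that the latter mixes to statistical uniformity after
roughly one swap per cell: beyond small `d` every field distribution
becomes indistinguishable from fully random, making the dispersal
parameter unrecoverable in principle. Under relocation the block retains
`(1−d)·k` abnormal units, so the field remains informative about `d` over
the whole range and the mean interface fraction rises strictly and
near-linearly.

Unit compliances are lognormal per label class — ratios stay positive —
with default medians 2.0 (normal) and 0.25 (abnormal) mL/cmH2O and sigma
0.25: a median ratio of 8, inside the 10:1 histological bound. Per
heterogeneous edge the stress multiplier is `(C_high/C_low)^(1/3)` of the
two incident units; summaries (mean, median, max, threshold exceedance)
are deterministic for a fixed field, and a field with no heterogeneous
edges yields an `n_edges = 0` sentinel with NaN statistics, not an
exception. One seeded generator drives each simulation; the seed is part
of the configuration.

`estimate_dispersal` recovers `d` by inverting a Monte Carlo calibration
(200 replicate fields per point on an 11-point dispersal grid, anchored to
a fixed internal seed so the curve is reproducible across processes,
monotonised before inversion). The inverted statistic is the
*block-retention* fraction — how much of the dispersal-0 block is still
abnormal — whose mean falls essentially linearly in `d` and is therefore
well-conditioned everywhere; the interface fraction itself flattens near
full dispersal (its calibration curve remains available via
`dispersal_calibration_curve` and underpins the monotonicity checks).
Measured on 50×50 grids with 30% abnormal units, recovery lands within
±0.1 of truth in 50/50 replicates (maximum error ≈ 0.05) across
independent seed streams.

## Synthetic cohort

`generate_synthetic_cohort` draws ARDS-plausible mechanics uniformly
(`C_obs` 15–45, `C_pred` 60–100 mL/cmH2O, ΔP 8–18, PEEP 5–16 cmH2O, f
14–28/min) and sets tidal volume consistently as `C_obs·ΔP`. Blood-gas
panels are constructed backwards from drawn shunt (0.05–0.30) and low-V/Q
(0.02–0.25) fractions, both capped by the headroom `1 − C_obs/C_pred`, so
every record is coherent by construction: `CvO2 ≤ CaO2 ≤ CcO2`, admixture ≥
true shunt, and the lung partition sums below 1. Arterial saturation and
tension are then chosen to reproduce the implied content (saturation capped
at 1 with the tension absorbing the remainder). The generator emulates the
*arithmetic* structure of clinical data — it does not emulate measurement
noise, oxyhemoglobin dissociation, hemodynamic coupling, or longitudinal
change, so passing tests demonstrate internal consistency of the model
pipeline, not clinical validity.

The packaged `data/synthetic_cohort.csv` is this generator's output for
n = 20, seed = 7.

## Numerical choices and limitations

* Geometric identities validated at 1e-9 relative; amplifier product
  identity at 1e-12; floating-point spill at admixture boundaries clipped
  within 1e-9.
* Problem sizes in tests and the acceptance script (4×4 exact enumeration,
  20×20 × 100 seeds for monotonicity, 50×50 × 50 replicates for recovery)
  were chosen as the smallest grids at which the lattice statistics are
  stable; all complete in seconds.
* The model is conceptual: static, spherical, linear. It is not a predictor
  of clinical outcomes, the composite score is not a validated index, and
  the lattice is a test bed for monotonicity claims — there is no
  quantitative mapping from a gas-exchange interface fraction to a spatial
  arrangement.
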