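# mpsflow

Design and analysis toolkit for **two-channel membrane-barrier
microphysiological systems** (organ-on-chip devices): microfluidic chips in
which an apical and a basal channel are separated by a porous culture
membrane, used to model tissue barriers such as the alveolar air–liquid
interface and the glomerular filtration barrier (GFB).

It is written for the people who design and run such chips: it answers the
hydraulic questions (what flows, pressures, shear stresses and
ultrafiltration rates a pump setting produces), quantifies membrane stretch
from microscope deflection measurements, generates the pump pressure
programs, and reduces the barrier-function assays (TEER, solute filtration)
to tidy tables.

## Models

**Hydraulics** — the chip is a resistor network via the hydraulic–electric
analogy (pressure ↔ voltage, flow ↔ current). A shallow channel contributes
the plane-Poiseuille resistance `R = 12 μ l / (b h³)` and its wall shear
stress at flow Q is `τ = 6 μ Q / (b h²)`. Each membrane pore is a
Hagen–Poiseuille pipe, `R_pore = 8 μ L / (π R⁴)`; the membrane is `A·ρ_pore`
pores in parallel (`ρ_pore` = pore areal density), `R_memb = R_pore /
(A ρ_pore)`, equivalent to a Darcy layer of permeability `k = π ρ_pore R⁴/8`.
The two channel chains, bridged segment-by-segment by the membrane over the
culture well, form a linear nodal system solved exactly; its net
basal→apical crossing flow is the ultrafiltration rate.

**Mechanics** — a pressurized membrane bulges as a semi-ellipsoid of cap
height `a` (the measured focal-distance change) over base semi-axes `b, c`.
Surface area uses the Thomsen approximation (p = 1.6075) plus the base
ellipse, and the bi-axial strain is `ε_SA = (SA(a) − SA(0)) / SA(0)`.

**Assays** — TEER by the Ohm's-law method, `TEER = (R_meas − R_blank) ·
M_area`; solute filtration by the renal-clearance form `([A]·AV)/[B]`,
normalized to the blank membrane.

**Synthetic data** — seeded generators emulate every instrument (flow meter,
focal-distance microscope, volt-ohm meter, plate reader) around known ground
truth, so parameter recovery is testable end-to-end without bench data.

## Worked example

```sh
mpsflow design --out runs/design
```

prints (abridged):

```
parameters:
  apical channel: width 6 mm, height 0.5 mm, length 45 mm, well span 4.5 mm at 6 mm; R = 7.2e+08 Pa.s/m^3
  basal channel: width 4.5 mm, height 0.5 mm, length 45 mm, well span 6 mm at 6 mm; R = 9.6e+08 Pa.s/m^3
  membrane: pore radius 1.5 um, thickness 10 um, pore density 2e+06 cm^-2 (porosity 0.141), area 27 mm^2
  R_pore = 5.03e+15 Pa.s/m^3
  R_memb = 9.315e+09 Pa.s/m^3
  k = 3.976e-14 m^2

wall shear stress at the culture well:
  Q = 100 uL/min: apical 0.006667 Pa, basal 0.008889 Pa

coupled network (64 segments):
  apical inlet pressure 1.217 Pa; basal inlet pressure 1.578 Pa
  transmembrane flow Q_tm = 1.692 uL/min (positive basal->apical)
```

Reading this: the narrower basal channel has the higher hydraulic resistance,
so at equal 100 µL/min inlet flows its pressure at the culture well exceeds
the apical pressure; that excess drives ~1.7 µL/min of ultrafiltration across
the membrane in the "urinary" (basal→apical) direction, the same mechanism
that filters plasma across the GFB. The shear stresses confirm the membrane's
two faces see different flow microenvironments at equal flow.

Other entry points:

```sh
mpsflow fixtures --out runs/fix --seed 7        # synthetic dataset tree
mpsflow assay runs/fix/filtration_readouts.csv  # normalized filtration table
mpsflow strain runs/fix/deflection_sweep.csv    # bi-axial strain curve
mpsflow waveform breathing                      # breathing-cycle pump program
```

Every run directory contains a `manifest.json` with the config hash, seed and
package version; reruns with the same config are byte-identical.

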