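# Methods

## Scope and model idea

`mpsflow` models a two-channel membrane-barrier chip as a lumped-parameter
hydraulic network. The full 3-D velocity/pressure field of such a device is a
finite-element problem (Navier–Stokes in the channels coupled to a Brinkman
porous layer); at the Reynolds numbers and geometries of these chips
(Re « 1, shallow channels), the flow is Stokes-like and unidirectional
almost everywhere, so a resistor-network reduction captures the quantities a
designer actually uses — pressures, flow splits, shear stresses, and the
transmembrane ultrafiltration rate — at a fraction of the cost, with exact
linear-algebraic conservation properties that are testable to machine
precision.

## Hydraulic network

- **Channels.** A shallow rectangular channel (h ≤ b) has plane-Poiseuille
  resistance `R = 12 μ l / (b h³)`. This closure is consistent with the
  plane-Poiseuille wall-shear formula `τ = 6 μ Q /(b h²)` used for the shear
  estimates. The exact rectangular-duct Fourier-series correction (a ~5–10%
  effect at h/b ≈ 0.1) is available via `channel_resistance(..., exact=True)`
  but is not the default, keeping the closure algebraically consistent with
  the shear formula.
- **Membrane.** Each track-etched pore is a circular pipe:
  `R_pore = 8 μ L/(π R⁴)`. With pore areal density ρ_pore on wetted area A,
  `R_memb = R_pore/(A ρ_pore)` (parallel pipes), equivalently a Darcy layer
  with `k = π ρ_pore R⁴/8 = φ R²/8` where `φ = ρ_pore π R²` is the open-area
  fraction. The identity `R_memb = μ L/(k A)` holds exactly and is enforced
  by test. Note ρ_pore carries units of m⁻²; treating it as the dimensionless
  porosity fraction would misstate the membrane resistance by the pore area
  factor π R² (~12 orders of magnitude here) — `MembraneSpec` therefore
  stores the density and derives the fraction.
- **Discretization.** The culture-well region of each channel is split into
  n segment-centre nodes (node-centred finite volume); segments outside the
  well are lumped inlet/outlet resistors. Each of the n membrane bridges
  carries area A/n (resistance n·R_memb) and connects facing segment centres
  (co-current alignment; the physical channels cross at the well, but at
  these resistance ratios the alignment choice is far below other closure
  errors). Kirchhoff's current law at every free node gives a small dense
  symmetric system solved directly (`numpy.linalg.solve`); n = 64 by default,
  converged to « 0.1% against n = 128, and n = 1 reproduces the hand-solved
  star circuit exactly.
- **Boundaries.** Each inlet is either a pressure or a flow source; outlets
  are fixed gauge pressures (default 0 = open reservoir) or sealed. A fully
  flow-driven, fully sealed configuration has no pressure reference and is
  rejected as ill-posed.
- **Sign convention.** Transmembrane flux is positive basal→apical — the
  urinary direction in the glomerular configuration.

## Default parameter set (and why)

Documented device facts: culture-well widths 6 mm (apical) / 4.5 mm (basal),
channel height 0.5 mm, water (μ = 1 mPa·s, ρ = 1000 kg/m³), 3 µm-pore
track-etched culture membrane, well overlap 6 × 4.5 mm = 27 mm². The
remaining parameters are not part of the device's documented
characterization and are closed once, here:

| parameter | default | rationale |
|---|---|---|
| membrane pore radius | 1.5 µm | half the 3 µm pore size |
| membrane thickness L | 10 µm | typical track-etched insert (10–25 µm); low end typical of 3 µm-pore PC/PET films |
| pore density ρ_pore | 2×10⁶ cm⁻² | manufacturer-typical for 3 µm inserts → open fraction φ ≈ 0.141 |
| channel length | 45 mm | chip-holder format (≈45 mm chip) |
| well axial offset | 6 mm from inlet | compact inlet routing; places the well near the inlet end |
| basal channel height | 0.5 mm | the apical value; the basal height is not separately documented (both are config fields) |
| planform semi-axes b, c | 3, 2.25 mm | half the culture-well widths |
| TEER area M_area | 0.336 cm² | transwell membrane area; **required explicit** in the API |

All are overridable through the config file, and every solver result carries
the parameter set it used. With these defaults the model predicts
Q_tm ≈ 1.69 µL/min at 100 µL/min on both inlets — the right magnitude and
direction for pressure-driven ultrafiltration in this class of device; the
prediction is most sensitive to the undocumented feed-channel geometry and
membrane thickness/density, which bound its fidelity to roughly ±25%.

## Membrane strain

The bulged membrane is treated as a semi-ellipsoid cap of height a (the
measured focal-distance change) over base semi-axes b ≥ c, with the Thomsen
surface-area approximation (p = 1.6075) plus the base ellipse. The reference
state SA(0) is evaluated **with the same formula at a = 0**, not as the flat
ellipse πbc: the Thomsen term leaves a residual `2πbc(1/3)^{1/p}` at a = 0
(an ≈1% artefact of the approximation), and using one formula for both
states cancels it and makes ε_SA(0) = 0 exact. The approximation is exact
for a hemisphere (3πr²), which the tests exploit as a closed-form oracle.
ε_SA is strictly increasing in a, so strain→deflection inversion (used to
anchor the 4% protocol maximum) is a bracketed root-find. No plate-theory
pressure→deflection model is implemented: deflection is always a measured
input; the synthetic generator's power-law compliance `a(P) = c₁P^{c₂}`
(c₂ = 0.8) is a monotone stand-in with no physical claim, its c₁ anchored so
the noiseless sweep ends at 4% strain at 315 mbar.

## Waveforms

Pump programs are idealized command series (inclusive endpoint, default
10 Hz sampling): constant holds and sinusoids `offset + A sin(2πft)`.
Commands must stay ≥ 0 (the pumps cannot pull vacuum); clipping at 0 is an
explicit opt-in. Real pump actuation reshapes the realized waveform; no
transfer function is available, so none is modeled. The breathing protocol
defaults to amplitude 345 mbar at 0.33 Hz (20 breaths/min) with offset =
amplitude so the trough touches 0 — the baseline is the package's own
choice, as none is documented for the hardware. CSV export uses shortest-repr floats, so
export→import→export is byte-identical.

## Assays

TEER: `(R_meas − R_blank)·M_area`. Negative cell-layer resistances are
returned with a warning, not raised (routine artefact; must not kill batch
runs). Filtration: `[A]·AV/[B]` (renal-clearance form), averaged per
(solute, condition) and normalized by the same-solute blank mean — hence
blank rows are exactly 1.0 for any replicate count. Raw plate-reader signals
map to concentration through a linear blank-subtracted calibration (slope,
intercept, blank); nonlinear (4PL) calibration and group-comparison
statistics (t-tests/ANOVA) are deliberately out of scope — outputs are tidy
CSV for any stats environment.

## Synthetic data and what the tests show

Noise models: additive Gaussian for physical sensors (flow meter: sd as
fraction of full scale, default 2%; focal distance: 2 µm; ohmmeter: 5 Ω) and
multiplicative log-normal (mean 1) for concentrations (default CV 10%).
TEER time courses use logistic coverage growth with plateaus ordered
co-culture > endothelial-only > podocyte-only (70/60/20 Ω·cm², co-culture
only slightly above endothelial alone). The injury scenario doubles albumin
sieving (control 0.15 → S1P 0.30, blank 0.90) and leaves inulin essentially
free (0.85 everywhere with cells); replicate count defaults to 3.

Passing tests therefore demonstrate: internal consistency (conservation,
linearity, mesh convergence, closed-form limits), correct implementation of
the stated formulas, and that the fitting routines recover known parameters
under the stated noise (resistance within 5% in ≥95% of 200 replicates at 2%
sensor noise; permeability median error <10% at 5% noise). They do **not**
validate the noise models against real instruments, the compliance law
against membrane mechanics, or the effect sizes against real biology — those
are inputs, not findings.

## Numerical choices

- Direct dense solve (systems ≤ ~2·10³ nodes); no iterative tolerance.
- Permeability fit: bounded scalar least squares (`scipy.optimize.
  least_squares`, xtol = ftol = 1e-14) on k ∈ (0, 0.999·R²/8] (open-area
  fraction must stay < 1); predictions below 1e-18 m³/s at the initial k are
  declared non-identifiable.
- P–Q fit: per-pressure-level means, then ordinary least squares
  (`scipy.stats.linregress`); slope ≤ 0 flags a degenerate fit (resistance
  ∞) rather than raising.
- Strain inversion: Brent bracketing with geometric bracket growth.
- Problem sizes in the test suite (n = 64 segments, 200/100-seed Monte
  Carlo batches, 8-segment operating points inside fit loops) keep the whole
  suite near 10 s on one core while leaving all statistical criteria
  comfortably resolved.

## Known limitations

- No entrance/developing-flow or port/via losses; feed channels share the
  culture-well width. The ultrafiltration prediction inherits the
  undocumented feed geometry's uncertainty.
- Single-phase liquid only; the air–liquid-interface configuration's gas
  phase is out of scope, as is two-phase flow in channels.
- Membrane resistance ignores pore-entrance (orifice) corrections and
  cell-layer hydraulic resistance; with cells present the real
  ultrafiltration is lower.
- Strain analysis assumes the semi-ellipsoid shape and uniform bi-axial
  expansion; no comparison to uniaxial in-vivo strain figures is attempted.
- Pump dynamics, instrument drift and temperature dependence of viscosity
  are not modeled.
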