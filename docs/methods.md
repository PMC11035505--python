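# Methods

This note records the models, numerical choices and limitations behind
`nmdose`, in the order the pipeline uses them.

## Biokinetics

The whole-body kinetics of a radiopharmaceutical is a linear compartment
system dA/dt = M·A − λ<sub>p</sub>·A with unit activity injected into one
compartment at t = 0 (minutes post administration throughout; conversion
to hours happens only at reporting).  The solution is analytic: within
each inter-void segment the state is propagated with the matrix
exponential, and time integrals use the block-matrix identity
expm([[A, y₀],[0, 0]]·t) so that time-integrated activities carry no
quadrature error.  Degenerate transfer rates (repeated eigenvalues, the
t·e^(−λt) limit forms) are handled exactly by the matrix exponential
itself rather than by perturbing rates.

**Bladder.** Urinary excretion feeds a bladder compartment that is emptied
*completely and instantaneously* at each time of the voiding schedule.
Complete emptying is the conventional assumption and matches the sharp
drop of the cumulated dose-rate curve at the first void.  A schedule is
either an explicit time list or `(first_void, interval)`; a plain
"interval" regime has its first void at one interval (e.g. a 120-min
regime voids at 120, 240, … min).  Supported regimes of interest: 30 min
then hourly, 45 min then hourly, 120-min interval, 210-min interval (the
reference-model default).

**Transfer coefficients.** The bundled model files
(`data/biokinetics/*.json`) carry *representative* first-order
coefficients chosen to reproduce the qualitative behaviour of the standard
reference models — for the bone agent: fast blood clearance (T½ ≈ 40 min)
split ~45/35/20 between skeletal uptake (trapped), the renal–urinary path
and exchangeable soft tissue, giving ≈ 25–30% urinary excretion by 2 h;
for FDG: plasma clearance with metabolic trapping (brain ≈ 8% of the
administered activity) and renal excretion of the non-metabolised
fraction; for iodide: thyroid uptake ≈ 25% of cleared activity, renal
excretion, salivary/gastric secretion feeding a first-order gut chain
that terminates at the recto-sigmoid segment (faecal clearance is slow on
the few-day horizon of interest).  These files are *configuration, not
constants*: reference coefficient sets can be dropped in without touching
code, and all downstream machinery (curves, integrals, uncertainty) is
agnostic to them.

**Conservation.** Decay-corrected compartment content plus decay-corrected
voided activity equals the administered activity to better than 1e-9 at
all times (tested).

## Phantoms

The generator builds a stylized adult — tapered leg cylinders, an
elliptical-cylinder trunk, neck and ellipsoidal head — on a regular voxel
grid (default pitch 5 mm, a speed/fidelity compromise at desk scale).
Named organs are ellipsoids at fixed fractional coordinates (bladder low
and anterior in the pelvis, kidneys posterior at mid-trunk, thyroid
anterior in the neck, …) painted only over unassigned soft tissue, which
guarantees that organ label sets are disjoint and that organs plus
"Remainder" partition the body.  A simplified skeleton (spine, pelvic
ring, skull shell, leg bones) carries the "Bone" source region; "Blood"
is treated as a whole-body distributed source.  Four materials are used:
soft tissue (1.04 g/cm³), cortical bone (1.92), lung (0.26) and air.

Given a target height and mass, the transverse body dimensions are scaled
until the voxelized mass matches the request to < 1% (head size is held
fixed, so added mass thickens trunk and legs).  This reproduces the
morphological effect that matters here: in a fixed-height family spanning
≈ 50–85 kg, deep sources (bladder, kidneys) are buried under progressively
more tissue and their 1-m dose-rate factors fall monotonically with mass,
while the distributed "Remainder" factor is nearly mass-independent.

Conventions fixed once and exposed in code: chest height (the tally
height) is 0.75 of standing height; distances are skin-to-skin (or
skin-to-tally) along the horizontal line through the chest point; the
side-by-side counterpart is placed laterally facing the same direction.
A small seeded jitter (≤ 3 mm) on organ centres makes different seeds
distinct anatomies without changing the morphology statistics.

**What the synthetic bodies are not.**  They stand in for licensed
reference voxel phantoms; organ shapes, arm anatomy and posture are
simplified, so absolute per-organ factors should not be read as
reference-phantom replications.  The analyses built on them use ratios,
spreads, bounds and band coverage, which the stylized family supports.

## Photon transport

**Cross-sections.**  Interactions are photoelectric absorption and
incoherent scattering.  The incoherent channel is the exact free-electron
Klein–Nishina cross-section scaled by electron density; the photoelectric
channel is a two-branch power law τ/ρ = τ₄₀·(40 keV/E)^p (p = 3.8 below
40 keV, 3.0 above) anchored per material at 40 keV against standard
compilations.  Coherent scattering and binding effects are omitted; at the
bundled emission energies (80–723 keV plus 511 keV, with minor K x-rays
near 18–34 keV) the budget is Compton-dominated and the expected bias is
a few percent at most.  Building attenuation, collision-type sampling and
angular sampling from one cross-section model keeps the engine internally
consistent.  Photons below 15 keV are absorbed locally.

**Monte Carlo.**  Analog Woodcock (delta) tracking across the voxel grid;
Compton angles sampled by inverse-CDF table lookup (1024-point CDFs on a
160-node log energy grid).  Free-space tallies use a next-event
point-detector estimator: the expected fluence contribution at the tally
point is scored at the emission point and at every scatter vertex, with
the optical depth obtained by half-voxel-step ray marching through the
grid and ambient-air attenuation beyond the grid bounding box (air
*scatter* outside the grid is neglected; at 1 m this is a sub-percent
effect).  Fluence is converted with the bundled H\*(10)-per-fluence table
(log-log interpolation, exact at nodes, no extrapolation).  Organ doses in
an exposed counterpart phantom are analog energy depositions per organ
mass (collision kerma; no electron transport).  One seeded single-threaded
random stream per run: identical inputs and seed give bit-identical
tallies.  Statistical errors come from 25 history batches.

**Point kernel.**  The deterministic backend sums attenuated primary
fluence over source voxels with a Berger-form water buildup factor
B = 1 + a(E)·τ·e^{b(E)τ} evaluated at the ray's total optical depth.  It
is a fast cross-checked engine — it agrees with the Monte Carlo backend
to ~12% on the vial benchmark and is exact in the vacuum limit — not a
precision standard; it is the default for factor *tables* (many regions ×
many phantoms) where only ratios and spreads are consumed.

**Effective dose.**  E = Σ w<sub>T</sub>·½(D<sub>T,male</sub> +
D<sub>T,female</sub>) with the bundled weighting factors (sum exactly 1).
Tissues without a segmented organ fall back to the "Remainder" organ dose;
with a single synthetic counterpart anatomy the sex average is degenerate
and E reduces to the weighted organ-dose sum.

**Units.**  Engines produce per-emitted-particle (MC) or per-decay (point
kernel) quantities; the total photon yield converts between them and the
fixed factor 3.6e15 converts Sv/s/Bq to µSv/h/MBq.

## Reference vial

The device-intercomparison reference is a 50 mm × 20 mm cylinder with 1 mm
borosilicate walls, lower half filled with aqueous solution carrying the
activity, voxelized at 1 mm; fluence is scored at a free-in-air point
level with the vial centre (default 1 m) and converted as above.  With
4×10⁵ histories the next-event estimator reaches ≈ 0.1% statistical error
in seconds; the computed ⁹⁹ᵐTc value is ≈ 2.10e-02 µSv/h/MBq, where
attenuation in solution and glass (≈ −10%) and scatter buildup (≈ +7%)
nearly cancel against the bare-point value.

## Uncertainty model

Simulated-side: the GUM quadrature of the module docstring, with the
log-normal factor-2 biokinetic variability transformed at k = 2; the
a-terms therefore already embed the coverage factor and the 95% band is
value ± U(t).  Per-region factor uncertainties u(C) default to the
statistical error of the backend (overridable from configuration; a
multi-code spread can be supplied the same way).  Measured-side: device,
positioning and activity components combine in quadrature; the positioning
component follows the symmetrized inverse-square rule (±10 cm at 1 m
→ ±20%), and the three defaults (10%, 20%, 7.5%) combine to 24%.

## Synthetic measurements

The campaign generator draws reading times uniformly over the simulated
grid and applies, in order: a multiplicative device bias, inverse-square
jitter from a Gaussian positioning error, and relative Gaussian device
noise; readings are scaled by a configurable administered activity
(700 MBq default, a typical bone-scan administration).  It emulates the
*error structure* of a campaign, not its patient mix: real biokinetic
inter-patient variability is represented only through the factor-2 band on
the simulated side, so band-coverage tests verify the propagation
arithmetic, not patient realism.

## Problem sizes

Defaults used by the test suite and the acceptance script, chosen as the
package's standard desk-scale configuration: vial reference 4×10⁵
histories (≈ 0.1% SE); spectrum-sensitivity comparisons 1.2×10⁵ histories
per run with a shared seed so the full/simplified difference is strongly
correlated; morphology study: four phantoms at 5 mm pitch, point-kernel
factors for the four bone-scan source regions, 5-min time grid to 120 min.

## Known limitations

* No coherent scattering, electron/beta transport, or bremsstrahlung;
  doses are photon collision kerma.
* Stylized anatomy (see above); no arms, no posture variation, no
  pediatric or pregnant models.
* Ambient air outside the scene grid attenuates but does not scatter
  toward the detector.
* The point-kernel buildup is a water-based approximation applied to all
  tissues.
* Bundled biokinetic coefficients are representative defaults, not fits
  to any patient population.
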