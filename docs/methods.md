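# Methods

This note documents the model, its numerical choices and its limitations,
in the order the pipeline runs.

## Materials and stopping power

Every medium is described by mass density ρ (g cm⁻³), relative electron
density ρ_e, relative atomic-core density ρ_c (both water = 1) and an
effective (Z, A, M_A).  Four presets are shipped — water/tissue
(Z = 7.42, A = M_A = 13.37, chosen so Z/A matches water's electron
content), air (Z = 7.64) and cortical bone (Z = 13.8, ρ = 1.85,
ρ_e = 1.78) — and CT-like densities map to presets by thresholds
(≤ 0.05 g cm⁻³ air, ≥ 1.2 bone, else water-like).  ρ_c follows the ρ_e
convention: cores per volume relative to water, with water normalised to
N_A/M_A cores cm⁻³.

The mass collision stopping power of water is an embedded 17-point table
over 0.5–20 MeV with log-linear interpolation; energies below the floor
clamp to the floor value.  The CSDA range this table implies for 17.5 MeV
is ≈ 90 mm of water (collision-only; the radiative part is excluded
because bremsstrahlung is outside the model).  The mass scattering power
uses the ICRU small-angle form with the nuclear-size cutoff angle
θ_m = 2A^(−1/3)/(αβ(τ+1)) and screening angle
θ_μ = 1.130 αZ^(1/3)/(β(τ+1)), α = 1/137 exactly and the electron rest
energy 0.511 MeV.

## Phantoms and ray tracing

Voxel grids are axis-aligned, 0-based, half-open boxes in mm.  Ray tracing
is exact Siddon traversal; boundary ties advance along the dominant
direction cosine, making the traversal deterministic and reversible.
Radiological path length is geometric length × ρ_e.

Synthetic fixtures: a homogeneous water tank (the measurement tank's
entry wall is water-equivalent, so the volume is uniform water); water
with user-placed air/bone slabs; an air/bone checkerboard "sinus" pocket;
and an ellipsoidal head with a 5 mm skin shell, a bone shell beneath it
and a superficial spherical GTV (default 14 mm diameter at 15 mm depth —
the geometry targeted by this treatment technique is > 10 mm size at
< 36 mm depth).  These fixtures reproduce the *geometry and density
contrast* of the use case, not real anatomy: passing tests demonstrate
the engine's internal consistency and its printed-arithmetic anchors, not
clinical accuracy on patient CT data.

## Classical fluence

Each spot is a quasi-parallel elliptical Gaussian (σ_x = 3.8 mm,
σ_y = 5.4 mm, source-axis distance 10 m, initial angular spread zero).
The energy spectrum is a truncated Gaussian (peak 17.5 MeV, FWHM 0.3 MeV,
bounds 17–18 MeV) handled by transporting 3 sub-bins separately.

Along each ray the engine accumulates, at segment midpoints (midpoint
energy for second-order accuracy; verified to 1% against a 5 µm-step
oracle):

* θ̄²(z) = ∫T du and the moments M₀, M₁, M₂ of T, so that
  r̄²(z) = z²M₀ − 2zM₁ + M₂ is O(n) rather than O(n²);
* the CSDA energy E(z);
* φ_z(z) at radiological depth, with R_ex = 2.825(1+0.0714√S)E.

The elliptical incident beam and the isotropic r̄² formalism are
reconciled by giving each transverse axis half of the scattering
increment: var_axis(z) = σ_axis² + r̄²_add(z)/2, which reduces to the
scalar form in the symmetric limit.  Lateral Gaussians are looked up from
a bank quantised at 0.1 mm² of mean-square width.  The equivalent-square
field size S for R_ex is the FWHM-equivalent square of a single spot and
the bounding box (plus one spacing) of a scanned field — the quantity is
not otherwise defined for pencil beams, so this is a package choice.

The angular distribution φ_θ = (1/cos θ)(1/π θ̄²) exp(−θ²/θ̄²) is projected
onto the solver ordinates by binning a dense equal-area direction lattice
to its nearest ordinate and reweighting with the Gaussian.  This
conserves each ordinate's Voronoi mass; a midpoint rule misallocates up
to 20% of the forward weight when the spread is narrower than the 30°
ordinate spacing.  A zero spread is a delta on the most forward ordinate.

## Discrete ordinates solver

Ordinates come from a 30° gantry×couch lattice (polar × azimuth) with
pole duplicates merged — 62 directions — weighted by spherical patch
area (Σw = 4π exactly).  Energies are 1–18 MeV at 1 MeV.  The solver is
the classic source iteration: scatter source from the current total
fluence, diamond-difference upwind sweep per octant with vacuum
boundaries and zero fix-up (clamped negatives are counted), then re-add
the classical fluence, 10 iterations by default (the water-tank dose
changes < 0.5% between 10 and 20).

Cross sections are standard forms: relativistic Møller differential in
energy transfer, restricted to the scattered primary (outgoing energy
≥ T/2 — the faster of the two indistinguishable electrons; slower ejected
electrons are not transported because the *unrestricted* collision
stopping power already deposits their energy locally), with the
free-electron angle–energy relation cos²θ = E(T+2m)/(T(E+2m)) mapping
each ordinate pair to an initial energy ordinate (ties split 50/50); and
screened Rutherford/Mott with the spin factor and the screening angle θ_μ.
Scatter-out totals are accumulated from exactly the discrete scatter-in
coefficients, so particle balance holds to machine precision.

**Angular cutoff.**  Deflections below 35° stay in the classical channel.
The classical fluence already contains all multiple small-angle
scattering *and* its depth attenuation, and it is never depleted by the
solver, so a low cutoff double counts: at 15° the "scattered" channel
adds 20–33% of the integral dose, which is inconsistent with the few-%
depth-dose accuracy this class of engine achieves against measurement.
At 35° (just above the ordinate spacing) the large-angle correction is
4.4% of the integral dose, concentrated laterally and distally — the
intended role of the solver channel.  The cutoff is a configuration
parameter.

**Dual resolution.**  The classical fluence and its dose are evaluated on
the fine 1 mm grid (the adaptive mask flags voxels above 10⁻³ of the
incident-fluence maximum as fine); the scattered transport always runs on
the 4× volume-averaged coarse grid, and its dose is block-resampled to
fine and added.  The scattered component is smooth and small, so solving
it coarsely loses little while cutting the sweep cost by ~64×; a 100³
water tank solves end-to-end in well under a minute on one CPU.

Dose is D = Σ_e S(E_e) Σ_n Φ with the mass collision stopping power;
vacuum voxels score zero.  Monitor units: 1 MU ≡ 1 cGy at the depth of
maximum over a 100 × 100 mm scanned area (625 spots at 4 mm spacing), so
a single spot given 1 MU peaks at 6.25 Gy; the engine calibrates this on
a reference water tank per beam energy.  The calibration uses the
classical component; the solver's scattered addition (~4%) rides on top.

## Temporal model and FLASH

Timing defaults: 30 ps bunches, 1 µs intervals, 1000 bunches per train,
99 ms between trains (interpreted as the gap after a 1 ms train, a 10 Hz
cycle), 2×10¹² Gy s⁻¹ within a bunch.  One bunch per spot in raster
order; MU modulation is by bunch charge.  A voxel's delivery window runs
from the first to the last bunch contributing > 0.1% of its dose (so
Gaussian tails cannot stretch the window) plus one bunch length (so a
single-bunch voxel sees the instantaneous rate); the mean dose rate is
dose/window.  Per-spot kernels are rescaled voxelwise so their sum equals
the solver dose exactly — temporal bookkeeping never changes total dose.

The FLASH factor is the two-branch dose-rate activation (threshold
40 Gy s⁻¹, strength 0.4) times the dose response (thresholds 10/5/2 Gy and
magnitudes 0.4/0.5/0.6 for the weak/medium/strong scenarios), continuous
at both thresholds, bounded in [1−F_D, 1], and fixed at 1 inside the GTV.
Beams separated by more than ~0.1 s are biologically independent: the
model is applied per beam and the biological doses are summed.  The dose
entering the factor is the beam's total physical dose (spots within one
beam overlap within a train, so they share one delivery).

## Inverse planning

Spot lattices are 4 mm grids covering the GTV's beam's-eye-view
projection plus one spacing of margin; the beam energy is 0.4 × the
maximum radiological GTV depth, rounded to 0.5 MeV (machine limit
17.5 MeV).  Inside the loop the dose engine is the empirical depth-dose
curve D(z) = (z^0.1/(N+z^0.2)) e^(−μz)(1 − (z−R₅₀)/√(n^0.5+(z−R₅₀)²) + t)
with N = 15, μ = 0.001 mm⁻¹, n = 4000e, R₅₀ = 2.5e, t = 0, times the
incident Gaussian profile at all depths.  The update is a multiplicative
dose-ratio step (importance-weighted desired/delivered over each spot's
influence), clipped to [0.5, 2] per iteration; DVH and maximum-dose
objectives penalise only voxels above their level.  Objective voxels are
subsampled to ≤ 4000 per structure with a seeded generator; the per-beam
mean dose rate entering the biological objective is refreshed every 10
iterations.  200 iterations by default — the update converges slowly for
heavily overlapping kernels (spot FWHM ≈ 2× spacing), which is also why
weight *recovery* experiments need a few thousand iterations to reach 5%
RMS even though the *dose* residual drops below 1% within hundreds.

After optimisation the final dose is recomputed (surrogate or full
solver), and the weights are rescaled so the prescription covers 98% of
the GTV exactly — valid because the GTV is exempt from FLASH sparing, so
its biological dose is linear in the weights.  Plan statistics are
DVH-based (1000 bins): D98%/D2% by inverse DVH lookup (bin-limited; the
normalisation itself uses the exact quantile), V_dose in cm³, dose to the
hottest 0.035 cm³, and conformity index = isodose volume / GTV volume.

## Known limitations

* Bremsstrahlung is absent; the distal tail of φ_z plays its practical
  role in depth dose but is not a photon transport.
* The additive fixed-classical scheme cannot strictly conserve energy:
  the classical fluence is never depleted by large-angle events, so the
  solver channel's magnitude is controlled by the angular cutoff rather
  than derived.
* Dose is reported in water-like terms (fluence × mass collision stopping
  power of water scaled by density class); no spectrum-dependent
  stopping-power ratios.
* The head fixture is geometric, not anatomical; DVH statistics on it
  demonstrate mechanics, not clinical performance.
* Proton comparators (passive scattering, arcs) and photon robotic plans
  are out of scope; only their pulse-train arithmetic is representable
  via `PulseTrain` parameters.
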