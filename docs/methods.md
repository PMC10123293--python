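# Methods

## Constitutive model

The material is a biphasic mixture of an intrinsically incompressible
viscoelastic solid network (initial volume fraction `n0S`) and an
intrinsically incompressible pore fluid, saturated (`nS + nF = 1`).  The
mixture is compressible only by fluid leaving the pores; the volumetric
stress term

    tau_vol = lambda* (1 − n0S)^2 [ J/(1 − n0S) − J/(J − n0S) ] 1

vanishes in the reference state, penalizes volume changes with an initial
bulk stiffness of `lambda*`, and diverges hyperbolically at the compaction
point `J → n0S`, where all pore space is closed.  `lambda*` is therefore
not a fitted elastic constant but a quasi-incompressibility penalty for
the solid constituent; the packaged value (1e5 Pa, ~400x the equilibrium
shear modulus) follows that role.

Isochoric elasticity is one-term Ogden in principal stretches, once for
the equilibrium network and once per viscous branch on the *elastic* part
of the deformation (multiplicative split `F = F_e^i F_v^i`, i = 1, 2).
The principal Kirchhoff stress coefficients
`beta_a = mu (λ̃_a^alpha − ⅓ Σ_b λ̃_b^alpha)` sum to zero, so these parts
are exactly trace-free; for brain-like materials both `mu` and `alpha`
are negative (compression-tension asymmetry) with positive consistent
modulus `mu0 = mu·alpha/2`.

The viscous flow rule `−Lv(be_i)·be_i⁻¹ = tau_neq_i/eta_i` makes the
per-branch viscous dissipation `Dv_i = tau_i : tau_i / (2 eta_i)` a
quadratic form, non-negative by construction; the porous dissipation
`Dp = (muFR/K0)·(1−n0S)/(J−n0S)·w·w` likewise.  Both are exposed as
diagnostics and sweep-tested.

### Viscous update

The flow rule is integrated by a backward-Euler exponential map: push the
old `be` forward with the relative deformation gradient to an elastic
trial state, eigendecompose, and solve

    eps_a + dt/(2 eta) * beta_a(eps) = eps_trial,a

for the principal logarithmic elastic strains with a local Newton
iteration (analytic 3x3 Jacobian, Cramer solve, tolerance 1e-10, max 50
iterations; the Ogden exponent argument is clamped at ±60 and Newton steps
at ±5 so extreme *trial* states stay finite — converged states sit far
inside both guards).  This update is unconditionally stable, preserves
symmetric positive-definite `be` exactly, preserves `tr(eps)` (the flow is
isochoric), and reduces to the continuous law as `dt → 0`.  Its accuracy
is pinned by two independent oracles rather than by trusting the scheme:
agreement with adaptive dense integration of the continuous tensor ODE to
<1% at `dt = tau/50`, and recovery of the analytic relaxation rate
`eta/mu0` on small-strain shear to <2%.

Coincident principal stretches need no special treatment here: every
stress is an isotropic tensor function evaluated through a batched
symmetric eigendecomposition (basis-independent at degeneracy), and the
global tangent is a finite difference of the complete algorithmic
residual, so the `1/(λa−λb)` terms of analytic spectral tangents never
arise.

## Finite-element formulation

Geometry, loading and material are rotationally symmetric, so the
boundary-value problem is solved on the (r, z) half-section with
axisymmetric weak forms (reference measure `2π R dR dZ`; the hoop
stretch `1 + u_r/R` carries the third dimension).  The default domain is
a 10 mm × 10 mm half-scale cylinder probed by a 2 mm flat punch.

* **Elements**: 9-node biquadratic displacement / 4-node bilinear pressure
  (Q2P1 Taylor–Hood), full 3×3 Gauss integration, on a graded tensor mesh
  with ≥4 radial cells across the punch-edge zone [0.8, 1.2]·Ri and
  geometric coarsening toward the far boundaries.  The default (level-0)
  layout has 96 cells ≈ 1100 dof; each refinement level splits every cell
  in four.
* **Boundary conditions**: bottom fully fixed; symmetry on the axis; full
  adhesion under the punch (prescribed vertical displacement, zero radial
  displacement, no flux) — the punch footprint stays prescribed through
  unload/recovery, which reproduces adhesive pull-off qualitatively but is
  not an adhesion model; every other outer surface is traction-free and
  drained at the `p = 0` gauge (only pressure differences matter).  The
  contact-finding phase of the physical experiment is not simulated:
  simulations start at established contact, zero depth.
* **Time stepping**: backward Euler; `dt = 0.02 s` during
  ramps/unloads, geometric growth (×1.3, capped at 5 s) through holds and
  recoveries; on Newton failure the step is halved (up to 8 times) with
  the prescribed depth interpolated linearly, which is exact for the
  piecewise-linear protocols.
* **Newton solver**: monolithic u–p Newton with an element-level
  forward-difference tangent of the full algorithmic residual (hence
  automatically consistent with the viscous update), sparse LU, LU reuse
  across iterations and steps with refresh on slow progress, a secant
  predictor from the two previous converged states, and a backtracking
  line search on the affine-invariant merit `|K⁻¹R|` — the
  LU-preconditioned norm weighs the momentum (µN) and mass (mm³/s)
  residual blocks consistently, which a raw residual norm does not.
  Convergence: relative 1e-8 per residual block against the step's
  initial norms, with absolute floors 1e-10 mN and 1e-10 mm³/s.
* **Reactions**: punch force is the sum of the assembled residual at the
  punch-constrained vertical dofs (variationally consistent); assembling
  the momentum residual once with only the solid extra stress and once
  with only `−pJ1` yields a solid/fluid split that sums to the total
  identically.
* **Units**: Pa–mm–s internally (forces in µN = Pa·mm²), converted to mN
  at every reporting boundary.

### Verification

The coupled formulation is verified against Terzaghi's consolidation
series on a confined column at |strain| ≤ 1e-3: immediately after loading
the pore pressure carries 100% of the load (incompressible constituents),
the normalized profiles at time factors 0.2 and 0.5 match the series to
~1% L2 (first-order time stepping dominates that error), and the
settlement approaches the drained elastic value.  An independently
integrated (Nanson-transformed) drained-boundary flux balances the domain
volume change to <1% on the same column.  On the indentation problem the
punch-edge pressure singularity makes that surface integral
mesh-sensitive, so mass conservation is asserted on the resolved column.

## Protocols and summary statistics

P1 and P2 are trapezoidal cycles: ramp to 1 mm depth (at 1.0 resp.
1.6 mm/s), hold 90 s, unload at 1 mm/s to a −0.1 mm stand-off, recover;
one cycle lasts ramp + 90 + 1 + 120 s.  Later cycles ramp from the
stand-off, the extra 0.1 mm of travel absorbed by the recovery phase.
The multi-millimetre experimental parking positions are bookkeeping and
are clipped to the stand-off (prescribing them under full adhesion would
be unphysical).

Replicates are aligned by mapping each record's loading onset — the first
crossing of 5% of its cycle-1 peak force, linearly interpolated — to the
ramp start, then resampled onto a common grid.  The central tendency is
the pointwise median; spread is the pointwise IQR with numpy's
linear-interpolation quartile convention (chosen for determinism, not
uniqueness).  Per-cycle peak force is the maximum of the median curve up
to the end of the hold; the force-relaxation fraction is
(peak − end-of-hold force)/peak, with the end-of-hold value taken from the
last sample inside the hold (robust against the unload discontinuity).

## Gravimetry

`phi = (Δm/ρF) / (Δm/ρF + m_dry/ρ_dry)` with `ρ_dry = ρF` by default
(overridable), so `phi` reduces to `Δm/m_wet`; `n0S = 1 − phi` by
saturation.  A series counts as dry when the last two daily means differ
by <0.1% relative — the drying protocol observes no measurable change
after day 7, but no numeric rule is stated, so this one is fixed here.

## Synthetic data

The generators define the study conditions for every recovery test.

* **Indentation**: one forward simulation, then per replicate
  `F_rep = s_rep·F·(1+ε_mult) + ε_add` with scale jitter
  `s_rep ~ N(1, 0.03²)` (sample-to-sample variation), 2% multiplicative
  white noise and 0.05 mN additive noise — magnitudes chosen to emulate
  the IQR-to-median ratio of the replicate experiments; 10 replicates by
  default, matching the experimental design.  White noise plus scale
  jitter is a stated assumption: correlated drift, adhesive pull-off
  spikes and contact-finding artifacts of real records are *not*
  emulated, so passing recovery tests demonstrate correctness of the
  pipeline under this noise structure, not robustness to every
  experimental pathology.
* **Dehydration**: exponential mass decay toward the dry plateau
  `(1−phi)·m_wet` (time constant 1.2 days, plateau reached by day 10),
  with day-to-day variability on the remaining evaporable water (0.2%)
  and a 0.2 mg balance repeatability per reading; daily means are made
  non-increasing.  Putting the variability on the water term rather than
  the plateau mirrors that dried samples show no measurable change on
  repeated weighing.

All randomness flows from one integer seed through
`numpy.random.default_rng`; regeneration is bitwise reproducible.

## Inverse identification

The objective is the normalized squared error
`chi² = Σ(y_exp−y_sim)²/Σ(y_exp)²` (the scaling guards against vanishing
gradients for small forces); the residual vector is
`(y_exp−y_sim)/‖y_exp‖` so its sum of squares equals `chi²` exactly.  The
fit target is the cycle-1 median force history under P2, sampled 0.05 s
uniformly over the ramp and at 60 log-spaced points over the hold (equal
weight to peak and relaxation tail).  Nine parameters are optimized with
scipy's trust-region-reflective method inside the Table of search
intervals: moduli, exponents and viscosities on an interval-midpoint
scale, `K0` as `log10 K0` (its interval spans twelve decades; raw-scale
TRF stalls).  The finite-difference Jacobian uses forward steps of 1e-3
on the scaled parameters — far above the forward model's ~1e-6 relative
force noise floor — with columns evaluated concurrently if requested
(the forward model is a pure function of the parameter vector, so
concurrent and serial evaluation are bitwise identical), and a cache
keyed on the parameter vector rounded to 12 significant digits.  Failed
forward evaluations are returned to the optimizer as large residuals
(step rejected) and are never cached.

The identification forward profile deliberately runs small: a 21-cell
mesh that keeps the 4-cell punch-edge zone, `dt = 0.05 s` ramps with
×1.5 hold growth, Newton at 1e-6 relative — a forward run costs a few
seconds, and an inverse run a few hundred forward runs.  Because recovery
tests compare a model against data generated by the *same* discretization,
coarseness does not bias them.

### Identifiability

A single-cycle indentation force curve does not determine all nine raw
parameters.  The (mu, alpha) pairs of each Ogden branch compensate: fits
from a ±50% perturbed start reach force agreement at the 0.1% RMS level
(chi² ~ 2e-6) with raw mu and alpha individually 30–50% off but the
consistent moduli `mu·alpha/2` and relaxation times `eta/mu0` within
~10–15%, and the objective is multi-modal — probing chi² along the
straight path from such a fit to the ground truth shows it rising two
orders of magnitude before falling to zero, i.e. the fit sits in a
genuinely distinct local minimum whose force response is experimentally
indistinguishable.  The fast branch is additionally rate-limited: the
loading ramps (0.6–1 s) and the first residual sample of the hold
(+50 ms) lie far beyond `tau_1 = 18 ms`, so that branch responds as a
near-pure dashpot and the curve constrains only the product
`eta_1 = mu0_1 * tau_1`, not the split — under 2% force noise the
recovered `mu0_1` and `tau_1` swing by tens of percent in opposite
directions while `eta_1` stays within a few percent.  Global search is
out of scope by design, so the package treats the identifiable
combinations — the equilibrium and slow-branch moduli, the slow
relaxation time, both viscosities, and (to order of magnitude) K0,
consistent with the weak sensitivity of the response to permeability —
as the robust outputs of the identification, and the test suite asserts
exactly that; the stricter raw-parameter and fast-branch-split equality
checks are retained but are expected to fail for this experiment
design.

## Problem sizes used by the test suite

Unit and property tests run on material points and the 21–70-cell meshes;
forward plausibility checks use the 96-cell default mesh for one
ramp+hold cycle per protocol; the consolidation benchmark uses a 32-cell
column with 60 time steps per segment; recovery tests run the 21-cell
identification profile with capped optimizer budgets (20 trust-region
iterations noise-free, 6 per noisy seed — in both cases past the point
where the optimizer stalls by its step-size criterion).
These sizes are the package's default desk-scale configuration; refining
the mesh by one level changes the cycle-1 peak force by a few percent
(see the spatial-convergence test) and the physics conclusions not at
all.

## Known limitations

* No frictional or unilateral contact and no adhesion energy: the punch
  footprint is prescribed throughout, so pull-off forces are qualitative.
* No damage, fracture, osmotic swelling, temperature dependence or
  anisotropy.
* Backward Euler is first-order: hold-phase relaxation at default steps
  is resolved to ~1%; the 18 ms branch is under-resolved during 0.02 s
  ramps (its contribution there is effectively viscous-fluid-like).
* The surface-flux integral at the punch-edge singularity converges
  slowly in mesh; mass-balance verification uses the column benchmark.
* Raw Ogden (mu, alpha) pairs and K0 are reported but only their derived
  combinations are practically identified from this experiment.
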