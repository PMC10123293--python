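# poroindent

Finite-strain poro-viscoelastic characterization of soft hydrated
materials by flat-punch indentation.

Brain-tissue-mimicking hydrogels (and brain tissue itself) relax under
load through two distinct mechanisms: intrinsic viscoelastic relaxation of
the polymer network, and migration of pore water through the network.
`poroindent` implements the full characterization pipeline for such
materials:

* a **biphasic Ogden-type material law** in the Theory of Porous Media —
  an incompressible solid network and an incompressible pore fluid whose
  volume fractions satisfy the saturation condition `nS + nF = 1`;
* an **axisymmetric coupled displacement–pore-pressure (u–p) finite-element
  solver** for flat-punch indentation with Taylor–Hood (Q2P1) elements;
* the **indentation loading protocols**, force-record handling and the
  median/IQR summary statistics used to compare curves;
* **gravimetric water-content** analysis feeding the initial solid volume
  fraction;
* **synthetic-data generators** so every stage is testable from a known
  ground truth; and
* an **inverse identification scheme** (bounded trust-region-reflective
  least squares with a cached, parallelizable finite-difference Jacobian)
  for the nine fitted material parameters.

## The model

The Kirchhoff stress splits into equilibrium, non-equilibrium, volumetric
and pore-pressure parts,

    tau = tau_eq + sum_i tau_neq_i + tau_vol − p J 1 ,

with one-term Ogden branches evaluated on isochoric principal stretches
(`beta_a = mu (λ̃_a^alpha − ⅓ Σ_b λ̃_b^alpha)`), a volumetric term
`lambda* (1−n0S)² [J/(1−n0S) − J/(J−n0S)] 1` that diverges at the
compaction point `J → n0S`, and two viscous branches whose elastic left
Cauchy–Green tensors evolve by

    −Lv(be_i) · be_i⁻¹ = tau_neq_i / eta_i .

Pore-fluid seepage follows a Darcy-like law
`w = −(K0/muFR) (J−n0S)/(1−n0S) ∇p`, and the weak forms of momentum and
mass balance are solved monolithically with backward-Euler time stepping.
The consistent small-strain shear modulus of each Ogden branch is
`mu0 = mu·alpha/2`; branch relaxation times are `tau_i = eta_i/mu0_i`;
hydraulic conductivity is `k = K0·rhoF·g/muFR`.

## Worked example

```sh
python examples/01_derived_quantities.py
```

prints, for the packaged hydrogel parameter set:

```
equilibrium shear modulus  mu0_eq :   234.36 Pa
branch-1 shear modulus     mu0_1  :   2821.5 Pa
branch-2 shear modulus     mu0_2  :   239.09 Pa
instantaneous modulus      sum    :   3294.9 Pa
relaxation time            tau_1  :   0.0179 s
relaxation time            tau_2  :    19.57 s
hydraulic conductivity     k      : 2.54e-08 m/s
```

The gel is ~235 Pa soft at equilibrium but an order of magnitude stiffer
on impact; the two relaxation times separate the fast network response
(~18 ms) from the slow conformational relaxation (~20 s), and `k` sets
the time scale of pressure-driven water migration.

A forward indentation simulation (`examples/03_flat_punch_indentation.py`,
protocol P2: 1 mm depth at 1.6 mm/s with a 2 mm punch, 90 s hold, coarse
mesh) prints

```
mesh: 96 Q2P1 cells
peak force:         12.54 mN at t = 0.625 s
  solid part:        6.88 mN
  fluid part:        5.66 mN
end-of-hold force:   5.43 mN
force relaxation:   56.7 %
```

— at the peak the pore pressure carries almost half the load; within
seconds of the hold the fluid has redistributed and the remaining decay is
viscoelastic.

Other examples: a material-point relaxation experiment, water-content
analysis, a Terzaghi-consolidation verification of the coupled solver, and
a short inverse-identification demo.  A thin CLI wraps the same library
calls (`poroindent simulate|simulate-point|fit|watercontent|synth ...`).

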