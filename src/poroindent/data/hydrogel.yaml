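# Reference poro-viscoelastic parameter set for the brain-tissue-mimicking
# PVA/Phytagel composite hydrogel, identified from flat-punch indentation.
# Units: mu_*, lambda_star in Pa; eta_* , muFR in Pa*s; K0 in mm^2; alpha_*, n0S dimensionless.
solid:
  mu_inf: -217.0
  alpha_inf: -2.16
  branches:
    - {mu: -418.0, alpha: -13.5, eta: 50.6}
    - {mu: -161.0, alpha: -2.97, eta: 4680.0}
  lambda_star: 1.0e+5
  n0S: 0.032
fluid:
  muFR: 0.89e-3
  K0: 2.30e-9
bounds:
  mu_inf: [-1000.0, -1.0]
  mu_1: [-1000.0, -1.0]
  mu_2: [-1000.0, -1.0]
  alpha_inf: [-30.0, -1.0]
  alpha_1: [-30.0, -1.0]
  alpha_2: [-30.0, -1.0]
  eta_1: [1.0, 1.0e+5]
  eta_2: [1.0, 1.0e+5]
  K0: [1.0e-14, 1.0e-2]
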