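"""Engineering quantities of the identified hydrogel parameter set.

Converts the raw Ogden/fluid parameters (shear-like moduli mu, exponents
alpha, dashpot viscosities eta, intrinsic permeability K0) into the
quantities usually quoted: consistent shear moduli mu0 = mu*alpha/2,
relaxation times tau = eta/mu0, and hydraulic conductivity
k = K0 rhoF g / muFR.
"""

from poroindent import derived_quantities, hydrogel_parameters

params = hydrogel_parameters()
d = derived_quantities(params)

print("equilibrium shear modulus  mu0_eq :", f"{d.mu0_eq:8.2f} Pa")
print("branch-1 shear modulus     mu0_1  :", f"{d.mu0_neq[0]:8.1f} Pa")
print("branch-2 shear modulus     mu0_2  :", f"{d.mu0_neq[1]:8.2f} Pa")
print("instantaneous modulus      sum    :", f"{d.mu0_instantaneous:8.1f} Pa")
print("relaxation time            tau_1  :", f"{d.tau_relax[0]:8.4f} s")
print("relaxation time            tau_2  :", f"{d.tau_relax[1]:8.2f} s")
print("hydraulic conductivity     k      :", f"{d.k_hydraulic:.3g} m/s")
print()
print("tau_1 ~ 18 ms governs the short-term (impact-like) response; "
      "tau_2 ~ 20 s the slow hold relaxation; k sets how fast pore water "
      "escapes the network.")
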