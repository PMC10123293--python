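"""Verification of the coupled solver against Terzaghi consolidation.

Runs a confined-compression column with a drained top under a small
vertical load and compares the computed pore-pressure profiles with the
classical series solution.  Takes ~20 s.
"""

from poroindent.benchmark import terzaghi_benchmark

res = terzaghi_benchmark(time_factors=(0.2, 0.5))

print(f"consolidation coefficient cv = {res.cv:.4g} mm^2/s")
print(f"undrained core pressure / load = {res.p_undrained_core:.4f} "
      "(expected ~1: incompressible constituents)")
for tf in res.time_factors:
    print(f"time factor Tv = {tf}: relative L2 mismatch vs series = "
          f"{res.l2_errors[tf] * 100:.2f} %")
print(f"settlement at Tv=0.5: {res.settlement['Tv=0.5'] * 1e3:.3f} um "
      f"(drained limit {res.settlement['drained_exact'] * 1e3:.3f} um)")
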