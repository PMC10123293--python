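"""Equilibrium water content from a (synthetic) dehydration series.

Generates a gravimetric table with ground-truth water volume fraction
phi = 0.968, runs it through the gravimetry pipeline and reports the
pooled water content and the solid fraction n0S = 1 - phi that feeds the
biphasic model.
"""

import tempfile
from pathlib import Path

from poroindent.gravimetry import (
    pooled_water_content,
    read_gravimetric_csv,
    solid_fraction,
    water_volume_fraction,
)
from poroindent.synthetic import generate_dehydration

path = Path(tempfile.mkdtemp()) / "dehydration.csv"
generate_dehydration(phi_true=0.968, n_samples=6, seed=1, path=path)

samples = read_gravimetric_csv(path)
for s in samples:
    print(f"sample {s.sample_id}: m_wet {s.m_wet:7.3f} g, "
          f"m_dry {s.m_dry:6.4f} g, phi {water_volume_fraction(s):.4f}")
mean, sd = pooled_water_content(samples)
print(f"\npooled water volume fraction: {mean:.4f} +/- {sd:.4f}")
print(f"solid volume fraction n0S:    {solid_fraction(mean):.4f}")
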