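"""Equilibrium water content from gravimetric dehydration series.

Hydrogel discs are weighed fully swollen (``m_wet``) and then daily during
ambient dehydration until the mass plateaus.  The water volume fraction is

    phi = (dm/rhoF) / (dm/rhoF + m_dry/rho_dry),     dm = m_wet - m_dry,

which with the usual assumption ``rho_dry ~= rhoF`` reduces to
``dm / m_wet``.  The saturation condition of a biphasic mixture then gives
the initial solid volume fraction ``n0S = 1 - phi`` that feeds the
poro-viscoelastic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: relative tolerance on the last two daily means for "dry" convergence
DRY_CONVERGENCE_RTOL = 1.0e-3


class NotEquilibratedError(ValueError):
    """Raised when a dehydration series has not reached constant mass."""


@dataclass(frozen=True)
class GravimetricSample:
    """Wet mass plus the daily dry-mass series (triplicate means) [g]."""

    sample_id: str
    m_wet: float
    m_dry_series: np.ndarray
    rho_F: float = 1.0    # g/cm^3, deionized water
    rho_dry: float = 1.0  # g/cm^3, dry-gel density ~ rho_F by assumption

    def __post_init__(self) -> None:
        m = np.asarray(self.m_dry_series, dtype=float)
        if len(m) < 2:
            raise ValueError("need at least two daily dry masses")
        if np.any(m <= 0) or self.m_wet <= 0:
            raise ValueError("masses must be positive")
        if np.any(m > self.m_wet * (1 + 1e-9)):
            raise ValueError("dry masses cannot exceed the wet mass")
        if self.rho_F <= 0 or self.rho_dry <= 0:
            raise ValueError("densities must be positive")

    @property
    def m_dry(self) -> float:
        """Final (converged) dry mass [g]."""
        return float(np.asarray(self.m_dry_series)[-1])

    def is_converged(self) -> bool:
        m = np.asarray(self.m_dry_series, dtype=float)
        return abs(m[-1] - m[-2]) <= DRY_CONVERGENCE_RTOL * m[-2]


def water_volume_fraction(sample: GravimetricSample) -> float:
    """Equilibrium water volume fraction phi of one sample.

    Raises
    ------
    NotEquilibratedError
        if the last two daily masses differ by more than 0.1% relative.
    """
    if not sample.is_converged():
        m = sample.m_dry_series
        raise NotEquilibratedError(
            f"sample {sample.sample_id}: dehydration not converged "
            f"(last masses {m[-2]:.6g} -> {m[-1]:.6g} g)")
    dm = sample.m_wet - sample.m_dry
    vol_f = dm / sample.rho_F
    vol_s = sample.m_dry / sample.rho_dry
    return vol_f / (vol_f + vol_s)


def solid_fraction(phi: float) -> float:
    """Initial solid volume fraction from saturation: n0S = 1 - phi."""
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi = {phi:g} outside [0, 1)")
    return 1.0 - phi


def read_gravimetric_csv(path: str | Path,
                         rho_F: float = 1.0,
                         rho_dry: float = 1.0) -> list[GravimetricSample]:
    """Read a dehydration table (sample_id, day, mass_g, replicate).

    Day 0 is the equilibrated wet weighing; replicates are averaged per
    day.
    """
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "day", "mass_g"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=True):
        daily = grp.groupby("day", sort=True)["mass_g"].mean()
        if 0 not in daily.index:
            raise ValueError(f"{path}: sample {sid} lacks a day-0 wet mass")
        samples.append(GravimetricSample(
            sample_id=str(sid),
            m_wet=float(daily.loc[0]),
            m_dry_series=daily.loc[daily.index > 0].to_numpy(),
            rho_F=rho_F, rho_dry=rho_dry,
        ))
    return samples


def pooled_water_content(samples: list[GravimetricSample]
                         ) -> tuple[float, float]:
    """(mean, SD) of phi across samples."""
    phis = np.array([water_volume_fraction(s) for s in samples])
    return float(phis.mean()), float(phis.std(ddof=1)) if len(phis) > 1 else 0.0
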