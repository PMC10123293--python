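"""Synthetic datasets with the statistical structure of the indentation
and dehydration experiments.

The generators exist so the full pipeline — alignment, summary statistics,
gravimetry, inverse identification — is testable end-to-end from a known
ground truth.  Replicate spread emulates what the experimental
interquartile range shows: a per-replicate scale jitter (sample-to-sample
variation), multiplicative white noise (force-proportional sensor/contact
noise) and additive white noise (load-cell floor).  Correlated drift and
adhesive pull-off spikes of real records are deliberately not modeled.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; regeneration with the same provenance is
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fem import SimulationResult, SolverSettings, run_protocol
from .identification import fit_mesh, fit_settings
from .materials import MaterialParameters
from .mesh import Geometry, Mesh
from .protocols import ForceRecord, IndentationProtocol


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise structure for synthetic force records.

    ``multiplicative`` and ``jitter`` are fractions; ``additive`` in mN.
    Defaults emulate the replicate spread (IQR-to-median ratio) of the
    hydrogel indentation experiments.
    """

    multiplicative: float = 0.02
    additive: float = 0.05
    jitter: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.multiplicative, self.additive, self.jitter) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class SyntheticDataset:
    """Replicated noisy force records plus their noiseless ground truth."""

    params_true: MaterialParameters
    protocol: IndentationProtocol
    records: list[ForceRecord]
    truth: ForceRecord
    simulation: SimulationResult
    provenance: dict = field(default_factory=dict)


def generate_indentation(params_true: MaterialParameters,
                         protocol: IndentationProtocol,
                         n_replicates: int = 10,
                         noise: NoiseModel | None = None,
                         mesh: Mesh | None = None,
                         settings: SolverSettings | None = None,
                         geometry: Geometry | None = None,
                         t_end: float | None = None,
                         sample_dt: float = 0.05) -> SyntheticDataset:
    """One forward simulation, then per-replicate perturbation

        F_rep(t) = s_rep * F(t) * (1 + eps_mult(t)) + eps_add(t),

    with s_rep ~ N(1, jitter^2) and white Gaussian eps terms."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    noise = noise or NoiseModel()
    mesh = mesh if mesh is not None else fit_mesh(geometry)
    settings = settings or fit_settings()
    sim = run_protocol(protocol, params_true, settings=settings, mesh=mesh,
                       geometry=geometry, t_end=t_end, diagnostics=False)
    t_stop = sim.t[-1]
    grid = np.arange(0.0, t_stop + 0.5 * sample_dt, sample_dt)
    F = np.interp(grid, sim.t, sim.force)
    u = np.interp(grid, sim.t, sim.depth)

    rng = np.random.default_rng(noise.seed)
    records = []
    for k in range(n_replicates):
        s = 1.0 + noise.jitter * rng.standard_normal()
        em = noise.multiplicative * rng.standard_normal(len(grid))
        ea = noise.additive * rng.standard_normal(len(grid))
        records.append(ForceRecord(
            replicate_id=f"synthetic_rep{k:02d}",
            protocol_id=protocol.name,
            t=grid.copy(), u=u.copy(), F=s * F * (1.0 + em) + ea,
        ))
    truth = ForceRecord(replicate_id="synthetic_truth",
                        protocol_id=protocol.name,
                        t=grid.copy(), u=u.copy(), F=F.copy())
    return SyntheticDataset(
        params_true=params_true, protocol=protocol, records=records,
        truth=truth, simulation=sim,
        provenance={
            "seed": noise.seed, "n_replicates": n_replicates,
            "noise": {"multiplicative": noise.multiplicative,
                      "additive": noise.additive, "jitter": noise.jitter},
            "protocol": protocol.name, "mesh_cells": mesh.n_cells,
            "sample_dt": sample_dt, "t_end": t_end,
        },
    )


def generate_dehydration(phi_true: float = 0.968,
                         n_samples: int = 6,
                         days: int = 14,
                         mass_scale: float = 25.0,
                         noise_sd: float = 0.002,
                         balance_sd: float = 2.0e-4,
                         seed: int = 0,
                         drying_time_days: float = 1.2,
                         path: str | Path | None = None) -> "pd.DataFrame":
    """Synthetic dehydration table (sample_id, day, mass_g, replicate).

    Mass decays exponentially from the wet mass toward the dry plateau
    ``(1 - phi_true) * m_wet`` with time constant ``drying_time_days``, so
    the series is stable well before day 14 and the 0.1%-relative
    convergence rule holds.  ``noise_sd`` is the relative day-to-day
    variability of the *remaining evaporable water* (ambient humidity and
    handling); ``balance_sd`` [g] is the per-reading weighing repeatability.
    At the dry plateau the water term vanishes, so repeated weighings
    scatter only by the balance floor — matching that no weight change is
    measurable once a sample is dry.  Daily means are made non-increasing
    (a drying sample never gains mass at the reported precision).
    """
    import pandas as pd

    if not 0.0 < phi_true < 1.0:
        raise ValueError("phi_true must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_samples):
        m_wet = mass_scale * (1.0 + 0.05 * rng.standard_normal())
        m_dry = (1.0 - phi_true) * m_wet
        day_means = []
        # exponential decay shifted to reach the plateau exactly by dry_day
        dry_day = min(10, days)
        e_end = np.exp(-dry_day / drying_time_days)
        for d in range(0, days + 1):
            frac = max(0.0, (np.exp(-d / drying_time_days) - e_end)
                       / (1.0 - e_end)) if d < dry_day else 0.0
            water = (m_wet - m_dry) * frac
            if d > 0:
                water *= 1.0 + noise_sd * rng.standard_normal()
            reps = m_dry + water + balance_sd * rng.standard_normal(3)
            day_means.append((d, reps))
        # enforce non-increasing daily means while keeping replicate spread
        means = np.array([r.mean() for _, r in day_means])
        floor = np.minimum.accumulate(means)
        for (d, reps), mu, lo in zip(day_means, means, floor):
            reps = reps + (lo - mu)
            for j, m in enumerate(reps):
                rows.append({"sample_id": f"S{s + 1}", "day": d,
                             "mass_g": float(m), "replicate": j + 1})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
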