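"""Verification oracle for the coupled solver: Terzaghi 1D consolidation.

A fluid-saturated column under a suddenly applied vertical load with a
drained top and impermeable base develops an excess pore pressure equal to
the load (incompressible constituents), which then decays by seepage.  In
the small-strain limit the normalized pressure follows the classical
series

    p(z, Tv)/p0 = sum_m 4/(pi (2m+1)) sin((2m+1) pi z / (2H))
                  exp(-(2m+1)^2 pi^2 Tv / 4),

with z measured from the drained face, H the drainage path and
Tv = cv t / H^2 the time factor built from the consolidation coefficient
cv = (K0/muFR) (lambda* + 4G/3).  Agreement of the nonlinear coupled
solver (run at |strain| <= 1e-3) with this closed form verifies the
discrete mass balance, the Darcy term and the u-p coupling independently
of the indentation problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import (
    FESystem,
    BoundaryConditions,
    SolverSettings,
    _GW,
    _lag2,
)
from .materials import MaterialParameters, OgdenBranch, ViscousBranch
from .mesh import Mesh, build_column_mesh


def terzaghi_pressure(z_over_H: np.ndarray, Tv: float,
                      n_terms: int = 200) -> np.ndarray:
    """Series solution p/p0; ``z_over_H`` measured from the drained face."""
    z = np.asarray(z_over_H, dtype=float)
    out = np.zeros_like(z)
    for m in range(n_terms):
        k = 2 * m + 1
        out += (4.0 / (np.pi * k) * np.sin(k * np.pi * z / 2.0)
                * np.exp(-k**2 * np.pi**2 * Tv / 4.0))
    return out


def linearized_params(G_eq: float = 234.36, lambda_star: float = 1.0e5,
                      n0S: float = 0.032, muFR: float = 0.89e-3,
                      K0: float = 1.775e-10) -> MaterialParameters:
    """Near-linear material for the benchmark: equilibrium Ogden network
    with consistent shear modulus ``G_eq`` and vanishingly soft viscous
    branches (so the solid is effectively elastic)."""
    alpha = -2.0
    return MaterialParameters(
        eq=OgdenBranch(mu=-G_eq, alpha=alpha),
        neq=(
            ViscousBranch(OgdenBranch(mu=-1.0e-3, alpha=-1.0), eta=1.0),
            ViscousBranch(OgdenBranch(mu=-1.0e-3, alpha=-1.0), eta=1.0),
        ),
        lambda_star=lambda_star, n0S=n0S, muFR=muFR, K0=K0,
    )


def _column_bcs(mesh: Mesh, load: float) -> BoundaryConditions:
    """Confined compression: rollers on all lateral surfaces and the base,
    uniform vertical traction on the (drained) top."""
    ru, zu = mesh.nodes_u[:, 0], mesh.nodes_u[:, 1]
    rp, zp = mesh.nodes_p[:, 0], mesh.nodes_p[:, 1]
    H = mesh.z_breaks[-1]
    R = mesh.r_breaks[-1]
    tol = 1e-9
    ndof_u = 2 * len(ru)

    bottom = np.nonzero(zu < tol)[0]
    sides = np.nonzero((ru < tol) | (ru > R - tol))[0]
    zero = np.concatenate([2 * bottom + 1, 2 * sides])
    drained = np.nonzero(zp > H - tol)[0] + ndof_u

    # consistent nodal loads on the top edge (reference configuration)
    f_ext = np.zeros(ndof_u + len(rp))
    nr = len(mesh.r_breaks) - 1
    nz = len(mesh.z_breaks) - 1
    dr = np.diff(mesh.r_breaks)
    gp = np.sqrt(3.0 / 5.0) * np.array([-1.0, 0.0, 1.0])
    ev, _ = _lag2(gp)
    for i in range(nr):
        c = (nz - 1) * nr + i
        top_nodes = mesh.conn_u[c, 6:9]  # local dj = 2 row
        r0 = mesh.r_breaks[i] + dr[i] / 2.0 * (1.0 + gp)
        for a_local, node in enumerate(top_nodes):
            w = np.sum(_GW * ev[a_local] * 2.0 * np.pi * r0) * dr[i] / 2.0
            f_ext[2 * node + 1] -= load * w  # downward [uN]
    facets = {"top_drained": [((nz - 1) * nr + i, 2) for i in range(nr)]}
    return BoundaryConditions(
        ndof=ndof_u + len(rp),
        zero_dofs=np.unique(zero),
        punch_z_dofs=np.array([], dtype=np.int64),
        drained_p_dofs=np.unique(drained),
        f_ext=f_ext,
        facet_classes=facets,
    )


@dataclass
class TerzaghiResult:
    """FE vs. series comparison at requested time factors."""

    cv: float                    # consolidation coefficient [mm^2/s]
    p0: float                    # applied load [Pa]
    z_over_H: np.ndarray         # from the drained face
    time_factors: tuple[float, ...]
    p_fe: dict                   # Tv -> nodal p/p0 profile
    p_exact: dict                # Tv -> series p/p0 profile
    l2_errors: dict              # Tv -> relative L2 mismatch
    p_undrained_core: float      # p/p0 at the base right after loading
    settlement: dict             # label -> top settlement [mm]


def terzaghi_benchmark(height: float = 1.0, load: float = 50.0,
                       params: MaterialParameters | None = None,
                       nz: int = 24,
                       time_factors: tuple[float, ...] = (0.2, 0.5),
                       ramp_time: float = 5.0e-3,
                       steps_per_segment: int = 60) -> TerzaghiResult:
    """Run the confined-consolidation column and compare with the series.

    ``load`` in Pa (kept small so strains stay within the linear range);
    the load is ramped over ``ramp_time`` and then held.
    """
    params = params or linearized_params()
    G = params.eq.mu0
    M = params.lambda_star + 4.0 * G / 3.0
    cv = (params.K0 / params.muFR) * M
    mesh = build_column_mesh(radius=0.3 * height, height=height, nr=2, nz=nz)
    bcs = _column_bcs(mesh, load)
    settings = SolverSettings(newton_atol_u=1e-10, newton_atol_p=1e-14)
    sys_ = FESystem(mesh, params, bcs, settings)
    x, internal, J_old = sys_.initial_state()

    t_targets = [tf * height**2 / cv for tf in time_factors]
    # grid: load ramp, then geometric growth hitting each target exactly
    times = [0.0, ramp_time / 2, ramp_time]
    t = ramp_time
    for tt in sorted(t_targets):
        seg = np.geomspace(t, tt, steps_per_segment)[1:]
        times.extend(seg.tolist())
        t = tt
    times = np.array(times)

    # pressure dof line along the axis r = 0, ordered bottom -> top
    axis_nodes = np.nonzero(mesh.nodes_p[:, 0] < 1e-9)[0]
    axis_nodes = axis_nodes[np.argsort(mesh.nodes_p[axis_nodes, 1])]
    z_fe = mesh.nodes_p[axis_nodes, 1]
    z_over_H = (height - z_fe) / height  # from the drained top face

    p_fe, p_exact, l2 = {}, {}, {}
    p_undrained = None
    settlement = {}
    t_prev = 0.0
    for t in times[1:]:
        sys_.f_scale = min(t / ramp_time, 1.0)
        x, aux, _ = sys_.advance(x, internal, J_old, 0.0, 0.0, t - t_prev)
        internal, J_old = aux["internal"], aux["J"]
        if p_undrained is None and t >= ramp_time:
            p_axis = x[sys_.ndof_u:][axis_nodes]
            p_undrained = float(p_axis[0] / load)  # base value
        for tf, tt in zip(time_factors, t_targets):
            if abs(t - tt) < 1e-9 * max(1.0, tt):
                prof = x[sys_.ndof_u:][axis_nodes] / load
                p_fe[tf] = prof
                p_exact[tf] = terzaghi_pressure(z_over_H, tf)
                l2[tf] = float(np.linalg.norm(prof - p_exact[tf])
                               / np.linalg.norm(p_exact[tf]))
                top = np.nonzero(mesh.nodes_u[:, 1] > height - 1e-9)[0]
                settlement[f"Tv={tf}"] = float(
                    -np.mean(x[2 * top + 1]))
        t_prev = t
    settlement["drained_exact"] = load * height / M
    return TerzaghiResult(
        cv=cv, p0=load, z_over_H=z_over_H, time_factors=time_factors,
        p_fe=p_fe, p_exact=p_exact, l2_errors=l2,
        p_undrained_core=p_undrained, settlement=settlement,
    )
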