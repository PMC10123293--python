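"""Quasi-static coupled displacement--pore-pressure finite elements.

Discretizes the axisymmetric weak forms

    int_B0 grad_x(du) : tau dV0 = 0
    int_B0 dp Jdot dV0 - int_B0 grad_x(dp) . w J dV0 = 0

(Kirchhoff stress ``tau``, volume-weighted seepage velocity ``w``, spatial
gradients, reference measure ``dV0 = 2 pi R dR dZ``) with Q2 displacement /
Q1 pressure Taylor-Hood quadrilaterals, full 3x3 Gauss integration and
backward-Euler time stepping.  The viscoelastic internal variables are
updated at every quadrature point inside each residual evaluation, so the
element-level finite-difference tangent is automatically the consistent
algorithmic tangent.

Internally forces are in uN (Pa * mm^2); reported punch forces in mN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    InternalState,
    LocalNewtonError,
    eq_stress,
    update_internal,
    vol_stress,
)
from .kinematics import spectral_decompose
from .materials import MaterialParameters
from .mesh import Geometry, Mesh, build_mesh
from .protocols import IndentationProtocol

UN_PER_MN = 1.0e3  # uN per mN


class SolverError(RuntimeError):
    """Raised when the Newton iteration fails to converge."""


@dataclass(frozen=True)
class SolverSettings:
    """Newton and time-stepping controls.

    Tolerances are on the free-dof residual norms: momentum in uN, mass in
    mm^3/s.  ``dt_ramp`` is the step during displacement ramps; during holds
    and recoveries the step grows geometrically from ``dt_ramp`` by
    ``dt_growth`` up to ``dt_max``.
    """

    newton_rtol: float = 1.0e-8
    newton_atol_u: float = 1.0e-7   # uN  (= 1e-10 mN)
    newton_atol_p: float = 1.0e-10  # mm^3/s
    max_newton: int = 25
    dt_ramp: float = 0.02
    dt_growth: float = 1.3
    dt_max: float = 5.0
    max_halvings: int = 8
    tangent_refresh_steps: int = 8   # reuse LU for at most this many steps
    tangent_refresh_iters: int = 4   # refresh when Newton needs more


# ---------------------------------------------------------------------------
# shape functions (tensor Lagrange on [-1,1]^2), 3x3 Gauss
# ---------------------------------------------------------------------------

_G = np.sqrt(3.0 / 5.0)
_GP = np.array([-_G, 0.0, _G])
_GW = np.array([5.0, 8.0, 5.0]) / 9.0


def _lag2(x):
    """Quadratic Lagrange values/derivatives on nodes (-1, 0, 1)."""
    vals = np.stack([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])
    ders = np.stack([x - 0.5, -2.0 * x, x + 0.5])
    return vals, ders


def _lag1(x):
    vals = np.stack([0.5 * (1.0 - x), 0.5 * (1.0 + x)])
    ders = np.stack([np.full_like(x, -0.5), np.full_like(x, 0.5)])
    return vals, ders


def _tabulate():
    xi, eta = np.meshgrid(_GP, _GP, indexing="xy")
    xi, eta = xi.ravel(), eta.ravel()  # 9 qps, xi fastest
    wq = np.outer(_GW, _GW).ravel()
    v2x, d2x = _lag2(xi)
    v2y, d2y = _lag2(eta)
    v1x, d1x = _lag1(xi)
    v1y, d1y = _lag1(eta)
    Nu = np.empty((9, 9))
    dNu = np.empty((9, 2, 9))
    for a in range(9):
        di, dj = a % 3, a // 3
        Nu[a] = v2x[di] * v2y[dj]
        dNu[a, 0] = d2x[di] * v2y[dj]
        dNu[a, 1] = v2x[di] * d2y[dj]
    Np_ = np.empty((4, 9))
    dNp = np.empty((4, 2, 9))
    for b in range(4):
        di, dj = b % 2, b // 2
        Np_[b] = v1x[di] * v1y[dj]
        dNp[b, 0] = d1x[di] * v1y[dj]
        dNp[b, 1] = v1x[di] * d1y[dj]
    return xi, eta, wq, Nu, dNu, Np_, dNp


_XI, _ETA, _WQ, _NU, _DNU, _NP, _DNP = _tabulate()

# 1D edge quadrature data for surface integrals (3-node quadratic edge)
_EV, _ED = _lag2(_GP)


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet sets for the coupled problem.

    ``zero_dofs`` are held at zero; ``punch_z_dofs`` follow the prescribed
    punch displacement; ``drained_p_dofs`` are pressure dofs set to the
    p = 0 drainage gauge.  ``f_ext`` is an optional static external load
    vector [uN] (used by the consolidation benchmark).
    """

    ndof: int
    zero_dofs: np.ndarray
    punch_z_dofs: np.ndarray
    drained_p_dofs: np.ndarray
    f_ext: np.ndarray | None = None
    facet_classes: dict = field(default_factory=dict)

    @property
    def constrained(self) -> np.ndarray:
        mask = np.zeros(self.ndof, dtype=bool)
        mask[self.zero_dofs] = True
        mask[self.punch_z_dofs] = True
        mask[self.drained_p_dofs] = True
        return mask


def classify_facets(mesh: Mesh, geometry: Geometry) -> dict[str, list]:
    """Classify every boundary facet (cell, side) exactly once.

    Sides: 0=bottom, 1=right, 2=top, 3=left of the (r, z) rectangle.
    Classes: bottom / outer / axis / punch / top_drained.
    """
    nr = len(mesh.r_breaks) - 1
    nz = len(mesh.z_breaks) - 1
    Ri = geometry.punch_radius
    out: dict[str, list] = {k: [] for k in
                            ("bottom", "outer", "axis", "punch", "top_drained")}
    for j in range(nz):
        for i in range(nr):
            c = j * nr + i
            if j == 0:
                out["bottom"].append((c, 0))
            if i == nr - 1:
                out["outer"].append((c, 1))
            if i == 0:
                out["axis"].append((c, 3))
            if j == nz - 1:
                r_mid = 0.5 * (mesh.r_breaks[i] + mesh.r_breaks[i + 1])
                cls = "punch" if r_mid < Ri else "top_drained"
                out[cls].append((c, 2))
    return out


def indentation_bcs(mesh: Mesh, geometry: Geometry) -> BoundaryConditions:
    """Standard flat-punch indentation boundary conditions: bottom fully
    fixed; axis symmetric; full-adhesion punch footprint (r <= Ri at the top:
    u_z prescribed, u_r = 0, undrained); every other outer surface
    traction-free and drained (p = 0)."""
    ru, zu = mesh.nodes_u[:, 0], mesh.nodes_u[:, 1]
    rp, zp = mesh.nodes_p[:, 0], mesh.nodes_p[:, 1]
    H, Rs, Ri = geometry.sample_height, geometry.sample_radius, geometry.punch_radius
    tol = 1e-9
    ndof_u = 2 * len(ru)
    ndof = ndof_u + len(rp)

    bottom = np.nonzero(zu < tol)[0]
    axis = np.nonzero(ru < tol)[0]
    top = np.nonzero(zu > H - tol)[0]
    punch = top[ru[top] <= Ri + tol]

    zero = np.concatenate([
        2 * bottom, 2 * bottom + 1,   # bottom: both components
        2 * axis,                     # axis: u_r = 0
        2 * punch,                    # punch: u_r = 0 (full adhesion)
    ])
    punch_z = 2 * punch + 1

    drained = np.nonzero(
        (zp < tol) | (rp > Rs - tol) | ((zp > H - tol) & (rp >= Ri - tol))
    )[0] + ndof_u

    return BoundaryConditions(
        ndof=ndof,
        zero_dofs=np.unique(zero),
        punch_z_dofs=np.unique(punch_z),
        drained_p_dofs=np.unique(drained),
        facet_classes=classify_facets(mesh, geometry),
    )


# ---------------------------------------------------------------------------
# the assembled system
# ---------------------------------------------------------------------------

class FESystem:
    """Assembly and solution driver for one mesh + material + BC set."""

    def __init__(self, mesh: Mesh, params: MaterialParameters,
                 bcs: BoundaryConditions,
                 settings: SolverSettings | None = None):
        self.mesh = mesh
        self.params = params
        self.bcs = bcs
        self.settings = settings or SolverSettings()

        nc = mesh.n_cells
        dr, dz = mesh.cell_sizes
        self.nc, self.nq = nc, 9
        self.ndof_u = 2 * len(mesh.nodes_u)
        self.ndof = self.ndof_u + len(mesh.nodes_p)

        # reference radius at each quadrature point
        rc = mesh.nodes_u[mesh.conn_u[:, 4], 0]  # cell-center node
        zc = mesh.nodes_u[mesh.conn_u[:, 4], 1]
        self.Rq = rc[:, None] + 0.5 * dr[:, None] * _XI[None, :]
        self.w0 = (_WQ[None, :] * (dr * dz / 4.0)[:, None]
                   * 2.0 * np.pi * self.Rq)

        # per-cell reference gradients (rectangular cells: diagonal map)
        self.DNu = np.empty((nc, 9, 9, 2))
        self.DNu[..., 0] = (_DNU[None, :, 0, :] * (2.0 / dr)[:, None, None])
        self.DNu[..., 1] = (_DNU[None, :, 1, :] * (2.0 / dz)[:, None, None])
        self.DNp = np.empty((nc, 4, 9, 2))
        self.DNp[..., 0] = (_DNP[None, :, 0, :] * (2.0 / dr)[:, None, None])
        self.DNp[..., 1] = (_DNP[None, :, 1, :] * (2.0 / dz)[:, None, None])

        # element dof maps: 18 u-dofs then 4 p-dofs
        eu = np.empty((nc, 18), dtype=np.int64)
        eu[:, 0::2] = 2 * mesh.conn_u
        eu[:, 1::2] = 2 * mesh.conn_u + 1
        ep = self.ndof_u + mesh.conn_p
        self.edof = np.concatenate([eu, ep], axis=1)
        self.rows = np.repeat(self.edof, 22, axis=1).ravel()
        self.cols = np.tile(self.edof, (1, 22)).ravel()

        self.free = ~bcs.constrained
        self.f_scale = 1.0  # external-load ramp factor (benchmark use)
        self._lu = None
        self._lu_age = 0

    # -- state helpers ------------------------------------------------------

    def initial_state(self):
        """(x, internal, J_old) of the stress-free reference configuration."""
        x = np.zeros(self.ndof)
        internal = InternalState.reference((self.nc, self.nq))
        J_old = np.ones((self.nc, self.nq))
        return x, internal, J_old

    def _gather(self, x):
        ue = x[self.edof[:, :18]].reshape(self.nc, 9, 2)
        pe = x[self.edof[:, 18:]]
        return ue, pe

    # -- element-level physics ----------------------------------------------

    def _element_residuals(self, ue, pe, internal_old, J_old, dt,
                           want_aux=False, split=False):
        """Residual contributions per element: (nc, 22) in uN | mm^3/s."""
        params = self.params
        grad_u = np.einsum("cai,caqj->cqij", ue, self.DNu)
        u_r = np.einsum("ca,aq->cq", ue[:, :, 0], _NU)

        F = np.zeros((self.nc, self.nq, 3, 3))
        F[..., 0, 0] = 1.0 + grad_u[..., 0, 0]
        F[..., 0, 1] = grad_u[..., 0, 1]
        F[..., 1, 0] = grad_u[..., 1, 0]
        F[..., 1, 1] = 1.0 + grad_u[..., 1, 1]
        F[..., 2, 2] = 1.0 + u_r / self.Rq

        state = spectral_decompose(F)
        J = state.J
        internal_new, tau_neq = update_internal(state, internal_old, dt, params)
        tau_solid = (eq_stress(state, params) + vol_stress(J, params)
                     + sum(tau_neq))
        p_q = np.einsum("cb,bq->cq", pe, _NP)
        tau_fluid = -(p_q * J)[..., None, None] * np.eye(3)

        F2inv = np.linalg.inv(F[..., :2, :2])
        gxu = np.einsum("caqj,cqji->caqi", self.DNu, F2inv)
        gxp = np.einsum("cbqj,cqji->cbqi", self.DNp, F2inv)
        r_cur = self.Rq + u_r

        def momentum(tau):
            Ru = np.einsum("cq,caqj,cqij->cai", self.w0, gxu, tau[..., :2, :2])
            Ru[..., 0] += np.einsum("cq,aq,cq->ca", self.w0, _NU,
                                    tau[..., 2, 2] / r_cur)
            return Ru.reshape(self.nc, 18)

        Ru = momentum(tau_solid + tau_fluid)

        grad_p = np.einsum("cb,cbqi->cqi", pe, gxp)
        mobility = ((params.K0 / params.muFR)
                    * (J - params.n0S) / (1.0 - params.n0S))
        wvec = -mobility[..., None] * grad_p
        Jdot = (J - J_old) / dt if dt > 0 else np.zeros_like(J)
        Rp = (np.einsum("cq,bq,cq->cb", self.w0, _NP, Jdot)
              - np.einsum("cq,cbqi,cqi->cb", self.w0 * J, gxp, wvec))

        Re = np.concatenate([Ru, Rp], axis=1)
        if not want_aux:
            return Re, None
        aux = {"internal": internal_new, "J": J, "state": state,
               "tau_neq": tau_neq, "wvec": wvec, "grad_p": grad_p}
        if split:
            aux["Ru_solid"] = momentum(tau_solid)
            aux["Ru_fluid"] = momentum(tau_fluid)
        return Re, aux

    def _scatter(self, Re):
        return np.bincount(self.edof.ravel(), weights=Re.ravel(),
                           minlength=self.ndof)

    def residual(self, x, internal_old, J_old, dt, want_aux=False,
                 split=False):
        """Assembled residual [uN | mm^3/s]; external load subtracted."""
        ue, pe = self._gather(x)
        Re, aux = self._element_residuals(ue, pe, internal_old, J_old, dt,
                                          want_aux=want_aux, split=split)
        R = self._scatter(Re)
        if self.bcs.f_ext is not None:
            R = R - self.f_scale * self.bcs.f_ext
        return (R, aux) if want_aux else R

    def tangent(self, x, internal_old, J_old, dt):
        """Consistent tangent by element-level forward differences of the
        full algorithmic residual (includes the viscous update)."""
        ue, pe = self._gather(x)
        Re0, _ = self._element_residuals(ue, pe, internal_old, J_old, dt)
        vals = np.empty((self.nc, 22, 22))
        for k in range(22):
            if k < 18:
                a, i = divmod(k, 2)
                h = 1.0e-7
                up = ue.copy()
                up[:, a, i] += h
                Re1, _ = self._element_residuals(up, pe, internal_old,
                                                 J_old, dt)
            else:
                b = k - 18
                h = 1.0e-3
                pp = pe.copy()
                pp[:, b] += h
                Re1, _ = self._element_residuals(ue, pp, internal_old,
                                                 J_old, dt)
            vals[:, :, k] = (Re1 - Re0) / h
        K = sp.coo_matrix((vals.ravel(), (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof)).tocsc()
        return K

    def assemble_system(self, x, internal_old, J_old, dt):
        """(residual, tangent) at the given state — the public assembly
        entry point used by verification tests."""
        return (self.residual(x, internal_old, J_old, dt),
                self.tangent(x, internal_old, J_old, dt))

    # -- nonlinear solve ------------------------------------------------------

    def _norms(self, R):
        free = self.free
        Ru = R[:self.ndof_u][free[:self.ndof_u]]
        Rp = R[self.ndof_u:][free[self.ndof_u:]]
        return (np.linalg.norm(Ru), np.linalg.norm(Rp))

    def _refresh_lu(self, x, internal_old, J_old, dt):
        K = self.tangent(x, internal_old, J_old, dt)
        Kff = K[self.free][:, self.free].tocsc()
        self._lu = spla.splu(Kff)
        self._lu_age = 0

    def solve_step(self, x, internal_old, J_old, depth, dt):
        """One backward-Euler step to prescribed punch depth [mm].

        Modified Newton with LU reuse and a backtracking line search; the
        line search also absorbs trial states that leave the admissible
        range (det F <= 0, pore closure).  Returns (x, aux, iterations);
        raises SolverError on failure so the caller can halve dt.
        """
        st = self.settings
        x = x.copy()
        x[self.bcs.zero_dofs] = 0.0
        x[self.bcs.punch_z_dofs] = -depth
        x[self.bcs.drained_p_dofs] = 0.0

        try:
            R, aux = self.residual(x, internal_old, J_old, dt, want_aux=True)
        except (ValueError, LocalNewtonError, FloatingPointError) as exc:
            raise SolverError(f"inadmissible step start: {exc}") from exc
        nu, np_ = self._norms(R)
        ref_u = max(nu, st.newton_atol_u)
        ref_p = max(np_, st.newton_atol_p)

        refreshes = 0
        for it in range(st.max_newton):
            if (nu <= max(st.newton_atol_u, st.newton_rtol * ref_u)
                    and np_ <= max(st.newton_atol_p, st.newton_rtol * ref_p)):
                aux["R"] = R
                return x, aux, it
            refreshed_now = False
            if (self._lu is None
                    or (it == 0 and self._lu_age >= st.tangent_refresh_steps)
                    or (it == st.tangent_refresh_iters and refreshes == 0)):
                self._refresh_lu(x, internal_old, J_old, dt)
                refreshed_now = True
                refreshes += 1
            while True:
                # affine-invariant (Newton-step) merit: the LU-preconditioned
                # residual norm weighs displacement and pressure consistently
                dx = self._lu.solve(-R[self.free])
                merit0 = np.linalg.norm(dx)
                alpha, accepted = 1.0, False
                for _ in range(8):
                    x_try = x.copy()
                    x_try[self.free] += alpha * dx
                    try:
                        R_try, aux_try = self.residual(
                            x_try, internal_old, J_old, dt, want_aux=True)
                    except (ValueError, LocalNewtonError,
                            FloatingPointError):
                        alpha *= 0.5
                        continue
                    nu_t, np_t = self._norms(R_try)
                    if not (np.isfinite(nu_t) and np.isfinite(np_t)):
                        alpha *= 0.5
                        continue
                    merit_t = np.linalg.norm(
                        self._lu.solve(R_try[self.free]))
                    if merit_t < (1.0 - 0.25 * alpha) * merit0 or (
                            nu_t <= max(st.newton_atol_u,
                                        st.newton_rtol * ref_u)
                            and np_t <= max(st.newton_atol_p,
                                            st.newton_rtol * ref_p)):
                        accepted = True
                        break
                    alpha *= 0.5
                if accepted:
                    x, R, aux, nu, np_ = x_try, R_try, aux_try, nu_t, np_t
                    break
                if refreshed_now:
                    raise SolverError(
                        f"line search stalled (|Ru|={nu:.3e} uN, "
                        f"|Rp|={np_:.3e} mm^3/s, dt={dt:g})")
                self._refresh_lu(x, internal_old, J_old, dt)
                refreshed_now = True
                refreshes += 1
        raise SolverError(
            f"no convergence in {st.max_newton} Newton iterations "
            f"(|Ru|={nu:.3e} uN, |Rp|={np_:.3e} mm^3/s, dt={dt:g})")

    def advance(self, x, internal_old, J_old, depth_prev, depth, dt,
                x_guess=None):
        """Step with automatic dt halving on failure; during substepping the
        prescribed depth is interpolated linearly between the previous and
        the target value (exact for piecewise-linear protocols).
        ``x_guess`` is an optional predictor start (free dofs only)."""
        st = self.settings
        n_sub, level = 1, 0
        while True:
            try:
                sub_dt = dt / n_sub
                xs, Js, ints = x, J_old, internal_old
                last_aux, iters = None, 0
                ints_prev, Js_prev = ints, Js
                for i in range(1, n_sub + 1):
                    d_i = depth_prev + (depth - depth_prev) * i / n_sub
                    ints_prev, Js_prev = ints, Js
                    start = x_guess if (i == 1 and n_sub == 1
                                        and x_guess is not None) else xs
                    try:
                        xs, aux, it = self.solve_step(start, ints, Js, d_i,
                                                      sub_dt)
                    except SolverError:
                        if start is not xs:  # retry without predictor
                            xs, aux, it = self.solve_step(xs, ints, Js, d_i,
                                                          sub_dt)
                        else:
                            raise
                    ints, Js = aux["internal"], aux["J"]
                    last_aux, iters = aux, iters + it
                    self._lu_age += 1
                # state *before* the last substep, for force reporting
                last_aux["prev"] = (ints_prev, Js_prev, sub_dt)
                return xs, last_aux, iters
            except SolverError:
                level += 1
                if level > st.max_halvings:
                    raise
                n_sub *= 2
                self._lu = None

    # -- diagnostics ----------------------------------------------------------

    def punch_force(self, x, internal_old, J_old, dt):
        """(total, solid, fluid) punch reaction force [mN], positive in
        compression, from the variationally consistent residual restricted
        to the punch-constrained vertical dofs."""
        R, aux = self.residual(x, internal_old, J_old, dt, want_aux=True,
                               split=True)
        Rs = self._scatter(np.concatenate(
            [aux["Ru_solid"], np.zeros((self.nc, 4))], axis=1))
        Rf = self._scatter(np.concatenate(
            [aux["Ru_fluid"], np.zeros((self.nc, 4))], axis=1))
        dofs = self.bcs.punch_z_dofs
        return (-R[dofs].sum() / UN_PER_MN,
                -Rs[dofs].sum() / UN_PER_MN,
                -Rf[dofs].sum() / UN_PER_MN)

    def volume_change(self, aux):
        """Domain volume change relative to reference [mm^3]."""
        return float(np.sum(self.w0 * (aux["J"] - 1.0)))

    def boundary_outflow(self, x, aux) -> float:
        """Fluid volume flux [mm^3/s] leaving through drained facets,
        integrated independently from the Darcy flux (Nanson-transformed
        surface integral)."""
        mesh = self.mesh
        params = self.params
        total = 0.0
        drained = [f for cls in ("bottom", "outer", "top_drained")
                   for f in self.bcs.facet_classes.get(cls, [])]
        ue, pe = self._gather(x)
        dr, dz = mesh.cell_sizes
        for c, side in drained:
            # 1D quadrature along the facet in reference coordinates
            if side in (0, 2):  # bottom/top: along r
                s = np.stack([_GP, np.full(3, -1.0 if side == 0 else 1.0)])
                dL = dr[c] / 2.0
                normal = np.array([0.0, -1.0]) if side == 0 \
                    else np.array([0.0, 1.0])
            else:  # left/right: along z
                s = np.stack([np.full(3, 1.0 if side == 1 else -1.0), _GP])
                dL = dz[c] / 2.0
                normal = np.array([1.0, 0.0]) if side == 1 \
                    else np.array([-1.0, 0.0])
            v2x, d2x = _lag2(s[0])
            v2y, d2y = _lag2(s[1])
            v1x, d1x = _lag1(s[0])
            v1y, d1y = _lag1(s[1])
            Nq = np.empty((9, 3))
            dNq = np.empty((9, 2, 3))
            for a in range(9):
                di, dj = a % 3, a // 3
                Nq[a] = v2x[di] * v2y[dj]
                dNq[a, 0] = d2x[di] * v2y[dj] * 2.0 / dr[c]
                dNq[a, 1] = v2x[di] * d2y[dj] * 2.0 / dz[c]
            Npq = np.empty((4, 3))
            dNpq = np.empty((4, 2, 3))
            for b in range(4):
                di, dj = b % 2, b // 2
                Npq[b] = v1x[di] * v1y[dj]
                dNpq[b, 0] = d1x[di] * v1y[dj] * 2.0 / dr[c]
                dNpq[b, 1] = v1x[di] * d1y[dj] * 2.0 / dz[c]
            uc = ue[c]  # (9, 2)
            pc = pe[c]  # (4,)
            grad_u = np.einsum("ai,adq->qid", uc, dNq)
            R0 = mesh.nodes_u[mesh.conn_u[c, 4], 0] + dr[c] / 2.0 * s[0]
            u_r = uc[:, 0] @ Nq
            Fq = np.zeros((3, 3, 3))
            for q in range(3):
                Fq[q, :2, :2] = np.eye(2) + grad_u[q]
                Fq[q, 2, 2] = 1.0 + u_r[q] / max(R0[q], 1e-12)
            J = np.linalg.det(Fq)
            F2inv = np.linalg.inv(Fq[:, :2, :2])
            grad_pq = np.einsum("b,bdq,qdi->qi", pc, dNpq, F2inv)
            mobility = ((params.K0 / params.muFR)
                        * (J - params.n0S) / (1.0 - params.n0S))
            wq_ = -mobility[:, None] * grad_pq
            # Nanson: n da = J F^{-T} N dA0, restricted to the (r,z) plane
            nda = J[:, None] * np.einsum("qji,j->qi", F2inv, normal)
            flux = np.einsum("qi,qi->q", wq_, nda)
            total += float(np.sum(_GW * flux * dL * 2.0 * np.pi * R0))
        return total


# ---------------------------------------------------------------------------
# protocol driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Punch force history with solid/fluid decomposition."""

    t: np.ndarray
    depth: np.ndarray          # prescribed punch depth [mm]
    force: np.ndarray          # total reaction [mN]
    force_solid: np.ndarray
    force_fluid: np.ndarray
    J_min: np.ndarray
    J_max: np.ndarray
    volume_change: np.ndarray  # [mm^3]
    outflow_rate: np.ndarray   # [mm^3/s] through drained boundaries
    newton_iters: np.ndarray
    mesh: Mesh
    snapshots: dict = field(default_factory=dict)

    def peak_force(self, t0: float = 0.0, t1: float | None = None) -> float:
        mask = (self.t >= t0) & (self.t <= (t1 if t1 is not None else np.inf))
        return float(np.max(self.force[mask]))

    def force_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.force))


def protocol_time_grid(protocol: IndentationProtocol,
                       settings: SolverSettings,
                       t_end: float | None = None) -> np.ndarray:
    """Backward-Euler grid: uniform ``dt_ramp`` during ramps/unloads,
    geometric growth during holds/recoveries; segment ends are hit
    exactly."""
    ts = [0.0]
    for t0, t1, kind in protocol.segments():
        if t_end is not None and t0 >= t_end - 1e-12:
            break
        stop = min(t1, t_end) if t_end is not None else t1
        t = t0
        dt = settings.dt_ramp
        while t < stop - 1e-12:
            if kind in ("ramp", "unload"):
                t = min(t + settings.dt_ramp, stop)
            else:
                t = min(t + dt, stop)
                dt = min(dt * settings.dt_growth, settings.dt_max)
            ts.append(t)
    return np.asarray(ts)


def run_protocol(protocol: IndentationProtocol,
                 params: MaterialParameters,
                 settings: SolverSettings | None = None,
                 geometry: Geometry | None = None,
                 mesh: Mesh | None = None,
                 refinement_level: int = 0,
                 t_end: float | None = None,
                 snapshot_times: tuple[float, ...] = (),
                 displacement: Callable[[float], float] | None = None,
                 diagnostics: bool = True,
                 ) -> SimulationResult:
    """Simulate a flat-punch indentation protocol.

    ``t_end`` truncates the simulation (e.g. after the first hold);
    ``displacement`` overrides the protocol's depth program (e.g. to replay
    a measured displacement record).  With ``diagnostics=False`` the
    solid/fluid force split and the mass-balance bookkeeping are skipped
    and the total punch force is read off the converged Newton residual —
    the fast path used inside the inverse identification loop.
    """
    settings = settings or SolverSettings()
    geometry = geometry or Geometry()
    if mesh is None:
        mesh = build_mesh(geometry, refinement_level)
    bcs = indentation_bcs(mesh, geometry)
    sys_ = FESystem(mesh, params, bcs, settings)
    x, internal, J_old = sys_.initial_state()

    times = protocol_time_grid(protocol, settings, t_end)
    depth_fn = displacement or protocol.displacement

    n = len(times)
    out = {k: np.zeros(n) for k in
           ("force", "force_solid", "force_fluid", "J_min", "J_max",
            "volume_change", "outflow_rate")}
    iters = np.zeros(n, dtype=int)
    depths = np.zeros(n)
    snapshots = {}
    t_prev = times[0]
    x_prev, dt_prev = x, 0.0
    for k, t in enumerate(times):
        d = float(depth_fn(t))
        depths[k] = d
        dt = float(t - t_prev)
        if k == 0:
            if abs(d) > 1e-12:
                raise ValueError("protocol must start at zero depth (contact)")
            out["J_min"][k] = out["J_max"][k] = 1.0
            t_prev = t
            continue
        guess = None
        if k >= 2 and dt_prev > 0:
            # secant predictor from the two previous converged states
            guess = x + (x - x_prev) * (dt / dt_prev)
        x_prev, dt_prev = x, dt
        x, aux, it = sys_.advance(x, internal, J_old, depths[k - 1], d, dt,
                                  x_guess=guess)
        if diagnostics:
            ft, fs, ff = sys_.punch_force(x, *aux["prev"])
            out["volume_change"][k] = sys_.volume_change(aux)
            out["outflow_rate"][k] = sys_.boundary_outflow(x, aux)
        else:
            ft = -aux["R"][sys_.bcs.punch_z_dofs].sum() / UN_PER_MN
            fs = ff = np.nan
        internal, J_old = aux["internal"], aux["J"]
        out["force"][k], out["force_solid"][k], out["force_fluid"][k] = ft, fs, ff
        out["J_min"][k] = aux["J"].min()
        out["J_max"][k] = aux["J"].max()
        iters[k] = it
        for ts_ in snapshot_times:
            if abs(t - ts_) < 1e-9:
                snapshots[ts_] = {
                    "u": x[:sys_.ndof_u].reshape(-1, 2).copy(),
                    "p": x[sys_.ndof_u:].copy(),
                }
        t_prev = t
    return SimulationResult(
        t=times, depth=depths, force=out["force"],
        force_solid=out["force_solid"], force_fluid=out["force_fluid"],
        J_min=out["J_min"], J_max=out["J_max"],
        volume_change=out["volume_change"],
        outflow_rate=out["outflow_rate"],
        newton_iters=iters, mesh=mesh, snapshots=snapshots,
    )
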