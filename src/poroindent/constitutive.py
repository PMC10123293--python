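"""Biphasic finite-strain Ogden-type poro-viscoelastic material law.

The total Kirchhoff stress is

    tau = tau_eq + tau_vol + sum_i tau_neq_i - p * J * 1,

with a one-term Ogden equilibrium network evaluated on the isochoric
principal stretches of ``b = F F^T``, two Ogden/dashpot branches evaluated on
the isochoric elastic principal stretches of the per-branch elastic left
Cauchy-Green tensors ``be_i``, and a volumetric term that diverges at the
compaction point ``J -> n0S`` (pore closure), enforcing solid
quasi-incompressibility.  Fluid seepage follows a Darcy-like law in the
volume-weighted seepage velocity ``w``.

The viscous flow rule for each branch,

    -Lv(be_i) . be_i^{-1} = tau_neq_i / eta_i,

is integrated by a backward-Euler exponential map in principal logarithmic
elastic strain with a local Newton loop; this preserves be_i symmetric
positive definite for any step size and reduces exactly to the continuous
law as dt -> 0.

All operations are batched over leading array dimensions.  Stresses in Pa,
lengths in mm, time in s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import DeformationState, spectral_decompose
from .materials import MaterialParameters, OgdenBranch

#: guard band above the compaction point J = n0S
COMPACTION_TOL = 1.0e-6
#: local Newton settings for the viscous return map
LOCAL_NEWTON_TOL = 1.0e-10
LOCAL_NEWTON_MAXIT = 50


class CompactionError(ValueError):
    """Raised when J approaches the compaction point n0S (pore closure)."""


class LocalNewtonError(RuntimeError):
    """Raised when the viscous return-map iteration fails to converge."""


# ---------------------------------------------------------------------------
# elastic stress parts
# ---------------------------------------------------------------------------

def ogden_beta(lam_iso: np.ndarray, branch: OgdenBranch) -> np.ndarray:
    """Principal Kirchhoff stress coefficients of a one-term Ogden network.

    beta_a = mu * (lam_iso_a^alpha - (1/3) sum_b lam_iso_b^alpha); the three
    coefficients sum to zero, so the resulting stress is trace-free.
    """
    x = lam_iso ** branch.alpha
    return branch.mu * (x - x.mean(axis=-1, keepdims=True))


def _spectral_assemble(beta: np.ndarray, n: np.ndarray) -> np.ndarray:
    """sum_a beta_a n_a (x) n_a with eigenvectors in the columns of n."""
    return (n * beta[..., None, :]) @ np.swapaxes(n, -1, -2)


def _solve3(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched 3x3 linear solve by Cramer's rule (faster than LAPACK
    dispatch for the small systems of the viscous return map)."""
    a00, a01, a02 = A[..., 0, 0], A[..., 0, 1], A[..., 0, 2]
    a10, a11, a12 = A[..., 1, 0], A[..., 1, 1], A[..., 1, 2]
    a20, a21, a22 = A[..., 2, 0], A[..., 2, 1], A[..., 2, 2]
    c00 = a11 * a22 - a12 * a21
    c01 = a12 * a20 - a10 * a22
    c02 = a10 * a21 - a11 * a20
    det = a00 * c00 + a01 * c01 + a02 * c02
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    x0 = (b0 * c00 + a01 * (a12 * b2 - a22 * b1)
          + a02 * (a21 * b1 - a11 * b2)) / det
    x1 = (a00 * (b1 * a22 - a12 * b2) + b0 * c01
          + a02 * (a10 * b2 - a20 * b1)) / det
    x2 = (a00 * (a11 * b2 - a21 * b1) + a01 * (a20 * b1 - a10 * b2)
          + b0 * c02) / det
    return np.stack([x0, x1, x2], axis=-1)


def eq_stress(state: DeformationState, params: MaterialParameters) -> np.ndarray:
    """Isochoric equilibrium Kirchhoff stress (trace-free)."""
    beta = ogden_beta(state.isochoric_stretches, params.eq)
    return _spectral_assemble(beta, state.principal_directions)


def neq_stress(be: np.ndarray, branch: OgdenBranch) -> np.ndarray:
    """Non-equilibrium Kirchhoff stress of one branch from its elastic left
    Cauchy-Green tensor ``be`` (symmetric positive definite)."""
    be = np.asarray(be, dtype=float)
    lam2, n = np.linalg.eigh(be)
    if np.any(lam2 <= 0.0):
        raise ValueError("be must be symmetric positive definite")
    lam = np.sqrt(lam2)
    Je = np.prod(lam, axis=-1)
    lam_iso = lam * Je[..., None] ** (-1.0 / 3.0)
    beta = ogden_beta(lam_iso, branch)
    return _spectral_assemble(beta, n)


def vol_stress_scalar(J: np.ndarray, params: MaterialParameters) -> np.ndarray:
    """Scalar coefficient s(J) of the volumetric stress ``tau_vol = s(J) 1``.

    s(J) = lambda* (1-n0S)^2 [ J/(1-n0S) - J/(J-n0S) ]; zero at J = 1 and
    hyperbolically divergent at the compaction point J -> n0S.
    """
    J = np.asarray(J, dtype=float)
    n0S = params.n0S
    if np.any(J <= n0S + COMPACTION_TOL):
        raise CompactionError(
            f"J = {np.min(J):g} at/below compaction point n0S = {n0S:g}: "
            "all pores closed"
        )
    c = params.lambda_star * (1.0 - n0S) ** 2
    return c * (J / (1.0 - n0S) - J / (J - n0S))


def vol_stress(J: np.ndarray, params: MaterialParameters) -> np.ndarray:
    """Volumetric Kirchhoff stress tensor ``s(J) 1``."""
    s = vol_stress_scalar(J, params)
    return np.asarray(s)[..., None, None] * np.eye(3)


# ---------------------------------------------------------------------------
# internal (viscous) state and its update
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InternalState:
    """Viscoelastic history: per-branch elastic left Cauchy-Green tensors.

    ``F`` records the deformation gradient of the configuration at which the
    ``be`` were converged; the next update forms the relative deformation
    gradient against it.  The reference state is ``be_i = F = 1``.
    """

    be: tuple[np.ndarray, ...]  # 2 x (..., 3, 3), SPD
    F: np.ndarray  # (..., 3, 3)

    @classmethod
    def reference(cls, shape: tuple[int, ...] = ()) -> "InternalState":
        eye = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
        return cls(be=(eye.copy(), eye.copy()), F=eye.copy())


def _return_map(eps_trial: np.ndarray, branch: OgdenBranch, eta: float,
                dt: float) -> np.ndarray:
    """Solve eps + dt/(2 eta) * beta(eps) = eps_trial for the principal
    logarithmic elastic strains (batched Newton, analytic Jacobian)."""
    if dt == 0.0:
        return eps_trial.copy()
    c = dt / (2.0 * eta)
    mu, alpha = branch.mu, branch.alpha
    eye = np.eye(3)
    eps = eps_trial.copy()
    for _ in range(LOCAL_NEWTON_MAXIT):
        eps_bar = eps.sum(axis=-1, keepdims=True) / 3.0
        # clamp the Ogden exponent to keep extreme trial states finite;
        # converged states are far inside the clamp
        x = np.exp(np.clip(alpha * (eps - eps_bar), -60.0, 60.0))
        x_bar = x.sum(axis=-1, keepdims=True) / 3.0
        beta = mu * (x - x_bar)
        r = eps + c * beta - eps_trial
        err = np.max(np.abs(r))
        if err < LOCAL_NEWTON_TOL:
            return eps
        # d beta_a / d eps_b = mu*alpha*[(delta_ab - 1/3) x_a
        #                                - (x_b - mean(x)) / 3]
        dbeta = mu * alpha * (
            (eye - 1.0 / 3.0) * x[..., :, None]
            - (x - x_bar)[..., None, :] / 3.0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            step = _solve3(eye + c * dbeta, r)
        if not np.all(np.isfinite(step)):
            raise LocalNewtonError(
                "viscous return map produced a singular local Jacobian")
        # trust-region style cap keeps extreme trials from overshooting
        step = np.clip(step, -5.0, 5.0)
        eps = eps - step
    raise LocalNewtonError(
        f"viscous return map did not converge in {LOCAL_NEWTON_MAXIT} "
        f"iterations (residual {err:.3e}, dt={dt:g}, eta={eta:g})"
    )


def update_internal(
    state_new: DeformationState,
    internal_old: InternalState,
    dt: float,
    params: MaterialParameters,
) -> tuple[InternalState, tuple[np.ndarray, ...]]:
    """Implicit update of the viscoelastic internal variables over ``dt``.

    Forms the elastic trial state by pushing each ``be`` forward with the
    relative deformation gradient ``f = F_new F_old^{-1}``, then relaxes the
    principal logarithmic elastic strains with the exponential-map return
    map.  Returns the new internal state and the per-branch non-equilibrium
    Kirchhoff stresses at ``t + dt``.
    """
    if dt < 0.0:
        raise ValueError("dt must be non-negative")
    f = state_new.F @ np.linalg.inv(internal_old.F)
    be_new: list[np.ndarray] = []
    tau_neq: list[np.ndarray] = []
    for vb, be_old in zip(params.neq, internal_old.be):
        be_tr = f @ be_old @ np.swapaxes(f, -1, -2)
        be_tr = 0.5 * (be_tr + np.swapaxes(be_tr, -1, -2))  # symmetrize
        lam2, n = np.linalg.eigh(be_tr)
        if np.any(lam2 <= 0.0):
            raise ValueError("trial be lost positive definiteness")
        eps_tr = 0.5 * np.log(lam2)
        eps = _return_map(eps_tr, vb.branch, vb.eta, dt)
        lam = np.exp(eps)
        Je = np.prod(lam, axis=-1)
        lam_iso = lam * Je[..., None] ** (-1.0 / 3.0)
        beta = ogden_beta(lam_iso, vb.branch)
        be_new.append(_spectral_assemble(np.exp(2.0 * eps), n))
        tau_neq.append(_spectral_assemble(beta, n))
    new = InternalState(be=tuple(be_new), F=state_new.F.copy())
    return new, tuple(tau_neq)


# ---------------------------------------------------------------------------
# assembled stress, fluid flux, dissipation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StressState:
    """Kirchhoff stress decomposition at a material point [Pa]."""

    tau_eq: np.ndarray
    tau_vol: np.ndarray
    tau_neq: tuple[np.ndarray, ...]
    p: np.ndarray
    tau_total: np.ndarray


def total_stress(
    state: DeformationState,
    internal: InternalState,
    p: np.ndarray | float,
    params: MaterialParameters,
) -> StressState:
    """Assemble the total Kirchhoff stress ``tau_E - p J 1`` with all parts
    stored separately (solid/fluid force reporting uses the split)."""
    p = np.asarray(p, dtype=float)
    t_eq = eq_stress(state, params)
    t_vol = vol_stress(state.J, params)
    t_neq = tuple(neq_stress(be, vb.branch)
                  for be, vb in zip(internal.be, params.neq))
    total = t_eq + t_vol + sum(t_neq) \
        - (p * state.J)[..., None, None] * np.eye(3)
    return StressState(tau_eq=t_eq, tau_vol=t_vol, tau_neq=t_neq, p=p,
                       tau_total=total)


def darcy_flux(grad_p: np.ndarray, J: np.ndarray | float,
               params: MaterialParameters) -> np.ndarray:
    """Volume-weighted seepage velocity [mm/s] from the spatial pressure
    gradient [Pa/mm]:  w = -(K0/muFR) (J - n0S)/(1 - n0S) grad p."""
    grad_p = np.asarray(grad_p, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(J <= params.n0S + COMPACTION_TOL):
        raise CompactionError(f"J = {np.min(J):g} at/below compaction point")
    mobility = (params.K0 / params.muFR) * (J - params.n0S) / (1.0 - params.n0S)
    return -np.asarray(mobility)[..., None] * grad_p


@dataclass(frozen=True)
class DissipationReport:
    """Non-negative dissipation density rates [Pa/s]."""

    Dv: np.ndarray  # viscous: sum_i tau_neq_i : tau_neq_i / (2 eta_i)
    Dp: np.ndarray  # porous: muFR/K0 (1-n0S)/(J-n0S) w.w


def dissipation(stresses: StressState, w: np.ndarray,
                state: DeformationState,
                params: MaterialParameters) -> DissipationReport:
    """Viscous and porous dissipation density rates (both >= 0 by
    construction: quadratic forms with positive coefficients)."""
    Dv = sum(
        np.einsum("...ij,...ij->...", t, t) / (2.0 * vb.eta)
        for t, vb in zip(stresses.tau_neq, params.neq)
    )
    w = np.asarray(w, dtype=float)
    coef = (params.muFR / params.K0) * (1.0 - params.n0S) / (state.J - params.n0S)
    Dp = coef * np.einsum("...i,...i->...", w, w)
    return DissipationReport(Dv=np.asarray(Dv), Dp=np.asarray(Dp))


# ---------------------------------------------------------------------------
# homogeneous-deformation driver (virtual material-point experiment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialPointResponse:
    """Stress and dissipation time series of a homogeneous history."""

    t: np.ndarray  # (nt,)
    F: np.ndarray  # (nt, 3, 3)
    tau_total: np.ndarray  # (nt, 3, 3), at p = 0 (drained point)
    tau_eq: np.ndarray
    tau_vol: np.ndarray
    tau_neq: np.ndarray  # (nt, 2, 3, 3)
    Dv: np.ndarray  # (nt,)


def run_material_point(F_history, times, params: MaterialParameters,
                       ) -> MaterialPointResponse:
    """Integrate the material law along a homogeneous deformation history.

    ``F_history`` is either an array of shape (nt, 3, 3) or a callable
    ``t -> F(t)``; ``times`` the (increasing) evaluation grid.  The pore
    pressure is zero (homogeneous drained state: no pressure gradients, no
    seepage), so the response isolates the viscoelastic solid.
    """
    times = np.asarray(times, dtype=float)
    if callable(F_history):
        Fs = np.stack([np.asarray(F_history(t), dtype=float) for t in times])
    else:
        Fs = np.asarray(F_history, dtype=float)
    if Fs.shape != (len(times), 3, 3):
        raise ValueError("F history must have shape (nt, 3, 3)")

    internal = InternalState.reference()
    out_tot, out_eq, out_vol, out_neq, out_dv = [], [], [], [], []
    t_prev = times[0]
    for k, t in enumerate(times):
        state = spectral_decompose(Fs[k])
        dt = float(t - t_prev) if k > 0 else 0.0
        internal, _ = update_internal(state, internal, dt, params)
        st = total_stress(state, internal, 0.0, params)
        rep = dissipation(st, np.zeros(3), state, params)
        out_tot.append(st.tau_total)
        out_eq.append(st.tau_eq)
        out_vol.append(st.tau_vol)
        out_neq.append(np.stack(st.tau_neq))
        out_dv.append(rep.Dv)
        t_prev = t
    return MaterialPointResponse(
        t=times, F=Fs,
        tau_total=np.stack(out_tot), tau_eq=np.stack(out_eq),
        tau_vol=np.stack(out_vol), tau_neq=np.stack(out_neq),
        Dv=np.asarray(out_dv, dtype=float),
    )
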