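"""Inverse identification of the poro-viscoelastic parameters.

Matches a simulated punch-force history to a reference (experimental or
synthetic) curve by bound-constrained nonlinear least squares over the nine
fitted parameters (mu_inf, mu_1, mu_2, alpha_inf, alpha_1, alpha_2, eta_1,
eta_2, K0), using the trust-region-reflective algorithm with a
finite-difference Jacobian.  The scalar objective is the normalized squared
error

    chi^2 = sum_i (y_exp_i - y_sim_i)^2 / sum_i (y_exp_i)^2,

whose scaling guards against vanishing gradients for small force values;
the residual vector is r_i = (y_exp_i - y_sim_i)/||y_exp||_2 so that
sum r_i^2 = chi^2 exactly.

Moduli, exponents and viscosities are optimized on an interval-midpoint
scale; K0 on a log10 scale (its search interval spans twelve decades).
Forward evaluations are cached on the parameter vector rounded to 12
significant digits, and the finite-difference Jacobian columns may be
evaluated concurrently — the forward model is a pure function of the
parameter vector, so concurrent and serial evaluation give identical
results.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .fem import SolverSettings, run_protocol
from .materials import FITTED_NAMES, MaterialParameters, hydrogel_parameters
from .mesh import Geometry, Mesh, build_mesh
from .protocols import IndentationProtocol, build_protocol


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def chi_squared(y_exp: np.ndarray, y_sim: np.ndarray) -> float:
    """Normalized squared error between force series of equal length."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y_exp.shape != y_sim.shape or y_exp.ndim != 1 or len(y_exp) < 1:
        raise ValueError("y_exp and y_sim must be equal-length 1-d arrays")
    denom = float(np.sum(y_exp**2))
    if denom == 0.0:
        raise ValueError("all-zero reference curve")
    return float(np.sum((y_exp - y_sim) ** 2) / denom)


def residual(y_exp: np.ndarray, y_sim: np.ndarray) -> np.ndarray:
    """Residual vector r with sum(r^2) = chi_squared(y_exp, y_sim)."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y_exp.shape != y_sim.shape or y_exp.ndim != 1 or len(y_exp) < 1:
        raise ValueError("y_exp and y_sim must be equal-length 1-d arrays")
    norm = float(np.linalg.norm(y_exp))
    if norm == 0.0:
        raise ValueError("all-zero reference curve")
    return (y_exp - y_sim) / norm


# ---------------------------------------------------------------------------
# parameter scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterVector:
    """Ordered fitted-parameter vector with its scaling rules.

    ``scaled`` maps natural values to the optimizer scale: division by the
    absolute interval midpoint for the linear parameters, log10 for K0.
    """

    values: np.ndarray  # natural units, FITTED_NAMES order
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (9,) or not np.all(np.isfinite(v)):
            raise ValueError("expected 9 finite parameter values")
        for x, (lo, hi), name in zip(v, self.bounds, FITTED_NAMES):
            if not lo <= x <= hi:
                raise ValueError(
                    f"{name} = {x:g} outside interval [{lo:g}, {hi:g}]")

    @classmethod
    def from_params(cls, params: MaterialParameters) -> "ParameterVector":
        fv = params.fitted_values()
        return cls(values=np.array([fv[n] for n in FITTED_NAMES]),
                   bounds=tuple(tuple(params.bounds[n]) for n in FITTED_NAMES))

    def _scales(self) -> np.ndarray:
        return np.array([abs(0.5 * (lo + hi)) for lo, hi in self.bounds[:8]])

    def scaled(self) -> np.ndarray:
        s = np.empty(9)
        s[:8] = self.values[:8] / self._scales()
        s[8] = np.log10(self.values[8])
        return s

    def scaled_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(9)
        hi = np.empty(9)
        sc = self._scales()
        for i, (a, b) in enumerate(self.bounds[:8]):
            lo[i], hi[i] = min(a, b) / sc[i], max(a, b) / sc[i]
        lo[8], hi[8] = np.log10(self.bounds[8][0]), np.log10(self.bounds[8][1])
        return lo, hi

    def with_scaled(self, x: np.ndarray) -> "ParameterVector":
        v = np.empty(9)
        v[:8] = x[:8] * self._scales()
        v[8] = 10.0 ** x[8]
        v = np.clip(v, [b[0] for b in self.bounds], [b[1] for b in self.bounds])
        return ParameterVector(values=v, bounds=self.bounds)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FITTED_NAMES, self.values))


# ---------------------------------------------------------------------------
# forward model and objective
# ---------------------------------------------------------------------------

def fit_mesh(geometry: Geometry | None = None) -> Mesh:
    """Coarse identification mesh: keeps the 4-cell punch-edge zone but
    minimal resolution elsewhere (the inverse loop runs hundreds of forward
    solves)."""
    return build_mesh(geometry or Geometry(), 0, inner_cells=1, edge_cells=4,
                      outer_cells=2, z_cells=3, z_growth=2.2)


def fit_settings() -> SolverSettings:
    """Identification solver profile: coarser stepping and a slightly looser
    Newton tolerance than the reporting profile — the forward-difference
    step of the Jacobian (1e-3 on the scaled parameters) sits far above the
    resulting force noise floor (~1e-6 relative)."""
    return SolverSettings(dt_ramp=0.05, dt_growth=1.5, newton_rtol=1.0e-6,
                          tangent_refresh_steps=4)


def evaluation_grid(protocol: IndentationProtocol) -> np.ndarray:
    """Residual sampling for cycle 1: uniform 0.05 s over the ramp, then 60
    log-spaced points across the 90 s hold (equal weight to the peak region
    and the relaxation tail)."""
    ramp_end = protocol.depth / protocol.speed
    hold_end = protocol.cycle_window(1)[1]
    ramp = np.arange(0.05, ramp_end + 1e-9, 0.05)
    if ramp.size == 0 or abs(ramp[-1] - ramp_end) > 1e-9:
        ramp = np.append(ramp, ramp_end)
    hold = ramp_end + np.geomspace(0.05, hold_end - ramp_end, 60)
    return np.concatenate([ramp, hold])


@dataclass
class ObjectiveSpec:
    """Reference curve plus the forward-model descriptor."""

    y_exp: np.ndarray
    times: np.ndarray
    protocol: IndentationProtocol
    base_params: MaterialParameters
    mesh: Mesh
    settings: SolverSettings
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        if len(self.y_exp) != len(self.times):
            raise ValueError("y_exp and times must have equal length")
        if float(np.linalg.norm(self.y_exp)) == 0.0:
            raise ValueError("reference curve must be nonzero")
        if self.times[-1] > self.protocol.cycle_window(1)[1] + 1e-9:
            raise ValueError("evaluation grid exceeds the simulated span")


def make_objective(y_exp: np.ndarray,
                   times: np.ndarray | None = None,
                   protocol: IndentationProtocol | None = None,
                   base_params: MaterialParameters | None = None,
                   geometry: Geometry | None = None) -> ObjectiveSpec:
    """Standard cycle-1 objective on the identification profile."""
    protocol = protocol or build_protocol("P2", 1)
    geometry = geometry or Geometry()
    if times is None:
        times = evaluation_grid(protocol)
    return ObjectiveSpec(
        y_exp=np.asarray(y_exp, dtype=float), times=np.asarray(times),
        protocol=protocol, base_params=base_params or hydrogel_parameters(),
        mesh=fit_mesh(geometry), settings=fit_settings(), geometry=geometry,
    )


class ForwardModel:
    """Cached, optionally concurrent forward evaluator y_sim(x_scaled)."""

    def __init__(self, spec: ObjectiveSpec, reference: ParameterVector):
        self.spec = spec
        self.reference = reference
        self.cache: dict[tuple, np.ndarray] = {}
        self.n_forward = 0
        self.n_cache_hits = 0

    @staticmethod
    def _key(x: np.ndarray) -> tuple:
        # round to 12 significant digits: evaluations closer than the
        # forward-model resolution are served from cache
        return tuple(float(f"{v:.11e}") for v in x)

    def simulate(self, pv: ParameterVector) -> np.ndarray:
        spec = self.spec
        params = spec.base_params.with_fitted(pv.as_dict())
        res = run_protocol(
            spec.protocol, params, settings=spec.settings, mesh=spec.mesh,
            geometry=spec.geometry, t_end=spec.protocol.cycle_window(1)[1],
            diagnostics=False,
        )
        return np.interp(spec.times, res.t, res.force)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        key = self._key(x)
        hit = self.cache.get(key)
        if hit is not None:
            self.n_cache_hits += 1
            return hit
        y = self.simulate(self.reference.with_scaled(np.asarray(x)))
        self.n_forward += 1
        self.cache[key] = y  # failed evaluations raise and are never cached
        return y


@dataclass
class FitResult:
    """Outcome of the inverse identification."""

    params: MaterialParameters
    vector: ParameterVector
    chi2: float
    chi2_history: list[float]
    n_forward: int
    n_cache_hits: int
    n_iterations: int
    termination: str


def fit(spec: ObjectiveSpec,
        start: MaterialParameters | None = None,
        max_nfev: int | None = None,
        diff_step: float = 1.0e-3,
        n_workers: int = 1,
        xtol: float = 1.0e-8,
        ftol: float = 1.0e-10,
        gtol: float = 1.0e-10) -> FitResult:
    """Trust-region-reflective bounded least squares.

    ``start`` defaults to the interval midpoints (on the optimizer scale);
    all iterates remain within the bounds; deterministic for fixed inputs.
    With ``n_workers > 1`` the finite-difference Jacobian columns are
    evaluated concurrently.
    """
    ref = ParameterVector.from_params(spec.base_params)
    if start is not None:
        x0 = ParameterVector.from_params(
            spec.base_params.with_fitted(start.fitted_values())).scaled()
    else:
        lo, hi = ref.scaled_bounds()
        x0 = 0.5 * (lo + hi)
    lo, hi = ref.scaled_bounds()
    model = ForwardModel(spec, ref)
    chi2_history: list[float] = []
    y_exp = spec.y_exp

    def fun(x: np.ndarray) -> np.ndarray:
        try:
            y = model(x)
        except (ValueError, RuntimeError, FloatingPointError):
            # failed evaluation: report a large residual so the step is
            # rejected; never cached
            return np.full(len(y_exp), 1.0e3)
        return residual(y_exp, y)

    def jac(x: np.ndarray) -> np.ndarray:
        # accepted iterate: record the chi^2 trajectory here
        r0 = fun(x)
        chi2_history.append(float(np.sum(r0**2)))
        steps = diff_step * np.maximum(1.0, np.abs(x))
        # reflect steps that would leave the box
        steps = np.where(x + steps > hi, -steps, steps)
        xs = [x.copy() for _ in range(9)]
        for j in range(9):
            xs[j][j] += steps[j]
        if n_workers > 1:
            with ThreadPoolExecutor(max_workers=n_workers) as ex:
                cols = list(ex.map(fun, xs))
        else:
            cols = [fun(xj) for xj in xs]
        J = np.empty((len(r0), 9))
        for j in range(9):
            J[:, j] = (cols[j] - r0) / steps[j]
        return J

    sol = least_squares(fun, x0, jac=jac, bounds=(lo, hi), method="trf",
                        xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=max_nfev)
    best = ref.with_scaled(sol.x)
    chi2_final = float(2.0 * sol.cost)  # least_squares cost = 0.5 sum r^2
    chi2_history.append(chi2_final)
    return FitResult(
        params=spec.base_params.with_fitted(best.as_dict()),
        vector=best,
        chi2=chi2_final,
        chi2_history=chi2_history,
        n_forward=model.n_forward,
        n_cache_hits=model.n_cache_hits,
        n_iterations=int(sol.njev or 0),
        termination=sol.message,
    )
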