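"""Material parameters for the biphasic Ogden-type poro-viscoelastic model.

The solid skeleton is a one-term Ogden equilibrium network in parallel with
two Ogden--dashpot (Maxwell-type) branches; a Darcy-like law with an initial
intrinsic permeability ``K0`` governs pore-fluid seepage.  Parameters follow
the conventions of finite-strain Ogden models in principal stretches: each
branch carries a shear-like modulus ``mu`` [Pa] and a dimensionless
nonlinearity exponent ``alpha``; the consistent small-strain shear modulus of
a branch is ``mu0 = mu * alpha / 2``, which must be positive (for brain-like
materials both ``mu`` and ``alpha`` are negative, capturing
compression-tension asymmetry).

Units at this interface: Pa, Pa*s, mm^2 (permeability), s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

#: density of the pore fluid (water) and standard gravity, used only for the
#: conversion of intrinsic permeability [mm^2] to hydraulic conductivity [m/s]
RHO_FLUID = 1000.0  # kg/m^3
GRAVITY = 9.81  # m/s^2

#: canonical ordering of the nine fitted parameters
FITTED_NAMES = (
    "mu_inf", "mu_1", "mu_2",
    "alpha_inf", "alpha_1", "alpha_2",
    "eta_1", "eta_2", "K0",
)

#: closed fit intervals per parameter (the default search box)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_inf": (-1000.0, -1.0),
    "mu_1": (-1000.0, -1.0),
    "mu_2": (-1000.0, -1.0),
    "alpha_inf": (-30.0, -1.0),
    "alpha_1": (-30.0, -1.0),
    "alpha_2": (-30.0, -1.0),
    "eta_1": (1.0, 1.0e5),
    "eta_2": (1.0, 1.0e5),
    "K0": (1.0e-14, 1.0e-2),
}


class MaterialError(ValueError):
    """Raised for physically inadmissible material parameters."""


@dataclass(frozen=True)
class OgdenBranch:
    """One-term Ogden branch: ``mu`` [Pa], ``alpha`` [-]."""

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if self.mu == 0.0 or self.alpha == 0.0:
            raise MaterialError("Ogden parameters mu and alpha must be nonzero")
        if self.mu * self.alpha <= 0.0:
            raise MaterialError(
                f"mu*alpha = {self.mu * self.alpha:g} <= 0: the consistent "
                "shear modulus mu*alpha/2 must be positive"
            )

    @property
    def mu0(self) -> float:
        """Consistent small-strain shear modulus ``mu*alpha/2`` [Pa]."""
        return 0.5 * self.mu * self.alpha


@dataclass(frozen=True)
class ViscousBranch:
    """Maxwell-type branch: Ogden spring in series with a dashpot ``eta`` [Pa*s]."""

    branch: OgdenBranch
    eta: float

    def __post_init__(self) -> None:
        if self.eta <= 0.0:
            raise MaterialError(f"viscosity eta = {self.eta:g} must be positive")

    @property
    def relaxation_time(self) -> float:
        """Characteristic time ``eta / mu0`` [s]."""
        return self.eta / self.branch.mu0


@dataclass(frozen=True)
class MaterialParameters:
    """Full poro-viscoelastic parameter set.

    Attributes
    ----------
    eq : OgdenBranch
        Equilibrium (long-term) Ogden network.
    neq : tuple of ViscousBranch
        Exactly two non-equilibrium branches.
    lambda_star : float
        First Lamé parameter of the solid skeleton [Pa]; set high enough to
        enforce quasi-incompressibility of the solid constituent.
    n0S : float
        Initial solid volume fraction [-] (saturation: fluid fraction 1-n0S).
    muFR : float
        Effective shear viscosity of the pore fluid [Pa*s].
    K0 : float
        Initial intrinsic permeability [mm^2].
    bounds : mapping
        Closed fit intervals for the nine fitted parameters.
    """

    eq: OgdenBranch
    neq: tuple[ViscousBranch, ...]
    lambda_star: float
    n0S: float
    muFR: float
    K0: float
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if len(self.neq) != 2:
            raise MaterialError("exactly two non-equilibrium branches are required")
        if self.lambda_star <= 0.0:
            raise MaterialError("lambda_star must be positive")
        if not 0.0 < self.n0S < 1.0:
            raise MaterialError("n0S must lie in (0, 1)")
        if self.muFR <= 0.0 or self.K0 <= 0.0:
            raise MaterialError("muFR and K0 must be positive")

    # -- fitted-vector view -------------------------------------------------

    def fitted_values(self) -> dict[str, float]:
        """The nine fitted parameters keyed by their canonical names."""
        return {
            "mu_inf": self.eq.mu,
            "mu_1": self.neq[0].branch.mu,
            "mu_2": self.neq[1].branch.mu,
            "alpha_inf": self.eq.alpha,
            "alpha_1": self.neq[0].branch.alpha,
            "alpha_2": self.neq[1].branch.alpha,
            "eta_1": self.neq[0].eta,
            "eta_2": self.neq[1].eta,
            "K0": self.K0,
        }

    def with_fitted(self, values: Mapping[str, float]) -> "MaterialParameters":
        """Return a copy with the given fitted parameters replaced."""
        v = self.fitted_values()
        v.update(values)
        return replace(
            self,
            eq=OgdenBranch(v["mu_inf"], v["alpha_inf"]),
            neq=(
                ViscousBranch(OgdenBranch(v["mu_1"], v["alpha_1"]), v["eta_1"]),
                ViscousBranch(OgdenBranch(v["mu_2"], v["alpha_2"]), v["eta_2"]),
            ),
            K0=v["K0"],
        )

    def check_bounds(self) -> None:
        """Raise if any fitted value lies outside its interval."""
        for name, value in self.fitted_values().items():
            lo, hi = self.bounds[name]
            if not lo <= value <= hi:
                raise MaterialError(
                    f"{name} = {value:g} outside its interval [{lo:g}, {hi:g}]"
                )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "solid": {
                "mu_inf": self.eq.mu,
                "alpha_inf": self.eq.alpha,
                "branches": [
                    {"mu": b.branch.mu, "alpha": b.branch.alpha, "eta": b.eta}
                    for b in self.neq
                ],
                "lambda_star": self.lambda_star,
                "n0S": self.n0S,
            },
            "fluid": {"muFR": self.muFR, "K0": self.K0},
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MaterialParameters":
        solid, fluid = d["solid"], d["fluid"]
        bounds = {k: tuple(v) for k, v in d.get("bounds", DEFAULT_BOUNDS).items()}
        return cls(
            eq=OgdenBranch(float(solid["mu_inf"]), float(solid["alpha_inf"])),
            neq=tuple(
                ViscousBranch(OgdenBranch(float(b["mu"]), float(b["alpha"])),
                              float(b["eta"]))
                for b in solid["branches"]
            ),
            lambda_star=float(solid["lambda_star"]),
            n0S=float(solid["n0S"]),
            muFR=float(fluid["muFR"]),
            K0=float(fluid["K0"]),
            bounds=bounds,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "MaterialParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def hydrogel_parameters() -> MaterialParameters:
    """Reference parameter set of the brain-tissue-mimicking PVA/Phytagel
    composite hydrogel (identified from flat-punch indentation).

    Solid fraction n0S from gravimetry; lambda_star chosen high for solid
    quasi-incompressibility; muFR is the viscosity of water at room
    temperature; the remaining nine parameters are fit results.
    """
    return MaterialParameters(
        eq=OgdenBranch(mu=-217.0, alpha=-2.16),
        neq=(
            ViscousBranch(OgdenBranch(mu=-418.0, alpha=-13.5), eta=50.6),
            ViscousBranch(OgdenBranch(mu=-161.0, alpha=-2.97), eta=4.68e3),
        ),
        lambda_star=1.0e5,
        n0S=0.032,
        muFR=0.89e-3,
        K0=2.30e-9,
    )


@dataclass(frozen=True)
class DerivedQuantities:
    """Engineering quantities derived from the raw Ogden/fluid parameters."""

    mu0_eq: float  # equilibrium consistent shear modulus [Pa]
    mu0_neq: tuple[float, ...]  # per-branch consistent shear moduli [Pa]
    tau_relax: tuple[float, ...]  # per-branch relaxation times eta/mu0 [s]
    k_hydraulic: float  # hydraulic conductivity K0*rhoF*g/muFR [m/s]

    @property
    def mu0_instantaneous(self) -> float:
        """Short-time (glassy) shear modulus: sum of all branch moduli [Pa]."""
        return self.mu0_eq + sum(self.mu0_neq)


def derived_quantities(params: MaterialParameters) -> DerivedQuantities:
    """Shear moduli, relaxation times and hydraulic conductivity.

    ``K0`` [mm^2] is converted to m^2 (factor 1e-6) before forming
    ``k = K0 * rhoF * g / muFR`` [m/s].
    """
    k = params.K0 * 1.0e-6 * RHO_FLUID * GRAVITY / params.muFR
    return DerivedQuantities(
        mu0_eq=params.eq.mu0,
        mu0_neq=tuple(b.branch.mu0 for b in params.neq),
        tau_relax=tuple(b.relaxation_time for b in params.neq),
        k_hydraulic=k,
    )
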