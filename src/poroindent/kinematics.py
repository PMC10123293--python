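"""Finite-strain kinematics at a material point.

All routines accept batched input: arrays of shape ``(..., 3, 3)`` are
processed simultaneously over the leading dimensions, which is how the FE
solver evaluates every quadrature point in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidDeformationError(ValueError):
    """Raised for deformation gradients with non-positive determinant."""


@dataclass(frozen=True)
class DeformationState:
    """Spectral description of a deformation gradient.

    ``principal_directions[..., :, a]`` is the unit eigenvector of
    ``b = F F^T`` belonging to ``principal_stretches[..., a]``; the isochoric
    stretches satisfy ``prod_a isochoric_stretches[..., a] == 1``.
    """

    F: np.ndarray  # (..., 3, 3)
    J: np.ndarray  # (...,)
    principal_stretches: np.ndarray  # (..., 3)
    principal_directions: np.ndarray  # (..., 3, 3), eigenvectors in columns
    isochoric_stretches: np.ndarray  # (..., 3)


def spectral_decompose(F: np.ndarray) -> DeformationState:
    """Decompose ``b = F F^T`` into principal stretches and directions.

    Raises
    ------
    InvalidDeformationError
        if ``det F <= 0`` anywhere in the batch.
    ValueError
        for non-finite entries.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) deformation gradient, got {F.shape}")
    if not np.all(np.isfinite(F)):
        raise ValueError("deformation gradient contains non-finite entries")
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise InvalidDeformationError(
            f"non-positive det(F) (min {np.min(J):g}); deformation is inadmissible"
        )
    b = F @ np.swapaxes(F, -1, -2)
    lam2, n = np.linalg.eigh(b)  # ascending eigenvalues of SPD b
    lam = np.sqrt(lam2)
    lam_iso = lam * J[..., None] ** (-1.0 / 3.0)
    return DeformationState(
        F=F, J=J, principal_stretches=lam,
        principal_directions=n, isochoric_stretches=lam_iso,
    )


def identity_state(shape: tuple[int, ...] = ()) -> DeformationState:
    """Reference (undeformed) state, optionally batched."""
    F = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    return spectral_decompose(F)
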