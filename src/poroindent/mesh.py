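"""Axisymmetric graded quadrilateral meshes for flat-punch indentation.

The domain is the (r, z) half-section of a cylindrical sample, meshed with a
tensor-product grid of rectangular cells graded toward the punch edge
(r = punch radius, top surface) where the contact-pressure singularity
lives, and toward the top surface where deformation localizes.  Displacement
uses 9-node biquadratic (Q2) nodes, pore pressure the 4-node bilinear (Q1)
corner subset — the inf-sup stable Taylor-Hood pair for coupled u-p
problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ConfigError(ValueError):
    """Raised for inadmissible geometry or mesh configuration."""


@dataclass(frozen=True)
class Geometry:
    """Sample and indenter geometry [mm].

    Defaults are the half-scale cylindrical sample (radius 10 mm, height
    10 mm) probed by a 2 mm flat punch.
    """

    sample_radius: float = 10.0
    sample_height: float = 10.0
    punch_radius: float = 2.0

    def __post_init__(self) -> None:
        if min(self.sample_radius, self.sample_height, self.punch_radius) <= 0:
            raise ConfigError("all geometric dimensions must be positive")
        if self.punch_radius >= self.sample_radius:
            raise ConfigError("punch radius must be smaller than sample radius")


def _geometric_breaks(x0: float, x1: float, n: int, growth: float) -> np.ndarray:
    """n intervals from x0 to x1 with lengths in geometric progression."""
    if growth == 1.0:
        return np.linspace(x0, x1, n + 1)
    w = growth ** np.arange(n)
    return x0 + (x1 - x0) * np.concatenate([[0.0], np.cumsum(w)]) / w.sum()


@dataclass(frozen=True)
class Mesh:
    """Tensor-product axisymmetric Q2/Q1 mesh.

    ``nodes_u``/``nodes_p`` hold (r, z) coordinates; ``conn_u`` (ncell, 9)
    and ``conn_p`` (ncell, 4) the per-cell connectivity.  Q2 local node
    ordering is row-major over the 3x3 patch (r fastest), Q1 over the 2x2
    corners.
    """

    r_breaks: np.ndarray
    z_breaks: np.ndarray
    nodes_u: np.ndarray
    nodes_p: np.ndarray
    conn_u: np.ndarray
    conn_p: np.ndarray
    refinement_level: int
    edge_zone: tuple[float, float] = field(default=(0.0, 0.0))

    @property
    def n_cells(self) -> int:
        return self.conn_u.shape[0]

    @property
    def cell_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        """(dr, dz) per cell."""
        nr = len(self.r_breaks) - 1
        nz = len(self.z_breaks) - 1
        dr = np.tile(np.diff(self.r_breaks), nz)
        dz = np.repeat(np.diff(self.z_breaks), nr)
        return dr, dz

    def min_map_jacobian(self) -> float:
        """Minimum isoparametric map Jacobian over cells (area/4 for the
        rectangular cells used here); positive for a valid mesh."""
        dr, dz = self.cell_sizes
        return float(np.min(dr * dz / 4.0))

    def edge_zone_cell_count(self) -> int:
        """Number of radial cells strictly inside the punch-edge zone."""
        lo, hi = self.edge_zone
        r = self.r_breaks
        return int(np.sum((r[:-1] >= lo - 1e-12) & (r[1:] <= hi + 1e-12)))

    def write_vtk(self, path: str | Path, point_data: dict | None = None) -> None:
        """Write the Q1 (corner) mesh and optional nodal fields as legacy
        ASCII VTK for visualization."""
        pts = self.nodes_p
        lines = ["# vtk DataFile Version 3.0", "poroindent mesh", "ASCII",
                 "DATASET UNSTRUCTURED_GRID",
                 f"POINTS {len(pts)} double"]
        lines += [f"{r:.9g} {z:.9g} 0" for r, z in pts]
        ncell = self.conn_p.shape[0]
        lines.append(f"CELLS {ncell} {5 * ncell}")
        # VTK_QUAD expects counter-clockwise corners
        for c in self.conn_p:
            lines.append(f"4 {c[0]} {c[1]} {c[3]} {c[2]}")
        lines.append(f"CELL_TYPES {ncell}")
        lines += ["9"] * ncell
        if point_data:
            lines.append(f"POINT_DATA {len(pts)}")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    lines.append(f"SCALARS {name} double 1")
                    lines.append("LOOKUP_TABLE default")
                    lines += [f"{v:.9g}" for v in arr]
                else:
                    lines.append(f"VECTORS {name} double")
                    lines += [f"{v[0]:.9g} {v[1]:.9g} 0" for v in arr]
        Path(path).write_text("\n".join(lines) + "\n")


def build_mesh(geometry: Geometry, refinement_level: int = 0, *,
               inner_cells: int = 2, edge_cells: int = 6,
               outer_cells: int = 4, z_cells: int = 8,
               outer_growth: float = 1.7, z_growth: float = 1.45) -> Mesh:
    """Graded tensor mesh: >= 4 radial cells across the punch-edge zone
    [0.8 Ri, 1.2 Ri], geometric coarsening toward the outer radius and the
    bottom.  Deterministic for fixed inputs; each refinement level splits
    every cell in four.  The keyword grading knobs allow coarser/finer base
    layouts while preserving the edge-zone resolution contract."""
    if refinement_level < 0:
        raise ConfigError("refinement_level must be >= 0")
    if edge_cells < 4:
        raise ConfigError("at least 4 cells across the punch-edge zone")
    Ri, Rs, H = geometry.punch_radius, geometry.sample_radius, geometry.sample_height
    if 1.2 * Ri >= Rs:
        raise ConfigError("sample radius too small for the punch-edge zone")

    r = np.concatenate([
        np.linspace(0.0, 0.8 * Ri, inner_cells + 1)[:-1],   # under the punch
        np.linspace(0.8 * Ri, 1.2 * Ri, edge_cells + 1),    # edge zone
        _geometric_breaks(1.2 * Ri, Rs, outer_cells, outer_growth)[1:],
    ])
    # downward coarsening from the indented top surface
    z = H - _geometric_breaks(0.0, H, z_cells, z_growth)[::-1]
    z = np.concatenate([[0.0], z[1:-1], [H]])

    if refinement_level > 0:
        k = 2 ** refinement_level
        r = np.concatenate([np.linspace(a, b, k + 1)[:-1]
                            for a, b in zip(r[:-1], r[1:])] + [[r[-1]]])
        z = np.concatenate([np.linspace(a, b, k + 1)[:-1]
                            for a, b in zip(z[:-1], z[1:])] + [[z[-1]]])

    nr, nz = len(r) - 1, len(z) - 1
    # Q2 grid: midside coordinates interleaved
    ru = np.empty(2 * nr + 1)
    ru[0::2] = r
    ru[1::2] = 0.5 * (r[:-1] + r[1:])
    zu = np.empty(2 * nz + 1)
    zu[0::2] = z
    zu[1::2] = 0.5 * (z[:-1] + z[1:])
    RU, ZU = np.meshgrid(ru, zu, indexing="xy")
    nodes_u = np.column_stack([RU.ravel(), ZU.ravel()])
    RP, ZP = np.meshgrid(r, z, indexing="xy")
    nodes_p = np.column_stack([RP.ravel(), ZP.ravel()])

    nru = 2 * nr + 1
    conn_u = np.empty((nr * nz, 9), dtype=np.int64)
    conn_p = np.empty((nr * nz, 4), dtype=np.int64)
    cell = 0
    for j in range(nz):
        for i in range(nr):
            i0, j0 = 2 * i, 2 * j
            patch = [(j0 + dj) * nru + (i0 + di)
                     for dj in range(3) for di in range(3)]
            conn_u[cell] = patch
            conn_p[cell] = [j * (nr + 1) + i, j * (nr + 1) + i + 1,
                            (j + 1) * (nr + 1) + i, (j + 1) * (nr + 1) + i + 1]
            cell += 1

    return Mesh(r_breaks=r, z_breaks=z, nodes_u=nodes_u, nodes_p=nodes_p,
                conn_u=conn_u, conn_p=conn_p, refinement_level=refinement_level,
                edge_zone=(0.8 * Ri, 1.2 * Ri))


def build_column_mesh(radius: float, height: float, nr: int, nz: int,
                      grade_top: float = 1.0) -> Mesh:
    """Uniform (or top-graded) column mesh for 1D consolidation benchmarks."""
    r = np.linspace(0.0, radius, nr + 1)
    z = height - _geometric_breaks(0.0, height, nz, grade_top)[::-1]
    z[0], z[-1] = 0.0, height
    nr_, nz_ = nr, nz
    ru = np.empty(2 * nr_ + 1)
    ru[0::2] = r
    ru[1::2] = 0.5 * (r[:-1] + r[1:])
    zu = np.empty(2 * nz_ + 1)
    zu[0::2] = z
    zu[1::2] = 0.5 * (z[:-1] + z[1:])
    RU, ZU = np.meshgrid(ru, zu, indexing="xy")
    nodes_u = np.column_stack([RU.ravel(), ZU.ravel()])
    RP, ZP = np.meshgrid(r, z, indexing="xy")
    nodes_p = np.column_stack([RP.ravel(), ZP.ravel()])
    nru = 2 * nr_ + 1
    conn_u = np.empty((nr_ * nz_, 9), dtype=np.int64)
    conn_p = np.empty((nr_ * nz_, 4), dtype=np.int64)
    cell = 0
    for j in range(nz_):
        for i in range(nr_):
            i0, j0 = 2 * i, 2 * j
            conn_u[cell] = [(j0 + dj) * nru + (i0 + di)
                            for dj in range(3) for di in range(3)]
            conn_p[cell] = [j * (nr_ + 1) + i, j * (nr_ + 1) + i + 1,
                            (j + 1) * (nr_ + 1) + i, (j + 1) * (nr_ + 1) + i + 1]
            cell += 1
    return Mesh(r_breaks=r, z_breaks=z, nodes_u=nodes_u, nodes_p=nodes_p,
                conn_u=conn_u, conn_p=conn_p, refinement_level=0)
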