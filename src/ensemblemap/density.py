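"""Real-space density maps on regular 3-D grids.

A :class:`DensityMap` is a scalar field sampled on a rectangular axis-aligned
grid: ``values[i, j, k]`` sits at ``origin + (i, j, k) * spacing`` (angstroms).
Sigma scaling normalizes a map to zero mean / unit standard deviation so that
contour levels quoted "in sigma" are comparable across datasets.

Volumes travel as CCP4/MRC-style binary files (via gemmi); the float ORIGIN
header words carry the box origin, so origins need not be grid-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import DegenerateMapError, FormatError, GridMismatchError, OutOfBoundsError

_SIGMA_TOL = 1e-6


@dataclass
class DensityMap:
    values: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"map values must be 3-D, got ndim={self.values.ndim}")
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise FormatError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_sigma_scaled(self) -> bool:
        """Recomputed from grid statistics: mean 0, sd 1 within 1e-6."""
        return (
            abs(float(self.values.mean())) < _SIGMA_TOL
            and abs(float(self.values.std()) - 1.0) < _SIGMA_TOL
        )

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d] for d in range(3)
        )  # type: ignore[return-value]

    def upper_corner(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) * self.spacing

    def grid_compatible(self, other: "DensityMap", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    def require_compatible(self, other: "DensityMap") -> None:
        if not self.grid_compatible(other):
            raise GridMismatchError("maps do not share origin/spacing/shape")

    def with_values(self, values: np.ndarray) -> "DensityMap":
        return DensityMap(values=values, origin=self.origin.copy(), spacing=self.spacing.copy())

    def copy(self) -> "DensityMap":
        return self.with_values(self.values.copy())

    def voxel_centers_mask_within(self, center: np.ndarray, radius: float) -> np.ndarray:
        """Boolean mask of voxels whose centers lie within ``radius`` A of a point."""
        ax = self.axes()
        d2 = (
            (ax[0] - center[0])[:, None, None] ** 2
            + (ax[1] - center[1])[None, :, None] ** 2
            + (ax[2] - center[2])[None, None, :] ** 2
        )
        return d2 <= radius**2

    def index_to_position(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing


def sigma_scale(density: DensityMap) -> DensityMap:
    """Affine-rescale a map to mean 0, standard deviation 1.

    Monotone and idempotent; raises on a constant map, whose contour levels
    would be meaningless.
    """
    sd = float(density.values.std())
    if sd == 0.0:
        raise DegenerateMapError("constant map cannot be sigma-scaled")
    return density.with_values((density.values - density.values.mean()) / sd)


def interpolate(density: DensityMap, points) -> np.ndarray | float:
    """Trilinear interpolation at one point or an (n, 3) array of points.

    Raises OutOfBoundsError for points outside the grid bounding box.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    interp = RegularGridInterpolator(
        density.axes(), density.values, method="linear", bounds_error=True
    )
    try:
        vals = interp(pts)
    except ValueError as exc:
        raise OutOfBoundsError(f"point outside map bounds: {exc}") from exc
    if np.asarray(points).ndim == 1:
        return float(vals[0])
    return vals


def write_map(density: DensityMap, path) -> None:
    """Write a CCP4/MRC-style volume (float32 data)."""
    if not np.all(np.isfinite(density.values)):
        raise FormatError("map contains non-finite values")
    nx, ny, nz = density.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * density.spacing[0], ny * density.spacing[1], nz * density.spacing[2],
            90.0, 90.0, 90.0,
        )
    )
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    np.asarray(grid, dtype=np.float32)[...] = density.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    """Read a CCP4/MRC-style volume written by :func:`write_map`."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read map {path}: {exc}") from exc
    values = np.array(ccp4.grid, copy=True, dtype=float)
    nx, ny, nz = values.shape
    cell = ccp4.grid.unit_cell
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    return DensityMap(values=values, origin=origin, spacing=spacing)
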