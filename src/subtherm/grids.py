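"""Voxel/subvoxel grid geometry, scalar-field containers and masks.

The acquisition lattice is modelled as one contiguous slab per slice whose
through-plane pitch is slice thickness + inter-slice gap (default
3 mm + 1.5 mm = 4.5 mm); there are no empty-gap cells.  Indexing is 0-based
``(row, col, slice)``, the physical position of a cell is its center, and
extents are half-open.  The subvoxel grid is an integer refinement of the
voxel grid (factor 2 on every axis by default), so each voxel owns exactly
``factor**3`` children and parent/child index mapping is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionParams",
    "VoxelGrid",
    "SubvoxelGrid",
    "MapStack",
    "Mask",
    "refine_grid",
    "average_to_voxels",
    "upsample_to_subvoxels",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class AcquisitionParams:
    """PRFS acquisition constants.

    Parameters
    ----------
    b0 : float
        Main field strength in tesla.
    te : float
        Echo time in seconds.
    alpha : float
        PRFS coefficient in ppm/degC (negative; water default -0.0094).
    gamma_bar : float
        Gyromagnetic ratio gamma/(2*pi) in Hz/T.
    dyn_period : float
        Time between dynamics (one image stack per respiratory cycle), s.
    """

    b0: float
    te: float
    alpha: float = -0.0094
    gamma_bar: float = 42.58e6
    dyn_period: float = 5.0

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.te <= 0:
            raise ValueError(f"te must be positive, got {self.te}")
        if self.alpha >= 0:
            raise ValueError(f"alpha must be negative (ppm/degC), got {self.alpha}")
        if self.gamma_bar <= 0:
            raise ValueError("gamma_bar must be positive")
        if self.dyn_period <= 0:
            raise ValueError("dyn_period must be positive")

    @property
    def rad_per_degc(self) -> float:
        """Phase change per degC: alpha*B0*gamma*TE with alpha in absolute units."""
        return self.alpha * 1e-6 * self.b0 * TWO_PI * self.gamma_bar * self.te

    @property
    def rad_per_ppm(self) -> float:
        """Phase change per ppm of field deviation: B0*gamma*TE*1e-6."""
        return 1e-6 * self.b0 * TWO_PI * self.gamma_bar * self.te


def _as_unit(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"direction must be a 3-vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise ValueError("direction must be nonzero")
    return v / n


@dataclass(frozen=True)
class VoxelGrid:
    """Acquisition voxel lattice.

    ``spacing`` is (d_row, d_col, d_slice_eff) in mm where the effective
    slice spacing already includes the inter-slice gap.  ``b0_dir`` is the
    unit B0 direction expressed in grid (row, col, slice) coordinates;
    the default +row axis matches the usual bottom-to-top display.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    b0_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three counts >= 1, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        unit = _as_unit(self.b0_dir)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "b0_dir", tuple(unit))

    @property
    def b0_unit(self) -> np.ndarray:
        return np.asarray(self.b0_dir, dtype=float)

    @property
    def cell_volume(self) -> float:
        """Cell volume in mm^3."""
        return float(np.prod(self.spacing))

    def cell_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (mm) of cells given integer (..., 3) indices."""
        idx = np.asarray(indices, dtype=float)
        return (idx + 0.5) * np.asarray(self.spacing)


@dataclass(frozen=True)
class SubvoxelGrid:
    """Integer refinement of a :class:`VoxelGrid` (same extents, finer cells)."""

    parent: VoxelGrid
    factor: int = 2

    def __post_init__(self) -> None:
        if int(self.factor) < 1:
            raise ValueError(f"refinement factor must be >= 1, got {self.factor}")
        object.__setattr__(self, "factor", int(self.factor))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(s * self.factor for s in self.parent.shape)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(s / self.factor for s in self.parent.spacing)

    @property
    def b0_dir(self) -> tuple[float, float, float]:
        return self.parent.b0_dir

    @property
    def b0_unit(self) -> np.ndarray:
        return self.parent.b0_unit

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def cell_centers(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return (idx + 0.5) * np.asarray(self.spacing)

    def children_of(self, voxel_indices: np.ndarray) -> np.ndarray:
        """Subvoxel indices of the factor**3 children of each voxel.

        Parameters
        ----------
        voxel_indices : (n, 3) integer array

        Returns
        -------
        (n, factor**3, 3) integer array of subvoxel indices.
        """
        vox = np.asarray(voxel_indices, dtype=int)
        f = self.factor
        offs = np.stack(
            np.meshgrid(np.arange(f), np.arange(f), np.arange(f), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return vox[:, None, :] * f + offs[None, :, :]


Grid = VoxelGrid | SubvoxelGrid


def refine_grid(grid: VoxelGrid, factor: int = 2) -> SubvoxelGrid:
    """Refine a voxel grid by an integer factor on every axis.

    Factor 1 returns a grid geometrically identical to the input.
    """
    if int(factor) < 1:
        raise ValueError(f"refinement factor must be >= 1, got {factor}")
    return SubvoxelGrid(parent=grid, factor=int(factor))


_UNITS = {"degC", "rad", "ppm", "1"}


@dataclass
class MapStack:
    """Scalar field over a grid, optionally with a leading time axis.

    ``values`` has spatial shape equal to ``grid.shape`` (3D) or a leading
    dynamics axis (4D, time first).  ``unit`` is one of ``degC``, ``rad``,
    ``ppm`` or ``1`` (dimensionless).
    """

    grid: Grid
    values: np.ndarray
    unit: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}; expected one of {_UNITS}")
        spatial = self.values.shape[-3:]
        if self.values.ndim not in (3, 4) or spatial != tuple(self.grid.shape):
            raise ValueError(
                f"values of shape {self.values.shape} do not match grid shape {self.grid.shape}"
            )

    @property
    def has_time(self) -> bool:
        return self.values.ndim == 4

    @property
    def n_dynamics(self) -> int:
        return self.values.shape[0] if self.has_time else 1


@dataclass
class Mask:
    """Boolean mask over a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask of shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer indices of true cells."""
        return np.argwhere(self.values)


def _average_blocks(values: np.ndarray, factor: int) -> np.ndarray:
    # spatial axes are the last three; lead axes (time) pass through untouched
    lead = values.shape[:-3]
    nr, nc, ns = (s // factor for s in values.shape[-3:])
    f = factor
    reshaped = values.reshape(*lead, nr, f, nc, f, ns, f)
    return reshaped.mean(axis=(-5, -3, -1))


def average_to_voxels(sub_field: MapStack) -> MapStack:
    """Average a subvoxel field down to its parent voxel grid.

    Each voxel value is the arithmetic mean of its ``factor**3`` children;
    the operation is linear and conserves the grand mean.
    """
    grid = sub_field.grid
    if not isinstance(grid, SubvoxelGrid):
        raise ValueError("average_to_voxels requires a field on a SubvoxelGrid")
    out = _average_blocks(sub_field.values, grid.factor)
    return MapStack(grid=grid.parent, values=out, unit=sub_field.unit)


def upsample_to_subvoxels(vox_field: MapStack, subgrid: SubvoxelGrid) -> MapStack:
    """Replicate each voxel value into its children (right inverse of averaging)."""
    if subgrid.parent.shape != tuple(vox_field.grid.shape):
        raise ValueError("subgrid is not a refinement of the field's grid")
    f = subgrid.factor
    vals = vox_field.values
    out = np.repeat(np.repeat(np.repeat(vals, f, axis=-3), f, axis=-2), f, axis=-1)
    return MapStack(grid=subgrid, values=out, unit=vox_field.unit)
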