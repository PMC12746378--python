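"""Dipole kernel, susceptibility-to-field convolution, and the forward operator.

A point magnetic dipole in a field along the unit vector ``n`` perturbs the
relative difference field (RDF) at offset ``x`` by

    d(x) = (1 / 4 pi) * (3 (x.n)^2 - |x|^2) / |x|^5        (d(0) = 0),

positive along the field axis, negative in the equatorial plane, and zero at
the magic angle (cos^2 theta = 1/3).  A discrete susceptibility distribution
chi (ppm, one value per subvoxel) induces RDF = d (x) chi, evaluated here as a
zero-padded FFT convolution of the analytic kernel sampled at cell-center
offsets and scaled by the cell volume (point-dipole discretization; the
subvoxel refinement is the remedy for near-field discretization error).

The composed linear operator A maps candidate-subvoxel chi to the weighted,
ROI-masked voxel RDF: convolution on the subvoxel grid, block-averaging to
voxel resolution, per-voxel weighting, and cropping to the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .grids import Grid, MapStack, Mask, SubvoxelGrid, VoxelGrid, average_to_voxels

__all__ = [
    "eval_kernel",
    "DipoleKernel",
    "SusceptibilityMap",
    "ForwardOperator",
    "forward_field",
    "voxel_field",
    "assemble_operator",
]

CHI_BOUNDS_PPM = (0.0, 10.0)


def eval_kernel(offsets, n) -> np.ndarray:
    """Analytic dipole kernel density (mm^-3) at one or more offsets (mm).

    Returns exactly 0 at zero offset.  ``n`` must be a unit vector.
    """
    n = np.asarray(n, dtype=float)
    if n.shape != (3,) or abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("n must be a unit 3-vector")
    x = np.asarray(offsets, dtype=float)
    scalar = x.ndim == 1
    x = np.atleast_2d(x)
    r2 = np.einsum("...i,...i->...", x, x)
    xn = x @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (3.0 * xn**2 - r2) / (4.0 * np.pi * r2**2.5)
    out = np.where(r2 == 0.0, 0.0, out)
    return float(out[0]) if scalar else out


def _padded_offsets(n_cells: int, pad: int, spacing: float) -> np.ndarray:
    # circular offset arrangement: index o -> o for o < n, o - pad otherwise
    idx = np.arange(pad)
    return np.where(idx < n_cells, idx, idx - pad) * spacing


class DipoleKernel:
    """Discrete dipole kernel on a grid, with a cached padded FFT.

    Kernel samples are the analytic density at cell-center offsets times the
    cell volume (dimensionless); the zero-offset sample is 0.  Padding to
    twice the grid size per axis makes the circular FFT convolution equal to
    the linear (zero-padded) convolution.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        self.b0_unit = grid.b0_unit
        shape = tuple(grid.shape)
        spacing = tuple(grid.spacing)
        self._pad = tuple(2 * s for s in shape)
        offs = [
            _padded_offsets(shape[a], self._pad[a], spacing[a]) for a in range(3)
        ]
        ox, oy, oz = np.meshgrid(*offs, indexing="ij")
        pts = np.stack([ox, oy, oz], axis=-1)
        self.values = eval_kernel(pts.reshape(-1, 3), self.b0_unit).reshape(
            self._pad
        ) * grid.cell_volume
        self._fft = np.fft.rfftn(self.values, axes=(0, 1, 2))

    def convolve(self, field: np.ndarray) -> np.ndarray:
        """Linear convolution of the kernel with a field on the same grid."""
        shape = tuple(self.grid.shape)
        if field.shape != shape:
            raise ValueError(f"field shape {field.shape} does not match grid {shape}")
        f = np.fft.rfftn(field, s=self._pad, axes=(0, 1, 2))
        out = np.fft.irfftn(f * self._fft, s=self._pad, axes=(0, 1, 2))
        return out[: shape[0], : shape[1], : shape[2]]


@dataclass
class SusceptibilityMap:
    """Subvoxel susceptibility variation chi_s (ppm), nonzero only on its support."""

    grid: SubvoxelGrid
    values: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("chi values do not match the subvoxel grid shape")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=bool)
            if self.support.shape != self.values.shape:
                raise ValueError("support mask shape mismatch")
            if np.any(self.values[~self.support] != 0.0):
                raise ValueError("chi must be zero outside its support mask")


def forward_field(chi: SusceptibilityMap, kernel: DipoleKernel) -> MapStack:
    """RDF (ppm) induced on the subvoxel grid by a susceptibility map."""
    if kernel.grid is not chi.grid and tuple(kernel.grid.shape) != tuple(chi.grid.shape):
        raise ValueError("chi and kernel must share a grid")
    rdf = kernel.convolve(chi.values)
    return MapStack(grid=chi.grid, values=rdf, unit="ppm")


@dataclass
class ForwardOperator:
    """Dense matrix form of A = M_ROI . W . P . D_A . D_s.

    Columns correspond 1:1 to candidate subvoxels (``cand_indices``), rows to
    ROI voxels (``roi_indices``).  Applying the matrix to a chi vector (ppm)
    yields the weighted, masked voxel RDF.
    """

    matrix: np.ndarray
    cand_indices: np.ndarray  # (n_cand, 3) subvoxel indices
    roi_indices: np.ndarray  # (n_roi, 3) voxel indices
    subgrid: SubvoxelGrid

    def apply(self, chi_vec: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(chi_vec, dtype=float)

    def chi_map(self, chi_vec: np.ndarray, clip_tiny: float = 0.0) -> SusceptibilityMap:
        """Scatter a candidate-ordered chi vector into a full subvoxel map."""
        full = np.zeros(self.subgrid.shape, dtype=float)
        vals = np.asarray(chi_vec, dtype=float)
        if clip_tiny > 0:
            vals = np.where(np.abs(vals) < clip_tiny, 0.0, vals)
        full[tuple(self.cand_indices.T)] = vals
        support = np.zeros(self.subgrid.shape, dtype=bool)
        support[tuple(self.cand_indices.T)] = True
        return SusceptibilityMap(grid=self.subgrid, values=full, support=support)


def _candidate_subvoxels(
    subgrid: SubvoxelGrid, bubble_mask: Mask, subslices: np.ndarray | None
) -> np.ndarray:
    """Subvoxel indices whose parent voxel is in the bubble mask, optionally
    restricted to a set of subslice indices."""
    vox_idx = bubble_mask.indices()
    if vox_idx.size == 0:
        raise ValueError("bubble mask is empty: no candidate subvoxels")
    children = subgrid.children_of(vox_idx).reshape(-1, 3)
    if subslices is not None:
        keep = np.isin(children[:, 2], np.asarray(subslices, dtype=int))
        children = children[keep]
        if children.size == 0:
            raise ValueError("no candidate subvoxels in the requested subslices")
    return children


def assemble_operator(
    subgrid: SubvoxelGrid,
    bubble_mask: Mask,
    roi_mask: Mask,
    weights: np.ndarray,
    candidate_subslices: np.ndarray | None = None,
    roi_slices: np.ndarray | None = None,
    chunk: int = 64,
) -> ForwardOperator:
    """Assemble the dense forward operator.

    Parameters
    ----------
    subgrid : SubvoxelGrid
        Refined grid on which chi lives.
    bubble_mask, roi_mask : Mask
        Disjoint voxel masks: candidate source voxels and data voxels.
    weights : ndarray
        Per-voxel nonnegative weights (1/ppm), zero outside the ROI.
    candidate_subslices : array of int, optional
        Restrict candidates to these subslice indices (per-slice correction).
    roi_slices : array of int, optional
        Restrict data rows to ROI voxels in these voxel slices.
    chunk : int
        Candidate block size for memory-bounded assembly.
    """
    voxgrid = subgrid.parent
    if tuple(bubble_mask.grid.shape) != tuple(voxgrid.shape) or tuple(
        roi_mask.grid.shape
    ) != tuple(voxgrid.shape):
        raise ValueError("masks must live on the parent voxel grid")
    if np.any(bubble_mask.values & roi_mask.values):
        raise ValueError("bubble and ROI masks must be disjoint")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != tuple(voxgrid.shape):
        raise ValueError("weights shape does not match the voxel grid")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(weights[~roi_mask.values] != 0):
        raise ValueError("weights must be zero outside the ROI")

    roi_idx = roi_mask.indices()
    if roi_slices is not None:
        roi_idx = roi_idx[np.isin(roi_idx[:, 2], np.asarray(roi_slices, dtype=int))]
    if roi_idx.size == 0:
        raise ValueError("ROI mask selects no data voxels")

    cand_idx = _candidate_subvoxels(subgrid, bubble_mask, candidate_subslices)

    # Row i, column j: w_i * mean over voxel-i children of d(x_child - x_cand) * V_sub.
    child_idx = subgrid.children_of(roi_idx)  # (n_roi, f^3, 3)
    child_pos = subgrid.cell_centers(child_idx)  # (n_roi, f^3, 3)
    cand_pos = subgrid.cell_centers(cand_idx)  # (n_cand, 3)
    w = weights[tuple(roi_idx.T)]
    n_roi, n_child = child_pos.shape[:2]
    n_cand = cand_pos.shape[0]
    vol = subgrid.cell_volume
    n = subgrid.b0_unit

    matrix = np.empty((n_roi, n_cand), dtype=float)
    for j0 in range(0, n_cand, chunk):
        block = cand_pos[j0 : j0 + chunk]  # (b, 3)
        diff = child_pos[:, :, None, :] - block[None, None, :, :]
        k = eval_kernel(diff.reshape(-1, 3), n).reshape(n_roi, n_child, len(block))
        matrix[:, j0 : j0 + len(block)] = k.mean(axis=1) * vol
    matrix *= w[:, None]

    return ForwardOperator(
        matrix=matrix, cand_indices=cand_idx, roi_indices=roi_idx, subgrid=subgrid
    )


def voxel_field(chi: SusceptibilityMap, kernel: DipoleKernel) -> MapStack:
    """Convolve and average: the induced voxel-resolution RDF (ppm)."""
    return average_to_voxels(forward_field(chi, kernel))


@lru_cache(maxsize=4)
def _cached_kernel(grid: Grid) -> DipoleKernel:
    return DipoleKernel(grid)


def get_kernel(grid: Grid) -> DipoleKernel:
    """Kernel for a grid, cached (the padded FFT dominates build time)."""
    return _cached_kernel(grid)
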