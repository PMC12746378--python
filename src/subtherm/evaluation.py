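"""Volumetric overlap and geometric agreement between lesion masks.

Given a source segmentation S (e.g. the thermal-dose lesion) and a reference
T (e.g. a manually segmented post-procedural lesion):

    Dice = 2|S n T| / (|S| + |T|)
    Total Overlap (TO) = |S n T| / |T|
    False Negative Rate (FNR) = |T \\ S| / |T| = 1 - TO

Geometric agreement uses the lesion volume (voxel count times voxel volume)
and the extents of the voxel-center point cloud along its three principal
(PCA) axes, in descending order.  Registration between spaces is out of
scope; a user-supplied affine can resample the source mask with
nearest-neighbor interpolation before comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Mask

__all__ = ["LesionComparison", "overlap_metrics", "geometry_metrics", "resample_mask"]


@dataclass(frozen=True)
class LesionComparison:
    dice: float
    total_overlap: float
    fnr: float
    n_source: int
    n_target: int
    n_intersection: int


def overlap_metrics(source: Mask, target: Mask) -> LesionComparison:
    """Dice, total overlap and false-negative rate of S against reference T."""
    if tuple(source.grid.shape) != tuple(target.grid.shape):
        raise ValueError("masks must live on the same grid")
    s, t = source.values, target.values
    ns, nt = int(s.sum()), int(t.sum())
    ni = int((s & t).sum())
    if nt == 0:
        if ns == 0:
            warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
            return LesionComparison(1.0, float("nan"), float("nan"), 0, 0, 0)
        raise ValueError("reference (target) mask is empty: TO/FNR undefined")
    dice = 2.0 * ni / (ns + nt) if (ns + nt) else 1.0
    to = ni / nt
    fnr = (nt - ni) / nt
    return LesionComparison(dice, to, fnr, ns, nt, ni)


def geometry_metrics(mask: Mask) -> tuple[float, tuple[float, float, float]]:
    """Lesion volume (cm^3) and principal-axis extents (mm, descending).

    Extents are center-to-center ranges of the voxel-center point cloud
    projected on its principal directions; a single voxel has extents 0.
    """
    idx = mask.indices()
    if idx.shape[0] == 0:
        raise ValueError("mask is empty")
    spacing = np.asarray(mask.grid.spacing)
    volume_cm3 = idx.shape[0] * float(np.prod(spacing)) / 1000.0
    pts = idx * spacing
    centered = pts - pts.mean(axis=0)
    if idx.shape[0] == 1:
        return volume_cm3, (0.0, 0.0, 0.0)
    # principal directions of the point cloud via SVD of the centered coords
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    proj = centered @ vt.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    extents = tuple(float(e) for e in sorted(extents, reverse=True))
    return volume_cm3, extents


def resample_mask(source: Mask, affine: np.ndarray, target_grid) -> Mask:
    """Nearest-neighbor resample of a mask under a voxel-to-voxel affine.

    ``affine`` is a 4x4 matrix mapping target voxel indices to source voxel
    indices (homogeneous coordinates).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be a 4x4 matrix")
    out = ndimage.affine_transform(
        source.values.astype(float),
        affine[:3, :3],
        offset=affine[:3, 3],
        output_shape=tuple(target_grid.shape),
        order=0,
        mode="constant",
        cval=0.0,
    )
    return Mask(grid=target_grid, values=out > 0.5)
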