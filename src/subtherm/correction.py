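"""Boiling-artifact correction: prior image, masks, weights, bounded inversion.

The correction estimates a subvoxel susceptibility distribution chi_s that
reproduces the stable component of a boiling-induced dipole artifact, then
subtracts the simulated artifact from the measured temperature series.

Pipeline per data slice z:

1.  Prior image: mean of five dynamics after artifact stabilization minus the
    mean of five dynamics before its appearance — a temperature image
    dominated by the artifact.
2.  Masks: the bubble mask M_b marks candidate source voxels inside the probe
    signal void; the ROI mask M_ROI is the probe line dilated in-plane by
    nine voxels, with M_b excluded (the two are disjoint by construction).
3.  Weights: per ROI voxel, SNR = mean magnitude over the "during" window
    divided by the temporal std of the pre-heating magnitude; the phase noise
    is approximately 1/SNR rad, so W = SNR * B0*gamma*TE*1e-6 converts to an
    inverse RDF standard deviation (1/ppm).
4.  Bounded least squares: minimize ||A chi - b||_2 with chi in [0, 10] ppm,
    where b is the weighted masked prior in RDF units and A is the composed
    forward operator.  Candidates for slice z live in the six subslices of
    voxel slices z-1, z, z+1 (central plus adjacent slabs).
5.  The forward-simulated RDF of chi* is converted to degC via 1/alpha and
    subtracted from every dynamic in the correction interval; the subtracted
    artifact is temporally constant.

An "all_slices" mode solves one inverse problem for the whole stack instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import lsq_linear
from skimage.morphology import disk

from .dipole import (
    CHI_BOUNDS_PPM,
    DipoleKernel,
    ForwardOperator,
    SusceptibilityMap,
    assemble_operator,
    voxel_field,
)
from .grids import AcquisitionParams, MapStack, Mask, SubvoxelGrid, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "build_prior",
    "build_bubble_mask",
    "build_roi_mask",
    "compute_weights",
    "solve_susceptibility",
    "correct_slice",
    "correct_stack",
    "CorrectionResult",
]

DEFAULT_N_AVG = 5
DEFAULT_DILATION_VOX = 9
DEFAULT_VOID_FRACTION = 0.5
MAX_SNR = 1e6


def build_prior(
    series: MapStack, onset_idx: int, during_idx: int, n_avg: int = DEFAULT_N_AVG
) -> MapStack:
    """Prior artifact image: mean("during" window) - mean("before" window).

    The "before" window is the ``n_avg`` dynamics ending at ``onset_idx - 1``;
    the "during" window is the ``n_avg`` dynamics starting at ``during_idx``.
    """
    if not series.has_time:
        raise ValueError("build_prior requires a time-resolved series")
    n_dyn = series.n_dynamics
    if n_avg < 1:
        raise ValueError("n_avg must be >= 1")
    if onset_idx < n_avg:
        raise ValueError(f"need onset_idx >= n_avg ({n_avg}), got {onset_idx}")
    if during_idx < onset_idx:
        raise ValueError("during window must not precede the onset")
    if during_idx + n_avg > n_dyn:
        raise ValueError("during window extends past the end of the series")
    before = series.values[onset_idx - n_avg : onset_idx].mean(axis=0)
    during = series.values[during_idx : during_idx + n_avg].mean(axis=0)
    return MapStack(grid=series.grid, values=during - before, unit=series.unit)


def _per_slice_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """2D (in-plane) binary dilation of each slice with a Euclidean disk."""
    if radius < 1:
        return mask.copy()
    selem = disk(radius)
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            out[:, :, z] = ndimage.binary_dilation(mask[:, :, z], structure=selem)
    return out


def build_bubble_mask(
    magnitude_before: MapStack,
    probe_line: Mask,
    void_fraction: float = DEFAULT_VOID_FRACTION,
    neighborhood_vox: int = 2,
) -> Mask:
    """Bubble mask M_b: signal-void voxels on or adjacent to the probe line.

    A voxel belongs to M_b when it lies within one voxel of the probe line
    and its "before"-state magnitude falls below ``void_fraction`` times the
    median magnitude over the probe neighborhood (line dilated in-plane by
    ``neighborhood_vox``).  Raises if no voxel qualifies (supply a manual
    mask in that case).
    """
    if probe_line.count == 0:
        raise ValueError("probe line mask is empty")
    mag = magnitude_before.values
    if mag.ndim != 3:
        raise ValueError("magnitude_before must be a single (3D) dynamic")
    neigh = _per_slice_dilate(probe_line.values, neighborhood_vox)
    median = float(np.median(mag[neigh]))
    near_line = _per_slice_dilate(probe_line.values, 1)
    mb = near_line & (mag < void_fraction * median)
    if not mb.any():
        raise ValueError(
            "no signal-void voxels found along the probe line; "
            "supply a manual bubble mask"
        )
    return Mask(grid=probe_line.grid, values=mb)


def build_roi_mask(
    probe_line: Mask, bubble_mask: Mask, dilation_vox: int = DEFAULT_DILATION_VOX
) -> Mask:
    """ROI mask M_ROI: per-slice in-plane dilation of the probe line, minus M_b."""
    if probe_line.count == 0:
        raise ValueError("probe line mask is empty")
    roi = _per_slice_dilate(probe_line.values, dilation_vox) & ~bubble_mask.values
    if not roi.any():
        raise ValueError("ROI mask is empty after excluding the bubble mask")
    return Mask(grid=probe_line.grid, values=roi)


def compute_weights(
    magnitude: MapStack,
    preheat_window: tuple[int, int],
    during_window: tuple[int, int],
    roi: Mask,
    params: AcquisitionParams,
    max_snr: float = MAX_SNR,
) -> np.ndarray:
    """Per-voxel inverse RDF standard deviation (1/ppm), zero outside the ROI.

    SNR = mean(|S|) over the during window / temporal std(|S|) over the
    pre-heating window; sigma_phase ~ 1/SNR rad; W = SNR * B0*gamma*TE*1e-6.
    Voxels with zero temporal std get the capped SNR (warning logged).
    """
    if not magnitude.has_time:
        raise ValueError("compute_weights requires a time-resolved magnitude stack")
    p0, p1 = preheat_window
    d0, d1 = during_window
    n_dyn = magnitude.n_dynamics
    if not (0 <= p0 < p1 <= n_dyn) or not (0 <= d0 < d1 <= n_dyn):
        raise ValueError("windows must be nonempty index ranges within the series")
    if d1 - d0 < 2 and p1 - p0 < 2:
        raise ValueError("windows too short to estimate noise")
    mean_during = magnitude.values[d0:d1].mean(axis=0)
    std_pre = magnitude.values[p0:p1].std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean_during / std_pre
    n_flat = int(np.sum((std_pre == 0) & roi.values))
    if n_flat:
        logger.warning(
            "%d ROI voxels with zero temporal magnitude std; SNR capped at %g",
            n_flat,
            max_snr,
        )
    snr = np.where(np.isfinite(snr), snr, max_snr)
    snr = np.clip(snr, 0.0, max_snr)
    weights = snr * params.rad_per_ppm
    weights[~roi.values] = 0.0
    return weights


@dataclass
class SolveInfo:
    """Diagnostics from one bounded least-squares solve."""

    residual_norm: float
    data_norm: float
    n_iterations: int
    status: int
    skipped: bool = False


def solve_susceptibility(
    operator: ForwardOperator,
    b: np.ndarray,
    bounds: tuple[float, float] = CHI_BOUNDS_PPM,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[SusceptibilityMap, SolveInfo]:
    """Minimize ||A chi - b||_2 subject to elementwise bounds (ppm).

    chi = 0 is always feasible, so the solution residual never exceeds
    ||b||.  A zero data vector short-circuits to chi = 0.
    """
    b = np.asarray(b, dtype=float)
    if b.shape != (operator.matrix.shape[0],):
        raise ValueError(
            f"data vector length {b.shape} does not match operator rows "
            f"{operator.matrix.shape[0]}"
        )
    b_norm = float(np.linalg.norm(b))
    n_cand = operator.matrix.shape[1]
    if b_norm == 0.0:
        chi = operator.chi_map(np.zeros(n_cand))
        return chi, SolveInfo(0.0, 0.0, 0, 0, skipped=True)
    res = lsq_linear(
        operator.matrix,
        b,
        bounds=bounds,
        method="bvls",
        tol=tol,
        max_iter=max(max_iter, n_cand + 1),
    )
    if res.status < 0:
        raise RuntimeError(
            f"bounded least-squares solver failed (status {res.status}): {res.message}"
        )
    chi_vec = np.clip(res.x, bounds[0], bounds[1])
    chi = operator.chi_map(chi_vec)
    resid = float(np.linalg.norm(operator.apply(chi_vec) - b))
    return chi, SolveInfo(resid, b_norm, int(res.nit), int(res.status))


def candidate_subslices_for_slice(
    slice_idx: int, n_slices: int, factor: int, adjacency: int = 1
) -> np.ndarray:
    """Subslice indices of voxel slices [z-adjacency, z+adjacency], clipped.

    With factor 2 and adjacency 1 this is the six-subslice slab (two central
    plus four adjacent subslices); boundary slices drop missing neighbors.
    """
    lo = max(0, slice_idx - adjacency)
    hi = min(n_slices - 1, slice_idx + adjacency)
    return np.concatenate(
        [np.arange(z * factor, (z + 1) * factor) for z in range(lo, hi + 1)]
    )


@dataclass
class CorrectionResult:
    """Output of an artifact correction run."""

    corrected: MapStack  # time-resolved temperature series (degC)
    artifact: MapStack  # temporally constant simulated artifact (degC, voxel grid)
    chi: SusceptibilityMap  # composite subvoxel susceptibility (ppm)
    onset_idx: int
    end_idx: int
    slice_info: dict[int, SolveInfo] = field(default_factory=dict)


def _subtract_artifact(
    series: MapStack, artifact: np.ndarray, onset_idx: int, end_idx: int
) -> MapStack:
    out = series.values.copy()
    out[onset_idx:end_idx] -= artifact[None, ...]
    return MapStack(grid=series.grid, values=out, unit="degC")


def correct_slice(
    series: MapStack,
    slice_idx: int,
    bubble_mask: Mask,
    roi_mask: Mask,
    weights: np.ndarray,
    kernel: DipoleKernel,
    params: AcquisitionParams,
    onset_idx: int,
    during_idx: int | None = None,
    end_idx: int | None = None,
    n_avg: int = DEFAULT_N_AVG,
    adjacency: int = 1,
    bounds: tuple[float, float] = CHI_BOUNDS_PPM,
    stabilization_lag: int = 5,
    solver_tol: float = 1e-8,
) -> CorrectionResult:
    """Correct one data slice with a multi-slice (slab) susceptibility estimate.

    Data rows are the ROI voxels of ``slice_idx``; candidate subvoxels live in
    the subslices of voxel slices ``slice_idx +- adjacency`` intersected with
    the bubble mask.  The subtracted artifact (restricted to this slice) is
    identical for every corrected dynamic.
    """
    subgrid = kernel.grid
    if not isinstance(subgrid, SubvoxelGrid):
        raise ValueError("kernel must be built on a SubvoxelGrid")
    n_dyn = series.n_dynamics
    if during_idx is None:
        during_idx = onset_idx + stabilization_lag
    if end_idx is None:
        end_idx = n_dyn
    if not (onset_idx < end_idx <= n_dyn):
        raise ValueError("need onset_idx < end_idx <= number of dynamics")

    prior = build_prior(series, onset_idx, during_idx, n_avg=n_avg)
    n_slices = series.grid.shape[2]
    subslices = candidate_subslices_for_slice(
        slice_idx, n_slices, subgrid.factor, adjacency
    )
    operator = assemble_operator(
        subgrid,
        bubble_mask,
        roi_mask,
        weights,
        candidate_subslices=subslices,
        roi_slices=np.array([slice_idx]),
    )
    prior_rdf = prior.values * params.alpha  # degC -> ppm
    b = weights[tuple(operator.roi_indices.T)] * prior_rdf[tuple(operator.roi_indices.T)]
    chi, info = solve_susceptibility(operator, b, bounds=bounds, tol=solver_tol)

    rdf_vox = voxel_field(chi, kernel)
    artifact_full = rdf_vox.values / params.alpha  # ppm -> degC
    artifact = np.zeros_like(artifact_full)
    artifact[:, :, slice_idx] = artifact_full[:, :, slice_idx]

    corrected = _subtract_artifact(series, artifact, onset_idx, end_idx)
    return CorrectionResult(
        corrected=corrected,
        artifact=MapStack(grid=series.grid, values=artifact, unit="degC"),
        chi=chi,
        onset_idx=onset_idx,
        end_idx=end_idx,
        slice_info={slice_idx: info},
    )


def correct_stack(
    series: MapStack,
    bubble_mask: Mask,
    roi_mask: Mask,
    weights: np.ndarray,
    kernel: DipoleKernel,
    params: AcquisitionParams,
    onset_idx: int,
    during_idx: int | None = None,
    end_idx: int | None = None,
    mode: str = "per_slice",
    n_avg: int = DEFAULT_N_AVG,
    adjacency: int = 1,
    bounds: tuple[float, float] = CHI_BOUNDS_PPM,
    stabilization_lag: int = 5,
    solver_tol: float = 1e-8,
) -> CorrectionResult:
    """Correct a multi-slice series.

    ``per_slice`` (default): one independent inverse problem per data slice
    with ROI voxels — slice results do not depend on processing order.  The
    composite chi map records, for each slice, the solved values on that
    slice's own (central) subslices.  ``all_slices``: a single inverse
    problem with every ROI voxel as data and every bubble subvoxel as a
    candidate.
    """
    subgrid = kernel.grid
    if not isinstance(subgrid, SubvoxelGrid):
        raise ValueError("kernel must be built on a SubvoxelGrid")
    n_dyn = series.n_dynamics
    if during_idx is None:
        during_idx = onset_idx + stabilization_lag
    if end_idx is None:
        end_idx = n_dyn
    if not (onset_idx < end_idx <= n_dyn):
        raise ValueError("need onset_idx < end_idx <= number of dynamics")

    if mode == "all_slices":
        prior = build_prior(series, onset_idx, during_idx, n_avg=n_avg)
        operator = assemble_operator(subgrid, bubble_mask, roi_mask, weights)
        prior_rdf = prior.values * params.alpha
        rows = tuple(operator.roi_indices.T)
        b = weights[rows] * prior_rdf[rows]
        chi, info = solve_susceptibility(operator, b, bounds=bounds, tol=solver_tol)
        artifact = voxel_field(chi, kernel).values / params.alpha
        corrected = _subtract_artifact(series, artifact, onset_idx, end_idx)
        return CorrectionResult(
            corrected=corrected,
            artifact=MapStack(grid=series.grid, values=artifact, unit="degC"),
            chi=chi,
            onset_idx=onset_idx,
            end_idx=end_idx,
            slice_info={-1: info},
        )
    if mode != "per_slice":
        raise ValueError(f"unknown correction mode {mode!r}")

    data_slices = sorted(set(roi_mask.indices()[:, 2].tolist()))
    artifact = np.zeros(series.grid.shape, dtype=float)
    chi_composite = np.zeros(subgrid.shape, dtype=float)
    support = np.zeros(subgrid.shape, dtype=bool)
    infos: dict[int, SolveInfo] = {}
    f = subgrid.factor
    bubble_slices = set(bubble_mask.indices()[:, 2].tolist())
    for z in data_slices:
        # a slice with no bubble voxels within reach has nothing to estimate
        if not any(abs(z - bz) <= adjacency for bz in bubble_slices):
            infos[z] = SolveInfo(0.0, 0.0, 0, 0, skipped=True)
            continue
        res = correct_slice(
            series,
            z,
            bubble_mask,
            roi_mask,
            weights,
            kernel,
            params,
            onset_idx,
            during_idx=during_idx,
            end_idx=end_idx,
            n_avg=n_avg,
            adjacency=adjacency,
            bounds=bounds,
            stabilization_lag=stabilization_lag,
            solver_tol=solver_tol,
        )
        artifact[:, :, z] = res.artifact.values[:, :, z]
        # composite chi: keep each slice's solution on its own central subslices
        sl = slice(z * f, (z + 1) * f)
        chi_composite[:, :, sl] = res.chi.values[:, :, sl]
        support[:, :, sl] |= res.chi.support[:, :, sl]
        infos[z] = res.slice_info[z]

    chi = SusceptibilityMap(grid=subgrid, values=chi_composite, support=support)
    corrected = _subtract_artifact(series, artifact, onset_idx, end_idx)
    return CorrectionResult(
        corrected=corrected,
        artifact=MapStack(grid=series.grid, values=artifact, unit="degC"),
        chi=chi,
        onset_idx=onset_idx,
        end_idx=end_idx,
        slice_info=infos,
    )
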