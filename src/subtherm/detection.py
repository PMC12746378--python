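"""Automatic onset detection for boiling-induced artifacts.

A boiling artifact shows up as two strongly negative temperature lobes
aligned with the B0 direction on either side of the probe.  The detector
counts, per dynamic, the ROI voxels colder than a threshold that sit inside
the double cone along +-B0 from the probe line, and reports the first
dynamic at which that count stays at or above ``min_count`` for
``consecutive`` dynamics.  Returning ``None`` (no onset) is a valid result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MapStack, Mask

__all__ = ["DetectionParams", "detect_onset", "lobe_counts"]


@dataclass(frozen=True)
class DetectionParams:
    neg_threshold: float = -10.0  # degC; voxels colder than this count
    min_count: int = 5  # voxels required per dynamic
    consecutive: int = 2  # dynamics the count must persist

    def __post_init__(self) -> None:
        if self.neg_threshold >= 0:
            raise ValueError("neg_threshold must be negative")
        if self.min_count < 1 or self.consecutive < 1:
            raise ValueError("min_count and consecutive must be >= 1")


def _lobe_mask(roi: Mask, probe_line: Mask, b0_dir: np.ndarray) -> np.ndarray:
    """ROI voxels lying in the half-spaces along +-B0 from the probe line.

    A voxel qualifies when its displacement (mm) from the nearest probe-line
    voxel is dominated by the component along B0 (a 90-degree double cone,
    matching where the negative dipole lobes form).
    """
    roi_idx = roi.indices()
    probe_idx = probe_line.indices()
    if probe_idx.shape[0] == 0:
        raise ValueError("probe line mask is empty")
    spacing = np.asarray(roi.grid.spacing)
    roi_pos = roi_idx * spacing
    probe_pos = probe_idx * spacing
    # displacement to the nearest probe voxel (probe lines are short)
    d2 = ((roi_pos[:, None, :] - probe_pos[None, :, :]) ** 2).sum(axis=2)
    disp = roi_pos - probe_pos[np.argmin(d2, axis=1)]
    along = disp @ b0_dir
    perp = disp - along[:, None] * b0_dir[None, :]
    keep = np.abs(along) >= np.linalg.norm(perp, axis=1)
    out = np.zeros(roi.grid.shape, dtype=bool)
    out[tuple(roi_idx[keep].T)] = True
    return out


def lobe_counts(
    series: MapStack,
    roi: Mask,
    probe_line: Mask,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Per-dynamic count of sub-threshold voxels in the +-B0 lobes."""
    if not series.has_time:
        raise ValueError("detect_onset requires a time-resolved series")
    if roi.count == 0:
        raise ValueError("ROI mask is empty")
    lobes = _lobe_mask(roi, probe_line, series.grid.b0_unit)
    cold = series.values < params.neg_threshold
    return cold[:, lobes].sum(axis=1)


def detect_onset(
    series: MapStack,
    roi: Mask,
    probe_line: Mask,
    params: DetectionParams = DetectionParams(),
) -> int | None:
    """First dynamic where the lobe count persists at >= min_count.

    Returns ``None`` when the criterion is never met.
    """
    counts = lobe_counts(series, roi, probe_line, params)
    hits = counts >= params.min_count
    run = 0
    for i, h in enumerate(hits):
        run = run + 1 if h else 0
        if run >= params.consecutive:
            return i - params.consecutive + 1
    return None
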