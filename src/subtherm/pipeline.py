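"""End-to-end orchestration: detect -> correct -> filter -> dose (-> evaluate).

Every intermediate (prior, masks, weights, chi, artifact, corrected series,
filtered series, dose, lesion) is written to the output directory as NIfTI,
together with a machine-readable JSON run log carrying the config hash, the
seed and per-stage diagnostics.  Any stage failure aborts with the stage
name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .correction import (
    build_bubble_mask,
    build_prior,
    build_roi_mask,
    compute_weights,
    correct_stack,
)
from .detection import DetectionParams, detect_onset
from .dipole import get_kernel
from .dosimetry import DoseParams, cem43, lesion_mask
from .evaluation import geometry_metrics, overlap_metrics
from .grids import MapStack, Mask, refine_grid
from .io import PipelineConfig, save_map, save_mask
from .thermometry import lowpass_filter

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    corrected: MapStack
    filtered: MapStack
    dose: MapStack
    lesion: Mask
    onset_idx: int
    report: dict


def run_pipeline(
    config: PipelineConfig,
    series: MapStack,
    magnitude: MapStack,
    probe_line: Mask,
    onset_idx: int | None = None,
    during_idx: int | None = None,
    bubble_mask: Mask | None = None,
    reference_lesion: Mask | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full correction pipeline on a temperature-variation series.

    ``onset_idx=None`` invokes automatic onset detection.  ``bubble_mask``
    overrides the magnitude-threshold construction.  ``reference_lesion``
    triggers the evaluation stage.
    """
    params = config.acquisition.to_params()
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    stage = "masks"
    try:
        mag_before = MapStack(
            grid=magnitude.grid,
            values=magnitude.values[: max(onset_idx or 5, 5)].mean(axis=0),
            unit="1",
        )
        if bubble_mask is None:
            bubble_mask = build_bubble_mask(
                mag_before, probe_line, void_fraction=config.masks.void_fraction
            )
        roi_mask = build_roi_mask(
            probe_line, bubble_mask, dilation_vox=config.masks.dilation_vox
        )
        if np.any(bubble_mask.values & roi_mask.values):
            raise ValueError("bubble and ROI masks overlap")
        report["stages"][stage] = {
            "n_bubble": bubble_mask.count,
            "n_roi": roi_mask.count,
        }
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        raise PipelineError(stage, exc) from exc

    stage = "detect"
    try:
        if onset_idx is None:
            det = DetectionParams(
                neg_threshold=config.detection.neg_threshold_c,
                min_count=config.detection.min_count,
                consecutive=config.detection.consecutive,
            )
            onset_idx = detect_onset(series, roi_mask, probe_line, det)
            if onset_idx is None:
                raise ValueError("no artifact onset detected; pass onset_idx")
        report["stages"][stage] = {"onset_idx": int(onset_idx)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "weights"
    try:
        heat_free = max(1, min(onset_idx - 5, 10))
        during0 = during_idx if during_idx is not None else onset_idx + 5
        during0 = min(during0, series.n_dynamics - 5)
        weights = compute_weights(
            magnitude, (0, heat_free + 1), (during0, during0 + 5), roi_mask, params
        )
        report["stages"][stage] = {"max_weight": float(weights.max())}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "correct"
    try:
        subgrid = refine_grid(series.grid, 2)
        kernel = get_kernel(subgrid)
        result = correct_stack(
            series,
            bubble_mask,
            roi_mask,
            weights,
            kernel,
            params,
            onset_idx,
            during_idx=during_idx,
            mode=config.mode,
            bounds=(config.solver.chi_min_ppm, config.solver.chi_max_ppm),
            solver_tol=config.solver.tol,
        )
        report["stages"][stage] = {
            "mode": config.mode,
            "residuals": {
                str(z): {"residual": info.residual_norm, "data_norm": info.data_norm}
                for z, info in result.slice_info.items()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "filter"
    try:
        filtered = lowpass_filter(
            result.corrected,
            cutoff_hz=config.filter.cutoff_hz,
            fs_hz=1.0 / params.dyn_period,
            mode=config.filter.mode,
        )
        report["stages"][stage] = {
            "cutoff_hz": config.filter.cutoff_hz,
            "mode": config.filter.mode,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "dose"
    try:
        dose_params = DoseParams(
            r_above=config.dose.r_above,
            r_below=config.dose.r_below,
            threshold=config.dose.threshold_cem43,
            t_init=config.dose.t_init_c,
        )
        dose = cem43(filtered, params.dyn_period, dose_params)
        lesion = lesion_mask(dose, config.dose.threshold_cem43)
        report["stages"][stage] = {"n_lesion": lesion.count}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    if reference_lesion is not None:
        stage = "evaluate"
        try:
            cmp_ = overlap_metrics(lesion, reference_lesion)
            entry = {
                "dice": cmp_.dice,
                "total_overlap": cmp_.total_overlap,
                "fnr": cmp_.fnr,
            }
            if lesion.count:
                vol, axes = geometry_metrics(lesion)
                entry["volume_cm3"] = vol
                entry["axes_mm"] = list(axes)
            report["stages"][stage] = entry
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    if out_dir is not None:
        stage = "write"
        try:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            prior = build_prior(
                series, onset_idx, during_idx if during_idx is not None else onset_idx + 5
            )
            save_map(prior, out / "prior.nii.gz")
            save_mask(bubble_mask, out / "bubble_mask.nii.gz")
            save_mask(roi_mask, out / "roi_mask.nii.gz")
            save_map(
                MapStack(grid=series.grid, values=weights, unit="1"),
                out / "weights.nii.gz",
            )
            save_map(
                MapStack(grid=result.chi.grid, values=result.chi.values, unit="ppm"),
                out / "chi.nii.gz",
            )
            save_map(result.artifact, out / "artifact.nii.gz")
            save_map(result.corrected, out / "corrected.nii.gz")
            save_map(filtered, out / "filtered.nii.gz")
            save_map(dose, out / "dose.nii.gz")
            save_mask(lesion, out / "lesion.nii.gz")
            with open(out / "run_log.json", "w") as fh:
                json.dump(report, fh, indent=2)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    return PipelineResult(
        corrected=result.corrected,
        filtered=filtered,
        dose=dose,
        lesion=lesion,
        onset_idx=onset_idx,
        report=report,
    )
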