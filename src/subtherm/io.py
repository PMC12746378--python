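"""NIfTI readers/writers and the validated pipeline configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .grids import AcquisitionParams, MapStack, Mask, VoxelGrid

__all__ = [
    "load_map",
    "save_map",
    "load_mask",
    "save_mask",
    "PipelineConfig",
]


def _grid_from_nifti(img: nib.Nifti1Image, b0_dir=(1.0, 0.0, 0.0)) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    shape = img.shape[:3]
    return VoxelGrid(shape=tuple(shape), spacing=tuple(float(z) for z in zooms), b0_dir=b0_dir)


def load_map(path: str | Path, unit: str = "1", b0_dir=(1.0, 0.0, 0.0)) -> tuple[MapStack, np.ndarray]:
    """Read a scalar map (3D, or 4D with time as the 4th dim) from NIfTI.

    Returns the map (time moved to the leading axis) and the affine.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = _grid_from_nifti(img, b0_dir)
    if data.ndim == 4:
        data = np.moveaxis(data, 3, 0)
    elif data.ndim != 3:
        raise ValueError(f"expected a 3D or 4D NIfTI, got shape {img.shape}")
    return MapStack(grid=grid, values=data, unit=unit), np.asarray(img.affine)


def save_map(field: MapStack, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a map to NIfTI (time axis stored as the 4th dimension)."""
    values = field.values
    if field.has_time:
        values = np.moveaxis(values, 0, 3)
    if affine is None:
        affine = np.diag(list(field.grid.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), np.asarray(affine))
    img.header.set_zooms(tuple(field.grid.spacing) + img.header.get_zooms()[3:])
    nib.save(img, str(path))


def load_mask(path: str | Path, b0_dir=(1.0, 0.0, 0.0)) -> tuple[Mask, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"mask NIfTI must be 3D, got shape {img.shape}")
    grid = _grid_from_nifti(img, b0_dir)
    return Mask(grid=grid, values=data > 0.5), np.asarray(img.affine)


def save_mask(mask: Mask, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag(list(mask.grid.spacing) + [1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), np.asarray(affine))
    nib.save(img, str(path))


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Base):
    b0_tesla: float = Field(gt=0, default=1.5)
    te_s: float = Field(gt=0, default=0.015)
    alpha_ppm_per_c: float = Field(lt=0, default=-0.0094)
    gamma_bar_hz_per_t: float = Field(gt=0, default=42.58e6)
    dyn_period_s: float = Field(gt=0, default=5.0)
    b0_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def to_params(self) -> AcquisitionParams:
        return AcquisitionParams(
            b0=self.b0_tesla,
            te=self.te_s,
            alpha=self.alpha_ppm_per_c,
            gamma_bar=self.gamma_bar_hz_per_t,
            dyn_period=self.dyn_period_s,
        )


class MaskConfig(_Base):
    dilation_vox: int = Field(ge=1, default=9)
    void_fraction: float = Field(gt=0, lt=1, default=0.5)


class SolverConfig(_Base):
    chi_min_ppm: float = 0.0
    chi_max_ppm: float = 10.0
    tol: float = Field(gt=0, default=1e-8)
    max_iter: int = Field(ge=1, default=500)

    @model_validator(mode="after")
    def _check_bounds(self):
        if self.chi_min_ppm >= self.chi_max_ppm:
            raise ValueError("chi bounds must satisfy min < max")
        return self


class FilterConfig(_Base):
    cutoff_hz: float = Field(gt=0, default=0.04)
    mode: str = "causal"

    @model_validator(mode="after")
    def _check_mode(self):
        if self.mode not in ("causal", "zero_phase"):
            raise ValueError("filter mode must be 'causal' or 'zero_phase'")
        return self


class DoseConfig(_Base):
    threshold_cem43: float = Field(gt=0, default=240.0)
    t_init_c: float = 37.0
    r_above: float = Field(gt=0, lt=1, default=0.5)
    r_below: float = Field(gt=0, lt=1, default=0.25)


class DetectionConfig(_Base):
    neg_threshold_c: float = Field(lt=0, default=-10.0)
    min_count: int = Field(ge=1, default=5)
    consecutive: int = Field(ge=1, default=2)


class PipelineConfig(_Base):
    """Validated configuration for the full correction pipeline.

    Unknown keys are rejected on load; defaults follow the reference
    acquisition protocol and the standard dose convention.
    """

    schema_version: int = 1
    acquisition: AcquisitionConfig = AcquisitionConfig()
    masks: MaskConfig = MaskConfig()
    solver: SolverConfig = SolverConfig()
    filter: FilterConfig = FilterConfig()
    dose: DoseConfig = DoseConfig()
    detection: DetectionConfig = DetectionConfig()
    mode: str = "per_slice"
    seed: int = 0

    @model_validator(mode="after")
    def _check_mode(self):
        if self.mode not in ("per_slice", "all_slices"):
            raise ValueError("mode must be 'per_slice' or 'all_slices'")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
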