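"""Cumulative thermal dose (CEM43) and lesion thresholding.

The Sapareto-Dewey equivalent time at 43 degC accumulates per dynamic as

    CEM43 += (dt / 60) * R ** (43 - T),

with R = 0.5 above the 43 degC breakpoint and R = 0.25 below it (the
standard convention).  Absolute temperature is the baseline (37 degC by
default) plus the measured variation.  A voxel is predicted necrotic when
its final dose reaches 240 equivalent minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MapStack, Mask

__all__ = ["DoseParams", "cem43", "lesion_mask"]


@dataclass(frozen=True)
class DoseParams:
    t_ref: float = 43.0  # breakpoint temperature, degC
    r_above: float = 0.5  # rate factor for T >= t_ref
    r_below: float = 0.25  # rate factor for T < t_ref
    threshold: float = 240.0  # lesion threshold, equivalent minutes
    t_init: float = 37.0  # baseline absolute temperature, degC

    def __post_init__(self) -> None:
        if not (0 < self.r_below <= self.r_above < 1):
            raise ValueError("need 0 < r_below <= r_above < 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def cem43(
    temp_series: MapStack,
    dt_s: float,
    params: DoseParams = DoseParams(),
    cumulative: bool = False,
) -> MapStack:
    """Cumulative equivalent minutes at 43 degC per voxel.

    Parameters
    ----------
    temp_series : MapStack
        Time-resolved temperature variation (degC, relative to baseline).
    dt_s : float
        Time per dynamic, seconds.
    cumulative : bool
        If true, return the running dose (time-resolved); otherwise the
        final dose map.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if not temp_series.has_time:
        raise ValueError("cem43 requires a time-resolved series")
    if temp_series.unit != "degC":
        raise ValueError(f"expected degC, got unit {temp_series.unit!r}")
    t_abs = params.t_init + temp_series.values
    r = np.where(t_abs >= params.t_ref, params.r_above, params.r_below)
    increments = (dt_s / 60.0) * r ** (params.t_ref - t_abs)
    if cumulative:
        dose = np.cumsum(increments, axis=0)
        return MapStack(grid=temp_series.grid, values=dose, unit="1")
    dose = increments.sum(axis=0)
    return MapStack(grid=temp_series.grid, values=dose, unit="1")


def lesion_mask(dose: MapStack, threshold: float = 240.0) -> Mask:
    """Voxels whose final cumulative dose reaches the threshold (>= convention)."""
    values = dose.values[-1] if dose.has_time else dose.values
    return Mask(grid=dose.grid, values=values >= threshold)
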