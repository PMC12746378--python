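"""Phase / temperature / RDF conversions and the temporal low-pass filter.

The PRFS relation links the phase change between a dynamic and the reference
to the temperature variation,

    dT = dPhi / (alpha * B0 * gamma * TE),

with gamma = 2 pi * gamma_bar and alpha the (negative) PRFS coefficient.
A susceptibility change adds B0*gamma*TE*(d (x) dchi) to the measured phase,
so in RDF units (ppm) the measured field is  alpha*dT_true + d (x) dchi  and
the artifact can be subtracted in the ppm domain before converting back to
degC.  All three conversions here are linear and exactly invertible.

Phase inputs are assumed already unwrapped; no unwrapping is attempted.
A user-supplied drift-correction transform may be applied upstream; this
module deliberately provides only a pass-through hook for it.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import signal

from .grids import AcquisitionParams, MapStack

__all__ = [
    "phase_to_temperature",
    "temperature_to_phase",
    "temperature_to_rdf",
    "rdf_to_temperature",
    "lowpass_filter",
    "apply_drift_correction",
]


def phase_to_temperature(phase: MapStack, params: AcquisitionParams) -> MapStack:
    """Convert an (unwrapped) phase-difference map in rad to degC."""
    if phase.unit != "rad":
        raise ValueError(f"expected a phase map in rad, got unit {phase.unit!r}")
    return MapStack(grid=phase.grid, values=phase.values / params.rad_per_degc, unit="degC")


def temperature_to_phase(temp: MapStack, params: AcquisitionParams) -> MapStack:
    """Inverse of :func:`phase_to_temperature`."""
    if temp.unit != "degC":
        raise ValueError(f"expected a temperature map in degC, got unit {temp.unit!r}")
    return MapStack(grid=temp.grid, values=temp.values * params.rad_per_degc, unit="rad")


def temperature_to_rdf(temp: MapStack, alpha: float) -> MapStack:
    """Temperature variation (degC) to relative difference field (ppm): RDF = alpha*dT."""
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    if temp.unit != "degC":
        raise ValueError(f"expected degC, got unit {temp.unit!r}")
    return MapStack(grid=temp.grid, values=temp.values * alpha, unit="ppm")


def rdf_to_temperature(rdf: MapStack, alpha: float) -> MapStack:
    """RDF (ppm) to temperature variation (degC): dT = RDF / alpha."""
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    if rdf.unit != "ppm":
        raise ValueError(f"expected ppm, got unit {rdf.unit!r}")
    return MapStack(grid=rdf.grid, values=rdf.values / alpha, unit="degC")


def lowpass_filter(
    series: MapStack,
    cutoff_hz: float = 0.04,
    fs_hz: float | None = None,
    mode: str = "causal",
) -> MapStack:
    """First-order Butterworth temporal low-pass (DC gain 1).

    Parameters
    ----------
    series : MapStack
        Time-resolved map (dynamics on the leading axis).
    cutoff_hz : float
        -3 dB cutoff frequency, Hz.
    fs_hz : float
        Sampling rate (1 / dynamic period), Hz; must exceed 2*cutoff.
    mode : {"causal", "zero_phase"}
        Causal single-pass (real-time compatible; the default) or
        forward-backward zero-phase filtering for retrospective analysis.
    """
    if not series.has_time:
        raise ValueError("lowpass_filter requires a time-resolved series")
    if fs_hz is None:
        raise ValueError("fs_hz is required")
    if cutoff_hz <= 0 or fs_hz <= 2.0 * cutoff_hz:
        raise ValueError(
            f"need 0 < cutoff ({cutoff_hz}) < Nyquist ({fs_hz / 2})"
        )
    b, a = signal.butter(1, cutoff_hz, btype="low", fs=fs_hz)
    x = series.values
    if mode == "causal":
        # initialize the filter state at the first sample so a constant
        # series passes through unchanged (steady-state start)
        zi = signal.lfilter_zi(b, a)
        x0 = x[0][None, ...]
        out, _ = signal.lfilter(b, a, x, axis=0, zi=zi[:, None, None, None] * x0)
    elif mode == "zero_phase":
        out = signal.filtfilt(b, a, x, axis=0)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return MapStack(grid=series.grid, values=out, unit=series.unit)


def apply_drift_correction(
    series: MapStack, transform: Callable[[np.ndarray], np.ndarray] | None
) -> MapStack:
    """Pass-through hook for an external spatiotemporal drift correction.

    ``transform`` receives the raw time-resolved array and must return an
    array of the same shape; ``None`` is the identity.
    """
    if transform is None:
        return series
    out = np.asarray(transform(series.values), dtype=float)
    if out.shape != series.values.shape:
        raise ValueError("drift transform changed the series shape")
    return MapStack(grid=series.grid, values=out, unit=series.unit)
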