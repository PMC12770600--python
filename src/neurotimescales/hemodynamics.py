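"""Canonical HRF convolution: neuronal activity density -> BOLD-like series.

The haemodynamic response function is the standard double-gamma difference
(positive lobe peaking near 5 s, delayed undershoot), sampled at the
neuronal time step.  Simulated activity is convolved causally with this
kernel and decimated to one sample per TR, so 300 s of 1 ms activity at
TR = 2 s yields exactly 150 BOLD-equivalent samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .simulator import ActivityTrace
from .timescales import TimeSeries

__all__ = ["HrfParams", "BoldLikeSeries", "canonical_hrf", "to_bold"]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (seconds), canonical defaults:
    peak delay 6 s, undershoot delay 16 s, unit dispersions, 1:6
    peak-to-undershoot ratio, 32 s kernel."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length: float = 32.0
    dt: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "kernel_length",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class BoldLikeSeries:
    """TR-sampled BOLD-equivalent series."""

    values: np.ndarray
    tr: float

    def to_timeseries(self, label: str = "") -> TimeSeries:
        return TimeSeries(values=self.values, dt=self.tr, label=label)


def canonical_hrf(params: HrfParams = HrfParams()) -> np.ndarray:
    """Double-gamma kernel sampled at ``params.dt``, peak-normalised to 1.

    gamma_pdf(t; peak_delay/peak_dispersion, peak_dispersion)
    - gamma_pdf(t; undershoot_delay/..., ...) / undershoot_ratio,
    truncated at ``kernel_length``.
    """
    t = np.arange(0.0, params.kernel_length, params.dt)
    peak = stats.gamma.pdf(
        t, a=params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    undershoot = stats.gamma.pdf(
        t,
        a=params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - undershoot / params.undershoot_ratio
    return kernel / kernel.max()


def to_bold(
    trace: ActivityTrace,
    params: HrfParams | None = None,
    tr: float = 2.0,
    *,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BoldLikeSeries:
    """Convolve an activity trace with the canonical HRF and decimate to TR.

    Causal full-mode convolution truncated to the input length, sampled at
    t = TR, 2·TR, ..., for ``floor(duration / tr)`` output samples.
    Optional additive Gaussian observation noise (off by default).
    """
    if params is None:
        params = HrfParams(dt=trace.dt)
    if abs(params.dt - trace.dt) > 1e-12:
        raise ValueError("HRF dt must match the trace dt")
    step_f = tr / trace.dt
    step = int(round(step_f))
    if abs(step_f - step) > 1e-9 or step < 1:
        raise ValueError("tr must be a positive integer multiple of the trace dt")
    n = trace.density.size
    duration = n * trace.dt
    if duration < tr:
        raise ValueError("trace shorter than one TR")
    kernel = canonical_hrf(params)
    conv = signal.fftconvolve(trace.density, kernel)[:n]
    n_out = int(np.floor(duration / tr + 1e-9))
    values = conv[step - 1 :: step][:n_out].copy()
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        values = values + rng.normal(0.0, noise_sd, values.size)
    return BoldLikeSeries(values=values, tr=tr)
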