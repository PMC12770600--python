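"""Intrinsic neural timescales and long-range temporal-correlation metrics.

The intrinsic neural timescale (INT) of a signal is the area under its
sample autocorrelation function (ACF) summed over the positive lags that
precede the first negative lag, scaled by the sampling interval.  Together
with thresholded area variants (INT_0.1, INT_0.5), autocorrelation-window
lags (ACW_0, ACW_0.1, ACW_0.5) and the detrended-fluctuation (DFA-1) Hurst
exponent, these seven numbers summarise how long a region's activity stays
self-correlated: long INT = slow, persistent dynamics.

Conventions
-----------
* The ACF uses the biased estimator: a single global mean and the
  full-sample variance in the denominator for every lag, so ``|ACF_k| <= 1``
  and ``ACF_0 = 1`` exactly.
* INT sums lags ``k = 1 .. n_lag - 1`` where ``n_lag`` is the first lag with
  a strictly negative ACF value; the thresholded variants truncate the same
  sum at the first lag at or below the threshold, so they are exact sub-sums
  of INT.
* ACW lags are linearly interpolated between the bracketing integer lags.
* When a curve never crosses its threshold, the full-lag-range value is
  returned and a :class:`NoCrossingWarning` is emitted — batch cohort runs
  must not abort on one flat ACF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "TimeSeries",
    "AcfCurve",
    "TimescaleSet",
    "DegenerateSeriesError",
    "NoCrossingWarning",
    "compute_acf",
    "compute_int",
    "compute_int_threshold",
    "compute_acw0",
    "compute_acw_threshold",
    "compute_hurst",
    "compute_all_metrics",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series is too short or has zero variance for a metric."""


class NoCrossingWarning(UserWarning):
    """Emitted when an ACF never reaches the requested threshold/zero line."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    values
        Signal samples, arbitrary units (BOLD, activity density, ...).
    dt
        Sampling interval in seconds (the TR for fMRI; the simulator time
        step for model activity).
    label
        Free-text identifier carried through to outputs.
    """

    values: np.ndarray
    dt: float
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if values.size < 8:
            raise DegenerateSeriesError(
                f"series too short ({values.size} points, need >= 8)"
            )
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(values)):
            raise ValueError("series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AcfCurve:
    """Sample autocorrelation at consecutive integer lags starting at 0."""

    lags: np.ndarray
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-d vectors")
        if lags[0] != 0 or np.any(np.diff(lags) != 1):
            raise ValueError("lags must start at 0 and increase by 1")
        if values[0] != 1.0:
            raise ValueError("ACF at lag 0 must equal 1 exactly")
        if np.any(np.abs(values) > 1.0 + 1e-9):
            raise ValueError("ACF values must lie in [-1, 1]")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class TimescaleSet:
    """The seven temporal-correlation summaries of one series.

    Time-valued fields are in seconds; ``hurst`` is dimensionless.  By
    construction ``int >= int01 >= int05`` and ``acw0 >= acw01 >= acw05``
    (nested truncations of a curve that starts at 1).
    """

    int: float
    int01: float
    int05: float
    acw0: float
    acw01: float
    acw05: float
    hurst: float

    def as_dict(self) -> dict[str, float]:
        return {
            "int": self.int,
            "int01": self.int01,
            "int05": self.int05,
            "acw0": self.acw0,
            "acw01": self.acw01,
            "acw05": self.acw05,
            "hurst": self.hurst,
        }


def compute_acf(series: TimeSeries, max_lag: int) -> AcfCurve:
    """Biased sample autocorrelation up to ``max_lag``.

    ``ACF_k = sum_{t=k+1..T} (y_t - ybar)(y_{t-k} - ybar)
              / sum_{t=1..T} (y_t - ybar)^2``
    with one global mean and the full-sample denominator for every lag.

    Raises
    ------
    DegenerateSeriesError
        If the series has zero variance.
    ValueError
        If ``max_lag`` is not in ``[1, len(series) - 1]``.
    """
    n = len(series)
    if not 1 <= max_lag < n:
        raise ValueError(f"max_lag must be in [1, {n - 1}], got {max_lag}")
    d = series.values - series.values.mean()
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise DegenerateSeriesError("zero-variance series has no ACF")
    method = "fft" if n > 500 else "direct"
    full = signal.correlate(d, d, mode="full", method=method)
    acov = full[n - 1 : n + max_lag]
    values = acov / denom
    values[0] = 1.0
    # FFT round-off can push values epsilon past +/-1; clip within tolerance.
    np.clip(values, -1.0, 1.0, out=values)
    return AcfCurve(lags=np.arange(max_lag + 1), values=values, dt=series.dt)


def _first_at_or_below(values: np.ndarray, threshold: float) -> int | None:
    """Index of the first lag >= 1 with ``values[k] <= threshold``."""
    below = np.nonzero(values[1:] <= threshold)[0]
    if below.size == 0:
        return None
    return int(below[0]) + 1


def compute_int(acf: AcfCurve) -> float:
    """Intrinsic neural timescale: ``dt * sum_{k=1..n_lag-1} ACF_k``.

    ``n_lag`` is the first lag with a strictly negative ACF value.  If the
    ACF is already negative at lag 1 the sum is empty and INT is 0.  If no
    lag is negative, the sum runs over every available lag and a
    :class:`NoCrossingWarning` is emitted.
    """
    neg = np.nonzero(acf.values[1:] < 0)[0]
    if neg.size > 0:
        n_lag = int(neg[0]) + 1
    else:
        warnings.warn(
            "ACF never becomes negative within the available lags; "
            "INT uses the full lag range",
            NoCrossingWarning,
            stacklevel=2,
        )
        n_lag = acf.values.size
    return float(acf.dt * acf.values[1:n_lag].sum())


def compute_int_threshold(acf: AcfCurve, threshold: float) -> float:
    """Area under the ACF up to its first decay to ``threshold``.

    The dt-weighted sum of ``ACF_k`` for ``k >= 1`` stops at (and excludes)
    the first lag whose value is at or below the threshold; the result is an
    exact sub-sum of :func:`compute_int`.  A curve that never reaches the
    threshold behaves like :func:`compute_int` (with a warning).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    stop = _first_at_or_below(acf.values, threshold)
    if stop is None:
        warnings.warn(
            f"ACF never decays to {threshold}; thresholded area uses the "
            "full positive range",
            NoCrossingWarning,
            stacklevel=2,
        )
        return compute_int(acf)
    return float(acf.dt * acf.values[1:stop].sum())


def _interpolated_lag(acf: AcfCurve, threshold: float) -> float | None:
    """Real-valued lag where the ACF first reaches ``threshold`` from above,
    linearly interpolated between the bracketing integer lags.  ``None`` when
    the curve never gets there."""
    k = _first_at_or_below(acf.values, threshold)
    if k is None:
        return None
    v_hi = acf.values[k - 1]
    v_lo = acf.values[k]
    if v_lo == threshold:
        return float(k)
    return float(k - 1 + (v_hi - threshold) / (v_hi - v_lo))


def compute_acw0(acf: AcfCurve) -> float:
    """Autocorrelation window: time lag of the first zero crossing.

    Linear interpolation between the last positive and the first
    non-positive ACF value; an exact zero counts as the crossing.  When the
    ACF never crosses zero, the full-lag-range time is returned with a
    :class:`NoCrossingWarning`.
    """
    lag = _interpolated_lag(acf, 0.0)
    if lag is None:
        warnings.warn(
            "ACF never crosses zero within the available lags",
            NoCrossingWarning,
            stacklevel=2,
        )
        return float(acf.dt * acf.lags[-1])
    return float(acf.dt * lag)


def compute_acw_threshold(acf: AcfCurve, threshold: float) -> float:
    """Time lag at which the ACF first decays to ``threshold``.

    Same interpolation convention as :func:`compute_acw0`.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    lag = _interpolated_lag(acf, threshold)
    if lag is None:
        warnings.warn(
            f"ACF never decays to {threshold} within the available lags",
            NoCrossingWarning,
            stacklevel=2,
        )
        return float(acf.dt * acf.lags[-1])
    return float(acf.dt * lag)


def _dfa_window_sizes(n: int, n_sizes: int = 10) -> np.ndarray:
    sizes = np.logspace(np.log10(4), np.log10(n // 4), n_sizes)
    return np.unique(np.round(sizes).astype(int))


def compute_hurst(series: TimeSeries, n_sizes: int = 10) -> float:
    """DFA-1 scaling exponent of the series.

    The mean-removed series is integrated to a profile, split into
    non-overlapping windows at ~``n_sizes`` log-spaced sizes from 4 to T/4,
    each window detrended with a first-order polynomial, and the exponent is
    the least-squares slope of log RMS fluctuation against log window size.
    0.5 for uncorrelated noise; larger under persistent long-range
    correlation.

    Raises
    ------
    DegenerateSeriesError
        For series shorter than 64 points or with zero variance.
    """
    x = series.values
    n = x.size
    if n < 64:
        raise DegenerateSeriesError(f"DFA needs >= 64 points, got {n}")
    if np.var(x) == 0.0:
        raise DegenerateSeriesError("zero-variance series has no DFA exponent")
    profile = np.cumsum(x - x.mean())
    sizes = _dfa_window_sizes(n, n_sizes)
    fluctuations = np.empty(sizes.size)
    for i, s in enumerate(sizes):
        n_win = n // s
        segments = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        design = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(design, segments.T, rcond=None)
        residuals = segments.T - design @ coef
        fluctuations[i] = np.sqrt(np.mean(residuals**2))
    slope, _ = np.polyfit(np.log(sizes), np.log(fluctuations), 1)
    return float(slope)


def compute_all_metrics(series: TimeSeries, max_lag: int | None = None) -> TimescaleSet:
    """All seven metrics of one series from a single shared ACF.

    ``max_lag`` defaults to ``len(series) - 1``.
    """
    if max_lag is None:
        max_lag = len(series) - 1
    acf = compute_acf(series, max_lag)
    return TimescaleSet(
        int=compute_int(acf),
        int01=compute_int_threshold(acf, 0.1),
        int05=compute_int_threshold(acf, 0.5),
        acw0=compute_acw0(acf),
        acw01=compute_acw_threshold(acf, 0.1),
        acw05=compute_acw_threshold(acf, 0.5),
        hurst=compute_hurst(series),
    )
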