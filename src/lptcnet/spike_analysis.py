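"""Spike detection and single/pairwise spike-train statistics.

Provides threshold-crossing spike detection on voltage traces, firing
rate differences from spontaneous activity, interspike-interval (ISI)
histograms with the coefficient of variation, and Pearson-normalized
firing-rate cross-correlograms (binned at 10 ms by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "RateSeries",
    "detect_spikes",
    "mean_rate",
    "rate_diff",
    "isi_distribution",
    "isi_cv",
    "rate_series",
    "cross_correlation",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) of one cell over [0, duration]."""

    cell: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration):
            raise ValueError("times must be strictly increasing within [0, duration]")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz (duration is in ms)."""
        return self.n / (self.duration / 1000.0)


@dataclass(frozen=True)
class RateSeries:
    """Windowed firing rates (Hz) at fixed bin width (ms)."""

    bin_width: float
    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")


def detect_spikes(voltage: np.ndarray, dt: float, threshold: float = 0.0,
                  refractory: float = 2.0, cell: str = "") -> SpikeTrain:
    """One event per upward threshold crossing separated by ≥ refractory."""
    v = np.asarray(voltage, dtype=float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for k in up:
        t = k * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return SpikeTrain(cell, np.asarray(times), v.size * dt)


def mean_rate(train: SpikeTrain) -> float:
    return train.rate


def rate_diff(stim_train: SpikeTrain, spont_train: SpikeTrain) -> float:
    """Mean rate under stimulation minus mean spontaneous rate, Hz."""
    return stim_train.rate - spont_train.rate


def isi_distribution(train: SpikeTrain, bin_width: float = 2.0,
                     t_max: float | None = None):
    """ISI histogram (counts, bin edges in ms) and the ISI CV.

    With fewer than two spikes the histogram is empty and the CV is
    reported as NaN (missing).
    """
    if train.n < 2:
        return np.zeros(0, dtype=int), np.zeros(1), float("nan")
    isi = np.diff(train.times)
    hi = t_max if t_max is not None else float(isi.max()) + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(isi, bins=edges)
    cv = float(isi.std() / isi.mean()) if isi.mean() > 0 else float("nan")
    return counts, edges, cv


def isi_cv(train: SpikeTrain) -> float:
    """Coefficient of variation of the interspike intervals (NaN if < 2 spikes)."""
    return isi_distribution(train)[2]


def rate_series(train: SpikeTrain, bin_width: float = 10.0) -> RateSeries:
    """Bin spike counts into non-overlapping windows; rates in Hz."""
    n_bins = int(train.duration // bin_width)
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    return RateSeries(bin_width, counts / (bin_width / 1000.0))


def cross_correlation(x: RateSeries, y: RateSeries, max_lag: float = 200.0,
                      centered: bool = False):
    """Normalized cross-correlogram of two firing-rate series.

    Returns (lags in ms, correlations).  The default estimator is the
    non-centered normalized form

        C_xy(τ) = Σ x(t)·y(t+τ) / sqrt(Σ x(t)² · Σ y(t+τ)²)

    over the overlapping samples at each lag, so its zero-lag value
    reflects both coincident modulation and the rate/regularity of the
    two trains.  ``centered=True`` subtracts the means first (Pearson
    form).  Either way values lie in [−1, 1] (Cauchy–Schwarz) and
    C_xy(τ) = C_yx(−τ).  Degenerate overlaps (all-zero, or
    zero-variance when centered) yield NaN (missing).
    """
    if x.bin_width != y.bin_width:
        raise ValueError("series must share the bin width")
    a = np.asarray(x.rates, dtype=float)
    b = np.asarray(y.rates, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    k_max = int(max_lag // x.bin_width)
    lags = np.arange(-k_max, k_max + 1) * x.bin_width
    out = np.empty(lags.size)
    for i, k in enumerate(range(-k_max, k_max + 1)):
        if k >= 0:
            u, v = a[: a.size - k], b[k:]
        else:
            u, v = a[-k:], b[: b.size + k]
        if u.size < 2:
            out[i] = np.nan
            continue
        if centered:
            u = u - u.mean()
            v = v - v.mean()
        norm = np.sqrt((u * u).sum() * (v * v).sum())
        out[i] = float((u * v).sum() / norm) if norm > 0.0 else np.nan
    return lags, out
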