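"""Basic signal features: mean, SD, tSNR, Welch spectrum, weighted average frequency.

The weighted average frequency (WAF) condenses a power spectrum into one
number,

    WAF = sum_x(P_x * f_x) / sum_x(P_x),

the power-weighted mean of the frequency grid.  A discrete variant returns
the grid frequency at which the cumulative sum of ``P_x * f_x`` first
exceeds half its total — a cheap, grid-valued surrogate for the same
quantity, and the package default (see :func:`waf`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .series import SampledSeries

__all__ = ["PowerSpectrum", "BasicProps", "basic_stats", "tsnr", "welch_psd", "waf",
           "basic_props"]

#: Number of Welch segments at 50% overlap; segment length = floor(T / 4.5).
WELCH_SEGMENTS = 8


@dataclass(frozen=True)
class PowerSpectrum:
    """Paired frequency (Hz) and power-density vectors from Welch estimation."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D vectors of equal length")
        if np.any(np.diff(freqs) <= 0) or freqs[0] < 0:
            raise ValueError("freqs must be nonnegative and strictly ascending")
        if np.any(power < 0):
            raise ValueError("power values must be >= 0")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)

    @property
    def total_power(self) -> float:
        return float(self.power.sum())


@dataclass(frozen=True)
class BasicProps:
    """Mean, SD, tSNR and WAF of one time course."""

    mean: float
    sd: float
    tsnr: float
    waf: float


def basic_stats(series: SampledSeries) -> tuple[float, float]:
    """Sample mean and sample standard deviation (n-1 denominator)."""
    x = series.values
    return float(x.mean()), float(x.std(ddof=1))


def tsnr(series: SampledSeries) -> float:
    """Temporal signal-to-noise ratio: mean divided by SD.

    Raises
    ------
    ValueError
        For a constant series, where the ratio is undefined.
    """
    mean, sd = basic_stats(series)
    if sd == 0.0:
        raise ValueError("tSNR undefined for a constant series (sd = 0)")
    return mean / sd


def _nfft(nperseg: int) -> int:
    return max(256, int(2 ** np.ceil(np.log2(nperseg))))


def welch_psd(series: SampledSeries) -> PowerSpectrum:
    """Welch power spectral density: 8 segments, 50% overlap, Hamming window.

    Segment length is ``floor(T / 4.5)`` (eight half-overlapping segments
    tile the series exactly); the FFT length is the next power of two of
    the segment length, at least 256, which fixes the frequency grid the
    discrete WAF variant selects from.  Returns a density on [0, Nyquist].
    """
    T = series.n
    nperseg = int(T / 4.5)
    if nperseg < 2:
        raise ValueError(f"series of length {T} too short for 8-segment Welch PSD")
    if T < 64:
        warnings.warn(
            f"Welch PSD on only {T} samples is poorly resolved", stacklevel=2
        )
    if np.ptp(series.values) == 0:
        warnings.warn("constant series: spectrum is all zero", stacklevel=2)
        freqs = np.fft.rfftfreq(_nfft(nperseg), d=series.dt)
        return PowerSpectrum(freqs, np.zeros_like(freqs))
    freqs, power = sps.welch(
        series.values,
        fs=series.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=_nfft(nperseg),
        detrend=False,
    )
    return PowerSpectrum(freqs, power)


def waf(spectrum: PowerSpectrum, method: str = "discrete_half_sum") -> float:
    """Weighted average frequency of a power spectrum, in Hz.

    method="eq1"
        The power-weighted mean frequency ``sum(P f) / sum(P)``.
    method="discrete_half_sum" (default)
        The smallest grid frequency at which the cumulative sum of
        ``P_x * f_x`` exceeds half of its total; always a member of the
        frequency grid.

    Both are invariant to rescaling of the power vector.

    Raises
    ------
    ValueError
        If total power is zero (WAF undefined) or the method is unknown.
    """
    p, f = spectrum.power, spectrum.freqs
    if spectrum.total_power <= 0:
        raise ValueError("WAF undefined for an all-zero spectrum")
    if method == "eq1":
        return float((p * f).sum() / p.sum())
    if method == "discrete_half_sum":
        weighted = p * f
        cum = np.cumsum(weighted)
        half = 0.5 * cum[-1]
        idx = int(np.searchsorted(cum, half, side="right"))
        return float(f[min(idx, f.size - 1)])
    raise ValueError(f"unknown WAF method: {method!r}")


def basic_props(series: SampledSeries, waf_method: str = "discrete_half_sum") -> BasicProps:
    """All four basic properties of one series in a single call.

    Mean, SD and tSNR are computed on the series as given; the WAF is
    computed on the demeaned series, mirroring the demeaning step of
    standard rs-fMRI preprocessing (otherwise leakage of a large baseline
    offset through the window swamps the low-frequency bins).
    """
    mean, sd = basic_stats(series)
    demeaned = SampledSeries(series.values - mean, series.dt)
    return BasicProps(
        mean=mean,
        sd=sd,
        tsnr=mean / sd if sd > 0 else float("nan"),
        waf=waf(welch_psd(demeaned), method=waf_method),
    )
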