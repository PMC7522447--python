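"""Core container for a single sampled time course.

A :class:`SampledSeries` is one parcel's BOLD time course together with its
sampling interval.  Every metric in this package — spectral, statistical or
dynamical — consumes this atom, so validation (finiteness, minimum length,
positive sampling interval) happens once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledSeries", "DEFAULT_DT"]

#: Repetition time of the emulated acquisition protocol, in seconds.
DEFAULT_DT = 0.72


@dataclass(frozen=True)
class SampledSeries:
    """A real-valued time course sampled at a fixed interval.

    Parameters
    ----------
    values
        Signal values (arbitrary units).  Must be finite and of length >= 2.
    dt
        Sampling interval in seconds (> 0).  Defaults to 0.72 s, the
        repetition time of standard high-temporal-resolution rs-fMRI.
    """

    values: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"series must be 1-D, got shape {values.shape}")
        if values.size < 2:
            raise ValueError(f"series needs at least 2 samples, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("series contains non-finite values")
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError(f"sampling interval must be positive, got {self.dt}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 0.5 / self.dt

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n * self.dt

    def zscored(self) -> "SampledSeries":
        """Return a copy standardised to zero mean and unit (sample) SD.

        Raises
        ------
        ValueError
            If the series is constant (zero variance).
        """
        sd = float(np.std(self.values, ddof=1))
        if sd == 0.0:
            raise ValueError("cannot z-score a constant series")
        return SampledSeries((self.values - self.values.mean()) / sd, self.dt)
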