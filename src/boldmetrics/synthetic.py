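"""Synthetic inputs: filtered-Gaussian simulation series and surrogate cohorts.

Two generators live here.

1. The *simulation* primitives — :func:`generate_gaussian_series`,
   :func:`bandpass`, :func:`add_noise` — produce the filtered-noise series
   used to probe how passband and additive noise move the complexity
   metrics (100 standard-normal series of 1200 points, bandpassed, with
   optional noise at 0.2 or 0.5 times the signal SD).

2. :func:`generate_cohort` builds a surrogate multi-subject, multi-parcel,
   multi-scan BOLD data set with the structure of a large test-retest
   cohort (two days x two scans per subject).  Each parcel is a narrowband
   stochastic oscillation whose centre frequency is set by a per-parcel
   weighted-average-frequency target, plus parcel-specific additive white
   noise; subjects differ by a multiplicative scale and a baseline offset.
   Parcel- and subject-level parameters are shared across scans — only the
   random realisation differs — which is precisely what makes test-retest
   reliability measurable on the output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .series import DEFAULT_DT, SampledSeries

__all__ = [
    "DEFAULT_SCANS",
    "CohortSpec",
    "generate_gaussian_series",
    "bandpass",
    "add_noise",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Session labels: day 1 scan 1/2, day 2 scan 1/2.
DEFAULT_SCANS = ("D1S1", "D1S2", "D2S1", "D2S2")

#: Butterworth order for the zero-phase bandpass (applied forward-backward).
FILTER_ORDER = 4


def generate_gaussian_series(
    n_series: int,
    T: int,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
) -> list[SampledSeries]:
    """Draw ``n_series`` i.i.d. standard-normal series of length ``T``.

    Reproducible under a fixed ``seed``; the atoms of the simulation study.
    """
    if n_series < 1:
        raise ValueError(f"n_series must be >= 1, got {n_series}")
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_series, T))
    return [SampledSeries(row, dt) for row in draws]


def _butter_sos(f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not (0.0 <= f_lo < f_hi < nyq):
        raise ValueError(
            f"band edges must satisfy 0 <= f_lo < f_hi < Nyquist ({nyq:g} Hz); "
            f"got [{f_lo}, {f_hi}]"
        )
    if f_lo == 0.0:
        return sps.butter(FILTER_ORDER, f_hi, btype="lowpass", fs=fs, output="sos")
    return sps.butter(FILTER_ORDER, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(series: SampledSeries, f_lo: float, f_hi: float) -> SampledSeries:
    """Zero-phase Butterworth bandpass of a series.

    An order-4 Butterworth is applied forward and backward (``sosfiltfilt``),
    doubling the effective attenuation and cancelling group delay, the
    standard practice for rs-fMRI band limiting.  A lower edge of 0 selects
    a pure lowpass.

    Raises
    ------
    ValueError
        If band edges are outside (0, Nyquist) or the series is too short
        for the filter's padding requirements.
    """
    sos = _butter_sos(f_lo, f_hi, series.fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.n <= padlen:
        raise ValueError(
            f"series of length {series.n} is too short for the order-"
            f"{FILTER_ORDER} zero-phase filter (needs > {padlen} samples)"
        )
    filtered = sps.sosfiltfilt(sos, series.values)
    return SampledSeries(filtered, series.dt)


def add_noise(
    series: SampledSeries, sigma_frac: float, seed: int | None = None
) -> SampledSeries:
    """Add i.i.d. Gaussian noise with SD equal to ``sigma_frac`` x SD(input).

    ``sigma_frac = 0`` returns the input unchanged.  The noise amplitude is
    defined relative to the input's own sample SD, so a zero-variance input
    with positive ``sigma_frac`` is rejected.
    """
    if sigma_frac < 0:
        raise ValueError(f"sigma_frac must be >= 0, got {sigma_frac}")
    if sigma_frac == 0:
        return SampledSeries(series.values.copy(), series.dt)
    sd = float(np.std(series.values, ddof=1))
    if sd == 0.0:
        raise ValueError("noise scale undefined for a zero-variance input")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(series.n) * (sigma_frac * sd)
    return SampledSeries(series.values + noise, series.dt)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a surrogate multi-scan BOLD cohort.

    Parcel-level parameters (WAF target, noise SD fraction, baseline) and
    subject-level parameters (multiplicative scale) are fixed properties of
    the cohort, reused identically in every scan; scans differ only in the
    random realisation of the underlying noise processes.

    Attributes
    ----------
    n_subjects, n_parcels, n_timepoints
        Cohort dimensions (each >= 2).
    dt
        Sampling interval in seconds.
    scans
        Session labels; default two scans on each of two days.
    parcel_waf_targets
        Per-parcel target weighted average frequency in Hz, each inside
        (0, Nyquist).  Default: evenly spread over 0.05-0.08 Hz, the
        observed range of parcel-mean WAF in resting-state data.
    parcel_noise_sd
        Per-parcel additive white-noise SD as a fraction of the oscillation
        SD (>= 0).  Default: evenly spread over 0.1-0.5, so that noisier
        parcels have both broader spectra (higher WAF) and noisier
        phase-space trajectories — the covariation the association analysis
        measures.
    parcel_baseline
        Per-parcel mean signal intensity (arbitrary scanner units); spread
        over 600-1200 by default to mimic coil-sensitivity differences.
    subject_scale
        Per-subject multiplicative amplitude factor; default evenly spread
        over 0.8-1.2.
    subject_gain_sd
        SD of a per-subject multiplicative gain on the baseline intensity
        (a stable subject trait, e.g. head size / coil loading); reused
        across scans.
    scan_gain_jitter
        SD of a per-scan multiplicative jitter on that gain (session-to-
        session scanner drift).
    scan_scale_jitter
        SD of a per-scan multiplicative jitter on the subject amplitude
        scale (session-to-session physiological state).  Together with
        ``scan_gain_jitter`` this makes subject-level profiles less
        reproducible than parcel-level ones, as observed in real
        test-retest cohorts.
    osc_halfwidth
        Half-width in Hz of each parcel's narrowband oscillation passband.
    seed
        Base seed; fixes the cohort bit-for-bit.
    """

    n_subjects: int
    n_parcels: int
    n_timepoints: int = 1200
    dt: float = DEFAULT_DT
    scans: tuple[str, ...] = DEFAULT_SCANS
    parcel_waf_targets: np.ndarray | None = None
    parcel_noise_sd: np.ndarray | None = None
    parcel_baseline: np.ndarray | None = None
    subject_scale: np.ndarray | None = None
    subject_gain_sd: float = 0.03
    scan_gain_jitter: float = 0.01
    scan_scale_jitter: float = 0.05
    osc_halfwidth: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_parcels", "n_timepoints"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.scans) < 1:
            raise ValueError("at least one scan label required")
        nyq = 0.5 / self.dt
        defaults = {
            "parcel_waf_targets": np.linspace(0.05, 0.08, self.n_parcels),
            "parcel_noise_sd": np.linspace(0.1, 0.5, self.n_parcels),
            "parcel_baseline": np.linspace(600.0, 1200.0, self.n_parcels),
            "subject_scale": np.linspace(0.8, 1.2, self.n_subjects),
        }
        for name, default in defaults.items():
            value = getattr(self, name)
            arr = default if value is None else np.asarray(value, dtype=float)
            object.__setattr__(self, name, arr)
        if self.parcel_waf_targets.shape != (self.n_parcels,):
            raise ValueError("parcel_waf_targets must have length n_parcels")
        if np.any(self.parcel_waf_targets <= 0) or np.any(self.parcel_waf_targets >= nyq):
            raise ValueError(f"parcel_waf_targets must lie in (0, {nyq:g}) Hz")
        for name, expect in (
            ("parcel_noise_sd", self.n_parcels),
            ("parcel_baseline", self.n_parcels),
            ("subject_scale", self.n_subjects),
        ):
            if getattr(self, name).shape != (expect,):
                raise ValueError(f"{name} must have length {expect}")
        if np.any(self.parcel_noise_sd < 0):
            raise ValueError("parcel_noise_sd must be >= 0")

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, val in out.items():
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
        out["scans"] = list(self.scans)
        return out


def _parcel_band(spec: CohortSpec, parcel: int) -> tuple[float, float]:
    """Narrow passband around a parcel's target frequency, clipped to (0, Nyq)."""
    fc = spec.parcel_waf_targets[parcel]
    lo = max(fc - spec.osc_halfwidth, 1e-3)
    hi = min(fc + spec.osc_halfwidth, spec.nyquist * 0.95)
    return lo, hi


def generate_cohort(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Generate a surrogate cohort: scan label -> (n_subjects, T, n_parcels).

    Parcel ``p`` of subject ``s`` is built as::

        baseline[p] * gain[s, scan]
        + scale[s] * amp[p] * (narrowband(p) + noise_sd[p] * white)

    where ``narrowband(p)`` is unit-SD Gaussian noise bandpassed to a
    narrow window around the parcel's WAF target, ``gain`` is a stable
    per-subject baseline gain with small per-scan drift, and ``amp[p]``
    scales the fluctuation amplitude proportionally to the parcel's
    baseline intensity (the BOLD fluctuation is a fraction of the local
    signal level), so amplitude structure is parcel-dominated as in real
    cohorts.  Realised
    parcel-mean WAF is therefore monotone in the targets, and higher-noise
    parcels get flatter spectra, higher entropy and lower trajectory
    stability — mirroring how site- and tissue-dependent noise shapes real
    parcel data.
    """
    ss = np.random.SeedSequence(spec.seed)
    scan_seeds = ss.spawn(len(spec.scans))
    trait_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    subject_gain = 1.0 + spec.subject_gain_sd * trait_rng.standard_normal(spec.n_subjects)
    parcel_amp = spec.parcel_baseline / spec.parcel_baseline.mean()
    T = spec.n_timepoints
    sos_per_parcel = [
        sps.butter(FILTER_ORDER, _parcel_band(spec, p), btype="bandpass",
                   fs=1.0 / spec.dt, output="sos")
        for p in range(spec.n_parcels)
    ]
    out: dict[str, np.ndarray] = {}
    for scan, scan_ss in zip(spec.scans, scan_seeds):
        rng = np.random.default_rng(scan_ss)
        scan_gain = subject_gain * (
            1.0 + spec.scan_gain_jitter * rng.standard_normal(spec.n_subjects)
        )
        scan_scale = spec.subject_scale * (
            1.0 + spec.scan_scale_jitter * rng.standard_normal(spec.n_subjects)
        )
        data = np.empty((spec.n_subjects, T, spec.n_parcels))
        for s in range(spec.n_subjects):
            raw = rng.standard_normal((T, spec.n_parcels))
            white = rng.standard_normal((T, spec.n_parcels))
            for p in range(spec.n_parcels):
                osc = sps.sosfiltfilt(sos_per_parcel[p], raw[:, p])
                osc_sd = osc.std(ddof=1)
                if osc_sd > 0:
                    osc = osc / osc_sd
                sig = osc + spec.parcel_noise_sd[p] * white[:, p]
                data[s, :, p] = (
                    spec.parcel_baseline[p] * scan_gain[s]
                    + scan_scale[s] * parcel_amp[p] * sig
                )
        out[scan] = data
    return out


def write_cohort(
    cohort: Mapping[str, np.ndarray], spec: CohortSpec, out_dir: str | Path
) -> Path:
    """Write one delimited-text matrix per subject per scan plus a JSON sidecar.

    Files are named ``<scan>_sub<k>.tsv`` with a header row of parcel labels;
    rows are time points.  The sidecar records dt, seed and the full spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parcel_labels = [f"parcel{p:03d}" for p in range(spec.n_parcels)]
    header = "\t".join(parcel_labels)
    for scan, data in cohort.items():
        for s in range(data.shape[0]):
            path = out_dir / f"{scan}_sub{s:03d}.tsv"
            np.savetxt(path, data[s], delimiter="\t", header=header, comments="")
    sidecar = {"dt": spec.dt, "seed": spec.seed, "spec": spec.to_dict()}
    (out_dir / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_cohort(in_dir: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a cohort written by :func:`write_cohort`.

    Returns the scan -> (n_subjects, T, n_parcels) mapping and the sidecar.
    """
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "cohort.json").read_text())
    scans: dict[str, list[np.ndarray]] = {}
    for path in sorted(in_dir.glob("*_sub*.tsv")):
        scan = path.stem.rsplit("_sub", 1)[0]
        scans.setdefault(scan, []).append(np.loadtxt(path, skiprows=1))
    cohort = {scan: np.stack(mats) for scan, mats in scans.items()}
    return cohort, sidecar
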