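"""Shared fixtures: deterministic reference signals and a small cohort."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from boldmetrics import CohortSpec, SampledSeries, bandpass, generate_cohort, generate_gaussian_series

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

DT = 0.72


@pytest.fixture(scope="session")
def white_noise() -> SampledSeries:
    rng = np.random.default_rng(42)
    return SampledSeries(rng.standard_normal(1200), DT)


@pytest.fixture(scope="session")
def sinusoid() -> SampledSeries:
    """Pure 0.05 Hz tone: period 1/0.05/0.72 ~ 27.8 samples."""
    t = np.arange(1200) * DT
    return SampledSeries(np.sin(2 * np.pi * 0.05 * t), DT)


@pytest.fixture(scope="session")
def filtered_noise() -> SampledSeries:
    """One Gaussian series bandpassed to 0.01-0.1 Hz, the reference condition."""
    (s,) = generate_gaussian_series(1, 1200, DT, seed=7)
    return bandpass(s, 0.01, 0.1)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 16 parcels x 2 scans with parcel-dominated structure."""
    spec = CohortSpec(
        n_subjects=10,
        n_parcels=16,
        seed=11,
        scans=("D1S1", "D1S2"),
        parcel_waf_targets=np.linspace(0.03, 0.09, 16),
    )
    return spec, generate_cohort(spec)
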