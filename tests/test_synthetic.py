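"""Generators: Gaussian series, bandpass filtering, noise, surrogate cohorts."""

import numpy as np
import pytest
from scipy import stats

from boldmetrics import (
    CohortSpec,
    SampledSeries,
    add_noise,
    bandpass,
    generate_cohort,
    generate_gaussian_series,
    waf,
    welch_psd,
)
from boldmetrics.synthetic import read_cohort, write_cohort

DT = 0.72


class TestSampledSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            SampledSeries(np.array([1.0]))  # too short
        with pytest.raises(ValueError):
            SampledSeries(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            SampledSeries(np.array([1.0, 2.0]), dt=0.0)

    def test_zscore_identity(self):
        rng = np.random.default_rng(0)
        z = SampledSeries(rng.normal(5, 3, 500), DT).zscored()
        assert z.values.mean() == pytest.approx(0, abs=1e-12)
        assert z.values.std(ddof=1) == pytest.approx(1, rel=1e-12)
        with pytest.raises(ValueError):
            SampledSeries(np.full(10, 2.0), DT).zscored()


class TestGaussianSeries:
    def test_pooled_moments(self):
        series = generate_gaussian_series(100, 1200, DT, seed=1)
        pooled = np.concatenate([s.values for s in series])
        n = pooled.size
        assert abs(pooled.mean()) < 3 / np.sqrt(n)
        assert abs(pooled.std(ddof=1) - 1) < 3 / np.sqrt(2 * n)

    def test_minimal_and_shapes(self):
        (s,) = generate_gaussian_series(1, 2, DT, seed=7)
        assert s.n == 2 and s.dt == DT

    def test_determinism(self):
        a = generate_gaussian_series(3, 100, DT, seed=9)
        b = generate_gaussian_series(3, 100, DT, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    @pytest.mark.parametrize("n,T", [(0, 100), (5, 1)])
    def test_invalid_counts(self, n, T):
        with pytest.raises(ValueError):
            generate_gaussian_series(n, T, DT, seed=0)


class TestBandpass:
    def test_band_concentration(self, white_noise):
        out = bandpass(white_noise, 0.01, 0.1)
        w = waf(welch_psd(out), method="eq1")
        assert 0.01 <= w <= 0.1

    def test_inband_passthrough(self, sinusoid):
        out = bandpass(sinusoid, 0.01, 0.1)
        trim = slice(100, -100)
        r = np.corrcoef(out.values[trim], sinusoid.values[trim])[0, 1]
        assert r > 0.99

    def test_stopband_attenuation(self):
        t = np.arange(1200) * DT
        tone = SampledSeries(np.sin(2 * np.pi * 0.3 * t), DT)
        out = bandpass(tone, 0.01, 0.1)
        assert out.values.std() < 0.1 * tone.values.std()

    def test_linearity(self, white_noise, sinusoid):
        a, b = 2.5, -1.3
        mix = SampledSeries(a * white_noise.values + b * sinusoid.values, DT)
        lhs = bandpass(mix, 0.01, 0.1).values
        rhs = (
            a * bandpass(white_noise, 0.01, 0.1).values
            + b * bandpass(sinusoid, 0.01, 0.1).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_errors(self, white_noise):
        with pytest.raises(ValueError):
            bandpass(white_noise, 0.1, 0.01)  # reversed edges
        with pytest.raises(ValueError):
            bandpass(white_noise, 0.01, 1.0)  # above Nyquist
        short = SampledSeries(np.random.default_rng(0).normal(size=20), DT)
        with pytest.raises(ValueError, match="too short"):
            bandpass(short, 0.01, 0.1)


class TestAddNoise:
    def test_zero_noise_identity(self, filtered_noise):
        out = add_noise(filtered_noise, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, filtered_noise.values)

    def test_variance_arithmetic(self, filtered_noise):
        sd_in = filtered_noise.values.std(ddof=1)
        out = add_noise(filtered_noise, 0.5, seed=3)
        ratio = np.var(out.values - filtered_noise.values, ddof=1) / sd_in**2
        assert ratio == pytest.approx(0.25, abs=3 * 0.25 * np.sqrt(2 / 1199))

    def test_output_sd(self):
        series = generate_gaussian_series(50, 1200, DT, seed=4)
        ratios = []
        for i, s in enumerate(series):
            out = add_noise(s, 0.2, seed=100 + i)
            ratios.append(out.values.std(ddof=1) / s.values.std(ddof=1))
        assert np.mean(ratios) == pytest.approx(np.sqrt(1.04), abs=0.005)

    def test_zero_variance_error(self):
        const = SampledSeries(np.full(100, 3.0), DT)
        with pytest.raises(ValueError, match="zero-variance"):
            add_noise(const, 0.2, seed=0)


class TestCohort:
    def test_waf_targets_recovered(self, small_cohort):
        spec, cohort = small_cohort
        data = cohort["D1S1"]
        realized = np.empty(spec.n_parcels)
        for p in range(spec.n_parcels):
            wafs = [
                waf(
                    welch_psd(
                        SampledSeries(
                            data[s, :, p] - data[s, :, p].mean(), spec.dt
                        )
                    )
                )
                for s in range(spec.n_subjects)
            ]
            realized[p] = np.mean(wafs)
        rho = stats.spearmanr(spec.parcel_waf_targets, realized).statistic
        assert rho >= 0.9

    def test_determinism_and_scan_variation(self, small_cohort):
        spec, cohort = small_cohort
        again = generate_cohort(spec)
        for scan in spec.scans:
            np.testing.assert_array_equal(cohort[scan], again[scan])
        assert not np.array_equal(cohort["D1S1"], cohort["D1S2"])

    def test_shapes(self, small_cohort):
        spec, cohort = small_cohort
        for scan in spec.scans:
            assert cohort[scan].shape == (
                spec.n_subjects,
                spec.n_timepoints,
                spec.n_parcels,
            )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1, n_parcels=10)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=4, n_parcels=3, parcel_waf_targets=np.array([0.05]))
        with pytest.raises(ValueError):
            CohortSpec(
                n_subjects=4, n_parcels=2, parcel_waf_targets=np.array([0.05, 0.9])
            )

    def test_roundtrip(self, small_cohort, tmp_path):
        spec, cohort = small_cohort
        write_cohort(cohort, spec, tmp_path / "c")
        back, sidecar = read_cohort(tmp_path / "c")
        assert sidecar["dt"] == spec.dt and sidecar["seed"] == spec.seed
        for scan in spec.scans:
            np.testing.assert_allclose(back[scan], cohort[scan], rtol=1e-5)
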