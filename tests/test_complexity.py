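"""Complexity metrics: correlation dimension, Lyapunov exponent, ApEn, suite."""

import numpy as np
import pytest

from boldmetrics import (
    EmbeddedCloud,
    EmbeddingParams,
    MetricConfig,
    SampledSeries,
    approximate_entropy,
    complexity_suite,
    correlation_dimension,
    delay_embed,
    lyapunov_exponent,
)

DT = 0.72


def _cloud(points: np.ndarray) -> EmbeddedCloud:
    return EmbeddedCloud(points=points, lag=1, dim=points.shape[1], dt=1.0)


def _brute_force_counts(points, radii, theiler):
    """O(M^2) pair count below each radius with temporal exclusion."""
    M = len(points)
    dists = []
    for i in range(M):
        for j in range(i + 1 + theiler, M):
            dists.append(np.linalg.norm(points[i] - points[j]))
    dists = np.asarray(dists)
    return np.array([(dists < r).sum() for r in radii]), dists.size


class TestCorrelationDimension:
    def test_line_segment_dimension_one(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 1, 1000)
        points = np.outer(t, [1.0, 2.0, -1.0])  # a segment in 3-D
        cd = correlation_dimension(_cloud(points), theiler=0)
        assert cd == pytest.approx(1.0, abs=0.1)

    def test_disk_dimension_two(self):
        rng = np.random.default_rng(3)
        r = np.sqrt(rng.uniform(0, 1, 1000))
        th = rng.uniform(0, 2 * np.pi, 1000)
        points = np.column_stack([r * np.cos(th), r * np.sin(th)])
        # fit in the small-radius scaling regime, where the analytic
        # dimension holds (large radii saturate at the disk boundary)
        cd = correlation_dimension(
            _cloud(points), theiler=0, radius_quantiles=(0.005, 0.2)
        )
        assert cd == pytest.approx(2.0, abs=0.15)

    def test_counts_match_brute_force(self, filtered_noise):
        # same pair counts as the O(M^2) oracle on a small embedding
        z = SampledSeries(filtered_noise.values[:280], DT).zscored()
        cloud = delay_embed(z, EmbeddingParams(lag=5, dim=2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(cloud.points))
        M = cloud.n_points
        iu, ju = np.triu_indices(M, k=cloud.lag + 1)
        d = D[iu, ju]
        d = d[d > 0]
        radii = np.geomspace(np.quantile(d, 0.01), np.quantile(d, 0.5), 10)
        counts_fast = np.searchsorted(np.sort(d), radii, side="left")
        counts_brute, n_pairs = _brute_force_counts(
            cloud.points, radii, theiler=cloud.lag
        )
        assert n_pairs == d.size
        np.testing.assert_array_equal(counts_fast, counts_brute)

    def test_affine_invariance(self, filtered_noise):
        cloud = delay_embed(filtered_noise.zscored(), EmbeddingParams(lag=7, dim=2))
        shifted = SampledSeries(3.2 * filtered_noise.values - 11.0, DT)
        cloud2 = delay_embed(shifted.zscored(), EmbeddingParams(lag=7, dim=2))
        # radii are distance quantiles, so the estimate is scale-free
        assert correlation_dimension(cloud) == pytest.approx(
            correlation_dimension(cloud2), rel=1e-9
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match=">= 50"):
            correlation_dimension(_cloud(np.zeros((10, 2))))
        with pytest.raises(ValueError):
            correlation_dimension(_cloud(np.zeros((200, 2))), theiler=0)


class TestLyapunov:
    def test_sinusoid_no_divergence(self, sinusoid):
        cloud = delay_embed(sinusoid.zscored(), EmbeddingParams(lag=7, dim=2))
        lam = lyapunov_exponent(cloud, unit_scale=1.0, series=sinusoid)
        assert abs(lam) < 0.02  # per-sample units

    def test_unit_scale_is_multiplicative(self, filtered_noise):
        cloud = delay_embed(filtered_noise.zscored(), EmbeddingParams(lag=7, dim=3))
        base = lyapunov_exponent(cloud, unit_scale=1.0, series=filtered_noise)
        scaled = lyapunov_exponent(cloud, unit_scale=4.15, series=filtered_noise)
        assert scaled == pytest.approx(4.15 * base, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 100"):
            lyapunov_exponent(_cloud(np.random.default_rng(0).normal(size=(50, 2))))


def _apen_oracle(x, m, lag, r):
    """Direct-definition ApEn: explicit template loops, Chebyshev distance."""

    def phi(mm):
        N = len(x) - (mm - 1) * lag
        templates = [x[i : i + mm * lag : lag] for i in range(N)]
        total = 0.0
        for a in templates:
            c = sum(
                1 for b in templates if np.max(np.abs(np.asarray(a) - b)) <= r
            )
            total += np.log(c / N)
        return total / N

    return phi(m) - phi(m + 1)


class TestApEn:
    def test_constant_is_zero(self):
        assert approximate_entropy(SampledSeries(np.full(150, 2.0), DT), m=2) == 0.0

    def test_square_wave_more_regular_than_noise(self):
        rng = np.random.default_rng(5)
        square = SampledSeries(np.tile([1.0] * 10 + [-1.0] * 10, 10), DT)
        noise = SampledSeries(rng.standard_normal(200), DT)
        ap_sq = approximate_entropy(square, m=2, lag=1, r_frac=0.2)
        ap_noise = approximate_entropy(noise, m=2, lag=1, r_frac=0.2)
        assert ap_sq < ap_noise

    @pytest.mark.parametrize("m,lag", [(2, 1), (3, 4)])
    def test_matches_direct_definition_oracle(self, m, lag):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(200)
        r = 0.2 * x.std(ddof=1)
        ours = approximate_entropy(SampledSeries(x, DT), m=m, lag=lag, r=r)
        assert ours == pytest.approx(_apen_oracle(x, m, lag, r), abs=1e-12)

    def test_affine_invariance_with_relative_radius(self, filtered_noise):
        a = approximate_entropy(filtered_noise, m=2, lag=7, r_frac=0.2)
        moved = SampledSeries(5.0 * filtered_noise.values + 3.0, DT)
        b = approximate_entropy(moved, m=2, lag=7, r_frac=0.2)
        assert a == pytest.approx(b, rel=1e-9)

    def test_radius_modes_and_errors(self, filtered_noise):
        z = filtered_noise.zscored()
        # on a unit-SD series the sd and var conventions coincide
        assert approximate_entropy(z, 2, 7, r_mode="sd") == pytest.approx(
            approximate_entropy(z, 2, 7, r_mode="var")
        )
        with pytest.raises(ValueError, match="r_mode"):
            approximate_entropy(z, 2, 7, r_mode="iqr")
        with pytest.raises(ValueError, match=">= 100"):
            approximate_entropy(SampledSeries(np.arange(50.0), DT), 2)


class TestComplexitySuite:
    def test_deterministic_and_recorded_params(self, filtered_noise):
        r1 = complexity_suite(filtered_noise)
        r2 = complexity_suite(filtered_noise)
        assert r1 == r2
        assert r1.params.lag >= 1 and r1.params.dim >= 2
        assert np.isfinite([r1.corr_dim, r1.lyap, r1.apen]).all()
        assert r1.apen >= 0 and r1.corr_dim >= 0

    def test_constant_series_names_failing_stage(self):
        const = SampledSeries(np.full(300, 1.5), DT)
        with pytest.raises(ValueError, match="z-score"):
            complexity_suite(const)
        with pytest.raises(ValueError, match="embedding estimation failed"):
            complexity_suite(const, MetricConfig(zscore=False))

    def test_estimated_dim_policy(self, filtered_noise):
        fixed = complexity_suite(filtered_noise)
        est = complexity_suite(
            filtered_noise, MetricConfig(corr_dim_dim=None, apen_m=None)
        )
        assert est.params == fixed.params
        # the dimension policy changes the metrics, not the embedding
        assert est.corr_dim != fixed.corr_dim
        assert est.apen != fixed.apen
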