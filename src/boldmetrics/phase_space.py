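"""Delay-embedding parameter estimation and phase-space reconstruction.

The embedding lag is the first local minimum of the average mutual
information (AMI) between the series and its lagged copy; the embedding
dimension is chosen by the false-nearest-neighbor (FNN) criterion of
Kennel: a neighbor in d dimensions is "false" if lifting to d+1 either
stretches the pair by more than ``r_tol`` relative to its d-dimensional
distance, or moves it by more than ``a_tol`` attractor sizes.  The first
dimension whose FNN fraction drops to ``cutoff`` or below is accepted.

All neighbor searches exclude temporally adjacent points (Theiler window
equal to the lag) so that trivially correlated successive samples never
count as phase-space neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .series import SampledSeries

__all__ = [
    "EmbeddingParams",
    "EmbeddedCloud",
    "average_mutual_information",
    "select_lag",
    "false_nearest_neighbors",
    "delay_embed",
    "estimate_embedding",
]

AMI_BINS = 10          # equiprobable bins per axis of the 2-D histogram
DEFAULT_MAX_LAG = 20   # ~14 s at dt = 0.72 s, well above observed lags
DEFAULT_MAX_DIM = 10
FNN_R_TOL = 15.0
FNN_A_TOL = None  # attractor-size test disabled by default; see false_nearest_neighbors
FNN_CUTOFF = 0.10


@dataclass(frozen=True)
class EmbeddingParams:
    """Estimated delay-embedding lag (samples) and dimension."""

    lag: int
    dim: int

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")


@dataclass(frozen=True)
class EmbeddedCloud:
    """Delay embedding of a series: M x dim points, M = T - (dim-1)*lag."""

    points: np.ndarray
    lag: int
    dim: int
    dt: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` (approximately) equiprobable bins."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def average_mutual_information(
    series: SampledSeries, max_lag: int = DEFAULT_MAX_LAG, n_bins: int = AMI_BINS
) -> np.ndarray:
    """AMI(tau) in nats for tau = 1..max_lag via a 2-D histogram estimate.

    Marginals are discretised into ``n_bins`` equiprobable (quantile) bins,
    which keeps the estimator well conditioned regardless of the marginal
    distribution of the signal.

    Raises
    ------
    ValueError
        For constant series (the histogram degenerates) or series shorter
        than 4 x max_lag.
    """
    x = series.values
    if np.ptp(x) == 0:
        raise ValueError("mutual information degenerate for a constant series")
    if series.n < 4 * max_lag:
        raise ValueError(
            f"series of length {series.n} too short for max_lag={max_lag} "
            f"(need >= {4 * max_lag})"
        )
    bins = _quantile_bins(x, n_bins)
    out = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        a, b = bins[:-tau], bins[tau:]
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        pa = joint.sum(axis=1, keepdims=True)
        pb = joint.sum(axis=0, keepdims=True)
        mask = joint > 0
        out[tau - 1] = float(
            (joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])).sum()
        )
    return out


def select_lag(ami: np.ndarray) -> int:
    """First local minimum of an AMI curve (1-indexed lag).

    A lag tau is the first local minimum when ``ami[tau] < ami[tau-1]`` and
    ``ami[tau] <= ami[tau+1]``; ties on the right break toward the smaller
    lag.  If the curve has no interior local minimum (e.g. strictly
    decreasing), falls back to the global argmin with a warning.
    """
    ami = np.asarray(ami, dtype=float)
    if ami.size < 2:
        raise ValueError("AMI curve must have at least 2 lags")
    for i in range(1, ami.size - 1):
        if ami[i] < ami[i - 1] and ami[i] <= ami[i + 1]:
            return i + 1
    warnings.warn(
        "AMI curve has no interior local minimum; falling back to argmin",
        stacklevel=2,
    )
    return int(np.argmin(ami)) + 1


def delay_embed(series: SampledSeries, params: EmbeddingParams) -> EmbeddedCloud:
    """Build the delay-coordinate point cloud.

    Row i is ``(x_i, x_{i+lag}, ..., x_{i+(dim-1)lag})``; there are
    ``T - (dim-1)*lag`` rows.
    """
    T, lag, dim = series.n, params.lag, params.dim
    span = (dim - 1) * lag
    if span >= T:
        raise ValueError(
            f"embedding infeasible: (dim-1)*lag = {span} >= T = {T}"
        )
    M = T - span
    idx = np.arange(M)[:, None] + lag * np.arange(dim)[None, :]
    return EmbeddedCloud(points=series.values[idx], lag=lag, dim=dim, dt=series.dt)


def _nearest_neighbors(points: np.ndarray, theiler: int) -> tuple[np.ndarray, np.ndarray]:
    """Index and distance of each point's nearest neighbor, excluding
    self-matches and points within ``theiler`` samples in time."""
    M = points.shape[0]
    tree = cKDTree(points)
    k = min(2 * theiler + 2, M)
    dists, idxs = tree.query(points, k=k)
    nn_idx = np.full(M, -1)
    nn_dist = np.full(M, np.inf)
    for i in range(M):
        valid = np.abs(idxs[i] - i) > theiler
        if valid.any():
            j = int(np.argmax(valid))
            nn_idx[i] = idxs[i][j]
            nn_dist[i] = dists[i][j]
    # points whose temporal exclusion swallowed all k candidates: brute force
    missing = np.flatnonzero(nn_idx < 0)
    for i in missing:
        d = np.linalg.norm(points - points[i], axis=1)
        d[np.abs(np.arange(M) - i) <= theiler] = np.inf
        j = int(np.argmin(d))
        if np.isfinite(d[j]):
            nn_idx[i], nn_dist[i] = j, d[j]
    return nn_idx, nn_dist


def false_nearest_neighbors(
    series: SampledSeries,
    lag: int,
    max_dim: int = DEFAULT_MAX_DIM,
    r_tol: float = FNN_R_TOL,
    a_tol: float | None = FNN_A_TOL,
    cutoff: float = FNN_CUTOFF,
) -> tuple[int, np.ndarray]:
    """Estimate embedding dimension by the false-nearest-neighbor test.

    For each candidate dimension d, every point's nearest neighbor (in the
    d-dimensional embedding, Theiler window = lag) is lifted to d+1; the
    pair is false if the added coordinate distance exceeds ``r_tol`` times
    the d-dimensional distance (the Kennel distance-ratio test).  Returns
    the smallest d whose false fraction is <= ``cutoff`` plus the full
    fraction curve; if the cutoff is never reached, returns ``max_dim``
    with a warning.

    ``a_tol``, when given, additionally flags a neighbor as false when the
    lifted distance exceeds ``a_tol`` attractor sizes (series SD).  It is
    disabled by default: for stochastic signals such as BOLD that test has
    a noise floor well above the 10% cutoff, so the fraction would never
    converge and every series would saturate at ``max_dim``.
    """
    x = series.values
    T = series.n
    if (max_dim - 1) * lag >= T // 2:
        raise ValueError(
            f"max_dim={max_dim} with lag={lag} leaves too few points (T={T})"
        )
    attractor_size = x.std(ddof=1)
    if attractor_size == 0:
        raise ValueError("FNN undefined for a constant series")
    fractions = np.full(max_dim, np.nan)
    chosen = 0
    for d in range(1, max_dim + 1):
        M = T - d * lag  # points for which the (d+1)-th coordinate exists
        if M < 10 * d:
            raise ValueError(
                f"too few embedded points ({M}) at dimension {d} for lag {lag}"
            )
        idx = np.arange(M)[:, None] + lag * np.arange(d)[None, :]
        pts = x[idx]
        nn_idx, nn_dist = _nearest_neighbors(pts, theiler=lag)
        ok = nn_idx >= 0
        i = np.flatnonzero(ok)
        j = nn_idx[i]
        extra = np.abs(x[i + d * lag] - x[j + d * lag])
        dist = nn_dist[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, extra / dist, np.inf)
        false = ratio > r_tol
        if a_tol is not None:
            lifted = np.sqrt(dist**2 + extra**2)
            false = false | (lifted / attractor_size > a_tol)
        fractions[d - 1] = false.mean() if false.size else 1.0
        if chosen == 0 and fractions[d - 1] <= cutoff:
            chosen = d
            break
    if chosen == 0:
        warnings.warn(
            f"FNN fraction never fell below {cutoff:.0%}; using max_dim={max_dim}",
            stacklevel=2,
        )
        chosen = max_dim
    return chosen, fractions


def estimate_embedding(
    series: SampledSeries,
    max_lag: int = DEFAULT_MAX_LAG,
    max_dim: int = DEFAULT_MAX_DIM,
    min_dim: int = 2,
    **fnn_kwargs,
) -> EmbeddingParams:
    """Full embedding-parameter estimate: AMI lag then FNN dimension.

    The returned dimension is floored at ``min_dim`` (a meaningful phase
    portrait needs at least a plane).
    """
    lag = select_lag(average_mutual_information(series, max_lag=max_lag))
    dim, _ = false_nearest_neighbors(series, lag, max_dim=max_dim, **fnn_kwargs)
    return EmbeddingParams(lag=lag, dim=max(dim, min_dim))
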