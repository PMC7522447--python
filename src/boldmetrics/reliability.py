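"""Test-retest consistency of subject x parcel metric matrices.

Three views of scan-to-scan reliability:

* :func:`matrix_correlation` — Pearson r over all flattened cells of two
  scans' matrices (how similar is the whole picture?).
* :func:`icc31` — two-way mixed-effects, consistency, single-measurement
  intraclass correlation ICC(3,1): sessions as fixed effects, units as
  random effects; insensitive to an additive session offset.
* :func:`averaged_correlation` — Pearson r of parcel profiles after
  averaging over subjects (or subject profiles after averaging over
  parcels), isolating where the reliable structure lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SubjectParcelMatrix",
    "ICCResult",
    "matrix_correlation",
    "icc31",
    "averaged_correlation",
]


@dataclass(frozen=True)
class SubjectParcelMatrix:
    """One metric evaluated for every subject x parcel in one scan session."""

    values: np.ndarray
    metric_label: str
    scan_label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected 2-D subject x parcel matrix, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"non-finite entries in {self.metric_label}/{self.scan_label}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """ICC(3,1) with its ANOVA mean-square components."""

    icc: float
    bms: float  # between-units mean square
    ems: float  # residual (error) mean square
    k: int      # number of sessions
    n: int      # number of units


def _check_shapes(A: SubjectParcelMatrix, B: SubjectParcelMatrix) -> None:
    if A.values.shape != B.values.shape:
        raise ValueError(
            f"shape mismatch: {A.values.shape} vs {B.values.shape}"
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def matrix_correlation(A: SubjectParcelMatrix, B: SubjectParcelMatrix) -> float:
    """Pearson correlation over all flattened subject x parcel cells."""
    _check_shapes(A, B)
    return _pearson(A.values.ravel(), B.values.ravel())


def icc31(
    A: SubjectParcelMatrix, B: SubjectParcelMatrix, unit: str = "subject_parcel"
) -> ICCResult:
    """ICC(3,1) between two sessions of the same metric.

    ``unit`` selects what counts as one measured unit: every subject-parcel
    cell (default, n = subjects x parcels), parcel means over subjects
    ("parcel_mean"), or subject means over parcels ("subject_mean").

    The two-way (units x sessions) ANOVA decomposition yields the
    between-units mean square BMS and the residual mean square EMS;
    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS) with k = 2 sessions.
    Consistency form: a constant shift between sessions leaves it at 1.
    """
    _check_shapes(A, B)
    if unit == "subject_parcel":
        a, b = A.values.ravel(), B.values.ravel()
    elif unit == "parcel_mean":
        a, b = A.values.mean(axis=0), B.values.mean(axis=0)
    elif unit == "subject_mean":
        a, b = A.values.mean(axis=1), B.values.mean(axis=1)
    else:
        raise ValueError(f"unknown unit: {unit!r}")
    table = np.column_stack([a, b])
    n, k = table.shape
    if n < 3:
        raise ValueError(f"need >= 3 units for ICC, got {n}")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom == 0:
        raise ValueError("ICC undefined: all units identical")
    return ICCResult(icc=float((bms - ems) / denom), bms=float(bms),
                     ems=float(ems), k=k, n=n)


def averaged_correlation(
    A: SubjectParcelMatrix, B: SubjectParcelMatrix, axis: str = "parcel"
) -> float:
    """Pearson r between per-parcel (or per-subject) means of two sessions.

    ``axis="parcel"`` averages over subjects and correlates the parcel
    profiles; ``axis="subject"`` averages over parcels and correlates the
    subject profiles.
    """
    _check_shapes(A, B)
    if axis == "parcel":
        return _pearson(A.values.mean(axis=0), B.values.mean(axis=0))
    if axis == "subject":
        return _pearson(A.values.mean(axis=1), B.values.mean(axis=1))
    raise ValueError(f"unknown axis: {axis!r}")
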