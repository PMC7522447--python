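"""End-to-end study orchestration.

Two studies are wired here:

* the *simulation study* — 100 filtered-Gaussian series per condition,
  full complexity suite, summarised as two tables: metrics by passband
  (0.01-0.1, 0.1-0.2, 0.01-0.2 Hz) and metrics by added-noise level
  (none, 0.2 sigma, 0.5 sigma, each on the 0.01-0.1 Hz band);

* the *cohort study* — generate a surrogate multi-scan cohort, evaluate
  every basic property and complexity metric for every subject x parcel
  x scan, then (a) test-retest reliability (full-matrix correlation,
  ICC(3,1), parcel- and subject-averaged correlations) and (b) the
  association analysis: Pearson correlation of each basic property with
  each complexity metric across parcel means, Bonferroni-corrected over
  the 4 x 3 = 12 tests (alpha 0.05, so p < 0.0042 flags significance).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import MetricConfig, complexity_suite
from .reliability import SubjectParcelMatrix, averaged_correlation, icc31, matrix_correlation
from .series import DEFAULT_DT, SampledSeries
from .signal_properties import basic_props
from .synthetic import CohortSpec, add_noise, bandpass, generate_cohort, generate_gaussian_series

logger = logging.getLogger("boldmetrics")

__all__ = [
    "AssociationResult",
    "StudyConfig",
    "BASIC_METRICS",
    "COMPLEXITY_METRICS",
    "PASSBANDS",
    "NOISE_LEVELS",
    "parcelwise_associations",
    "fullmatrix_associations",
    "simulation_condition",
    "run_simulation_study",
    "cohort_metric_matrices",
    "reliability_table",
    "run_cohort_study",
]

BASIC_METRICS = ("mean", "sd", "tsnr", "waf")
COMPLEXITY_METRICS = ("corr_dim", "lyap", "apen")

#: The three passbands of the filtering experiment, in Hz.
PASSBANDS = ((0.01, 0.1), (0.1, 0.2), (0.01, 0.2))

#: Added-noise amplitudes (fractions of the filtered-series SD).
NOISE_LEVELS = (0.0, 0.2, 0.5)

ALPHA = 0.05
N_TESTS = len(BASIC_METRICS) * len(COMPLEXITY_METRICS)  # 12


@dataclass(frozen=True)
class AssociationResult:
    """One basic-property vs complexity-metric correlation."""

    basic_metric: str
    complexity_metric: str
    r: float
    p: float
    significant: bool


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to rerun a study end to end."""

    seed: int = 0
    n_series: int = 100
    n_timepoints: int = 1200
    dt: float = DEFAULT_DT
    passbands: tuple[tuple[float, float], ...] = PASSBANDS
    noise_levels: tuple[float, ...] = NOISE_LEVELS
    noise_band: tuple[float, float] = (0.01, 0.1)
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    cohort: CohortSpec | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.cohort is not None:
            out["cohort"] = self.cohort.to_dict()
        return out


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    res = stats.pearsonr(x, y)  # two-sided t test, n-2 dof
    return float(res.statistic), float(res.pvalue)


def parcelwise_associations(
    basic: Mapping[str, SubjectParcelMatrix],
    complexity: Mapping[str, SubjectParcelMatrix],
    alpha: float = ALPHA,
    n_tests: int = N_TESTS,
) -> list[AssociationResult]:
    """Correlate parcel means of each basic property with each complexity metric.

    Each matrix is averaged over subjects to a per-parcel vector; every
    basic x complexity pair gets a Pearson r and two-sided p, flagged
    significant when p < alpha / n_tests (Bonferroni).
    """
    shapes = {m.values.shape for m in list(basic.values()) + list(complexity.values())}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {shapes}")
    out = []
    for bname, bmat in basic.items():
        for cname, cmat in complexity.items():
            r, p = _pearson_with_p(
                bmat.values.mean(axis=0), cmat.values.mean(axis=0)
            )
            out.append(
                AssociationResult(bname, cname, r, p, significant=p < alpha / n_tests)
            )
    return out


def fullmatrix_associations(
    basic: Mapping[str, SubjectParcelMatrix],
    complexity: Mapping[str, SubjectParcelMatrix],
    alpha: float = ALPHA,
    n_tests: int = N_TESTS,
) -> list[AssociationResult]:
    """As :func:`parcelwise_associations` but on flattened matrices (no averaging)."""
    shapes = {m.values.shape for m in list(basic.values()) + list(complexity.values())}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {shapes}")
    out = []
    for bname, bmat in basic.items():
        for cname, cmat in complexity.items():
            r, p = _pearson_with_p(bmat.values.ravel(), cmat.values.ravel())
            out.append(
                AssociationResult(bname, cname, r, p, significant=p < alpha / n_tests)
            )
    return out


def simulation_condition(
    band: tuple[float, float],
    noise: float,
    n_series: int,
    T: int,
    dt: float,
    seed: int,
    config: MetricConfig,
) -> pd.DataFrame:
    """One simulation condition: generate, filter, (optionally) add noise, measure.

    Returns a per-series DataFrame of lag, dim and the three complexity
    metrics.  The noise seed is derived from ``seed`` so the clean and
    noisy conditions share base series, as in the original experiment
    (noise is *added to* the filtered series).
    """
    series = generate_gaussian_series(n_series, T, dt, seed=seed)
    rows = []
    noise_rng = np.random.SeedSequence([seed, int(noise * 1000)]).generate_state(n_series)
    for i, s in enumerate(series):
        f = bandpass(s, *band)
        if noise > 0:
            f = add_noise(f, noise, seed=int(noise_rng[i]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = complexity_suite(f, config)
        rows.append(
            dict(series=i, lag=res.params.lag, dim=res.params.dim,
                 corr_dim=res.corr_dim, lyap=res.lyap, apen=res.apen)
        )
    return pd.DataFrame(rows)


def _summarise(per_series: pd.DataFrame, label: str) -> dict:
    row = {"condition": label}
    for m in COMPLEXITY_METRICS:
        row[f"{m}_mean"] = per_series[m].mean()
        row[f"{m}_sd"] = per_series[m].std(ddof=1)
    return row


def run_simulation_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The filtering-and-noise experiment: two summary tables.

    Table one: mean +/- SD of each complexity metric for Gaussian series
    filtered to each passband.  Table two: the 0.01-0.1 Hz band with added
    Gaussian noise at each level (the no-noise row is by construction the
    same condition as the first row of table one).  All randomness derives
    from ``config.seed``.
    """
    band_rows, noise_rows = [], []
    cache: dict[tuple, pd.DataFrame] = {}

    def condition(band, noise):
        key = (band, noise)
        if key not in cache:
            logger.info("simulation condition band=%s noise=%.1f", band, noise)
            cache[key] = simulation_condition(
                band, noise, config.n_series, config.n_timepoints,
                config.dt, config.seed, config.metric_config,
            )
        return cache[key]

    for band in config.passbands:
        df = condition(band, 0.0)
        band_rows.append(_summarise(df, f"{band[0]:g}-{band[1]:g} Hz"))
    for noise in config.noise_levels:
        df = condition(config.noise_band, noise)
        label = "none" if noise == 0 else f"{noise:g} sigma"
        noise_rows.append(_summarise(df, label))
    return pd.DataFrame(band_rows), pd.DataFrame(noise_rows)


def cohort_metric_matrices(
    cohort: Mapping[str, np.ndarray],
    dt: float,
    config: MetricConfig = MetricConfig(),
) -> dict[str, dict[str, SubjectParcelMatrix]]:
    """Evaluate every metric for every subject x parcel in every scan.

    Returns ``{scan: {metric: SubjectParcelMatrix}}`` for the four basic
    properties and three complexity metrics.  Basic properties and
    complexity metrics are computed on the same generated series (the
    suite z-scores internally for the complexity stage).
    """
    out: dict[str, dict[str, SubjectParcelMatrix]] = {}
    for scan, data in cohort.items():
        n_sub, T, n_parc = data.shape
        mats = {m: np.empty((n_sub, n_parc)) for m in BASIC_METRICS + COMPLEXITY_METRICS}
        for s in range(n_sub):
            for p in range(n_parc):
                ts = SampledSeries(data[s, :, p], dt)
                bp = basic_props(ts)
                mats["mean"][s, p] = bp.mean
                mats["sd"][s, p] = bp.sd
                mats["tsnr"][s, p] = bp.tsnr
                mats["waf"][s, p] = bp.waf
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cx = complexity_suite(ts, config)
                mats["corr_dim"][s, p] = cx.corr_dim
                mats["lyap"][s, p] = cx.lyap
                mats["apen"][s, p] = cx.apen
        out[scan] = {
            m: SubjectParcelMatrix(v, metric_label=m, scan_label=scan)
            for m, v in mats.items()
        }
        logger.info("metrics computed for scan %s (%d x %d)", scan, n_sub, n_parc)
    return out


def reliability_table(
    metrics: Mapping[str, Mapping[str, SubjectParcelMatrix]],
    reference_scan: str,
    comparison_scans: Sequence[str],
) -> pd.DataFrame:
    """Reliability of every metric between a reference scan and each comparison.

    One row per metric per scan pair: full-matrix Pearson CC, ICC(3,1) with
    its mean squares, and the parcel-/subject-averaged correlations.
    """
    rows = []
    for other in comparison_scans:
        for m in BASIC_METRICS + COMPLEXITY_METRICS:
            A, B = metrics[reference_scan][m], metrics[other][m]
            icc = icc31(A, B)
            rows.append(
                dict(
                    metric=m,
                    comparison=f"{reference_scan}-{other}",
                    cc=matrix_correlation(A, B),
                    icc=icc.icc,
                    bms=icc.bms,
                    ems=icc.ems,
                    parcel_r=averaged_correlation(A, B, axis="parcel"),
                    subject_r=averaged_correlation(A, B, axis="subject"),
                )
            )
    return pd.DataFrame(rows)


def _assoc_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def run_cohort_study(
    config: StudyConfig, out_dir: str | Path, force: bool = False
) -> dict[str, pd.DataFrame]:
    """Generate a cohort and run metrics, reliability and associations.

    Writes delimited-text tables (per-scan metric matrices, reliability,
    parcelwise and full-matrix associations) plus a JSON run manifest to
    ``out_dir``.  Refuses to overwrite an existing output directory unless
    ``force`` is set.  Returns the tables keyed by name.
    """
    if config.cohort is None:
        raise ValueError("StudyConfig.cohort must be set for a cohort study")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out_dir} is not empty; pass force=True to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    spec = config.cohort
    cohort = generate_cohort(spec)
    metrics = cohort_metric_matrices(cohort, spec.dt, config.metric_config)

    scans = list(spec.scans)
    reference = scans[0]
    rel = reliability_table(metrics, reference, scans[1:])

    basic = {m: metrics[reference][m] for m in BASIC_METRICS}
    cx = {m: metrics[reference][m] for m in COMPLEXITY_METRICS}
    parcelwise = _assoc_frame(parcelwise_associations(basic, cx))
    fullmatrix = _assoc_frame(fullmatrix_associations(basic, cx))

    long_rows = []
    for scan, mats in metrics.items():
        for m, mat in mats.items():
            for s in range(mat.n_subjects):
                for p in range(mat.n_parcels):
                    long_rows.append(
                        dict(scan=scan, metric=m, subject=s, parcel=p,
                             value=mat.values[s, p])
                    )
    metric_long = pd.DataFrame(long_rows)

    tables = {
        "metrics": metric_long,
        "reliability": rel,
        "associations_parcelwise": parcelwise,
        "associations_fullmatrix": fullmatrix,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {"config": config.to_dict(), "tables": sorted(tables)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("cohort study written to %s", out_dir)
    return tables
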