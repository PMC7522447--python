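# Methods

`boldmetrics` asks a deliberately skeptical question about nonlinear
complexity metrics applied to resting-state BOLD time series: how much of
what correlation dimension, the largest Lyapunov exponent and approximate
entropy report is dynamics, and how much is ordinary signal properties —
amplitude, signal-to-noise ratio, and above all the frequency profile?
The package provides (1) the per-series estimators, (2) a test-retest
reliability layer, (3) an association analysis between basic properties
and complexity metrics, and (4) the synthetic inputs that make the whole
chain reproducible without any external data: filtered Gaussian noise for
the controlled experiments, and a surrogate multi-scan cohort for the
reliability and association analyses.

## Signal model and generators

**Filtered-noise experiment.** The reference conditions are 100 i.i.d.
standard-normal series of 1200 points at a sampling interval of
dt = 0.72 s (the repetition time of modern high-temporal-resolution
rs-fMRI protocols; 1200 points is one standard scan). Each series is
bandpass filtered — 0.01–0.1 Hz, 0.1–0.2 Hz, or 0.01–0.2 Hz — with an
order-4 Butterworth applied forward and backward (`sosfiltfilt`), the
standard zero-phase practice in rs-fMRI. For the noise conditions,
i.i.d. Gaussian noise with SD equal to 0.2 or 0.5 times the
filtered-series SD is added to the 0.01–0.1 Hz series. Series are
z-scored before metric computation (mirroring the z-scoring of parcel
time courses in standard preprocessing); a config switch disables this.

**Surrogate cohort.** Parcel p of subject s in one scan is

    x(t) = baseline[p] · gain[s, scan] + scale[s, scan] · amp[p] · (osc_p(t) + noise_sd[p] · w(t))

where `osc_p` is unit-SD Gaussian noise bandpassed to a ±0.015 Hz window
around the parcel's target weighted average frequency (defaults spread
over 0.05–0.08 Hz, the parcel-mean range observed in large rs-fMRI
cohorts), `w` is white noise with parcel-specific amplitude (defaults
0.1–0.5), `baseline` spans 600–1200 intensity units (coil-sensitivity
variation), `amp ∝ baseline` (BOLD fluctuations are a fraction of local
signal level), and the subject gain/scale factors are stable traits with
small per-scan jitter (1% on gain, 5% on scale — scanner drift and
physiological state). All parcel and subject parameters are reused across
scans; only noise realizations differ. That one design choice is what
makes test-retest reliability measurable, and the parcel-specific noise
level is what couples the frequency profile to the complexity metrics: a
noisier parcel has a flatter spectrum (higher WAF), higher entropy, and
a faster-saturating divergence curve (lower Lyapunov estimate), by
construction.

What the generator does **not** emulate: head motion, physiological
(cardiac/respiratory) rhythms, spatial correlation between parcels,
scanner drift within a scan, non-Gaussian amplitude distributions, and
any genuinely nonlinear neural dynamics. Passing tests on this cohort
therefore demonstrate that the pipeline recovers the structure this
generative model plants — frequency/noise-driven covariation of WAF and
complexity, parcel-dominated reliability — not that real BOLD complexity
is noise. The absence of deterministic structure is intentional: it shows
the metrics respond strongly to linear spectral properties alone.

## Basic signal properties

Mean and SD are the sample moments (n−1 denominator; at T = 1200 the
choice is negligible). tSNR is mean/SD, and is an explicit error — not an
infinity — for constant input. The power spectrum is a Welch estimate
with 8 Hamming-tapered segments at 50% overlap (segment length
floor(T/4.5), FFT length the next power of two, at least 256), giving a
density on [0, Nyquist]. The weighted average frequency is

    WAF = Σ P_x f_x / Σ P_x                       (power-weighted mean)

with a discrete variant — the default — that returns the smallest grid
frequency at which the cumulative Σ P_x f_x first exceeds half its total.
The discrete variant is always a member of the frequency grid; both are
invariant to rescaling the power vector. The f = 0 bin is included (it
contributes nothing to the numerator). In `basic_props` the WAF is
computed on the demeaned series: a large static baseline otherwise leaks
through the window into the lowest bins and pins the half-sum there.

## Embedding estimation

The embedding lag is the first local minimum of the average mutual
information between the series and its lagged copy, estimated on a 10×10
histogram with equiprobable (quantile) bins — robust at T ≈ 1200
regardless of the marginal. A lag τ is a first minimum when
AMI(τ) < AMI(τ−1) and AMI(τ) ≤ AMI(τ+1) (ties break toward smaller lag);
a curve with no interior minimum falls back to the argmin with a warning.
The default search range is 20 samples (≈14 s), comfortably above the
3–9-sample regime these signals produce.

The embedding dimension uses the false-nearest-neighbor test: each
point's nearest neighbor in d dimensions (Euclidean metric, ties toward
the smaller index, Theiler window = lag so temporally adjacent samples
never count as neighbors) is lifted to d+1, and the pair is false when
the added-coordinate distance exceeds R_tol = 15 times the d-dimensional
distance. The first d with a false fraction ≤ 10% is accepted (floor 2,
cap 10). The classical second criterion — lifted distance above A_tol = 2
attractor sizes — is implemented but **disabled by default**: on
stochastic signals it has a noise floor near 15% at every dimension, so
the fraction never clears the cutoff and every series saturates at the
cap. With the distance-ratio test alone, band-limited BOLD-like signals
land at dimension 3–4 with lags of 3–9 samples, the regime reported for
real parcel data, which is the calibration surface this estimator is held
to.

## Complexity metrics and their conventions

All three metrics consume the per-series embedding (estimated per parcel
per subject; no pooling). Two conventions below were fixed by a one-time
calibration against the filtered-noise reference condition and then
frozen; they are choices about reproducing the established tooling's
output scale, not tunable parameters.

**Correlation dimension.** Grassberger–Procaccia: C(r) is the fraction of
admissible point pairs (temporal separation > Theiler window = lag)
closer than r, on 10 log-spaced radii between the 1st and 50th percentile
of pairwise distances; the estimate is the least-squares slope of
log C(r) vs log r, with an explicit failure when fewer than 3 radii have
0 < C(r) < 1. The correlation integral is evaluated on a **fixed
two-dimensional embedding** by default (`corr_dim_dim = 2`; the estimated
lag is used). Rationale: with the FNN dimension the estimate is strongly
band-dependent on filtered noise (≈2.0 in the 0.01–0.1 Hz band but ≈1.6
at 0.1–0.2 Hz), whereas the reference results for this experiment are
strikingly invariant (≈1.95 in every band and at every noise level) —
behavior only consistent with the common tooling default of dimension 2,
under which our estimate is 1.87 everywhere. Set `corr_dim_dim=None` to
use the estimated dimension (then expect values near the embedding
dimension on stochastic signals, as in the ≈3.3 reported for real data
with dims 3–4).

**Largest Lyapunov exponent.** Rosenstein's method: each point is paired
with its nearest neighbor at temporal distance greater than the series'
mean period (reciprocal of the power-weighted mean frequency); the mean
log distance between the paired trajectories is tracked k steps forward
and the exponent is the least-squares slope over steps 1–5, in per-sample
units. Reported values multiply this slope by the package constant
`LYAP_UNIT_SCALE = 4.15`, calibrated once so that the reference condition
(100 series, 0.01–0.1 Hz) reports 0.85, the established tooling's scale
for that condition; the per-sample slope is recovered by passing
`unit_scale=1`. A divergence curve that fails to expand over the fit
window yields a warning plus the best-fit slope, not an error.

Known residual: under this estimator added noise monotonically *lowers*
the fitted slope (0.205 → 0.114 → 0.042 per sample at 0σ/0.2σ/0.5σ).
The direction matches the qualitative finding — noise degrades the
manifold and suppresses coherent divergence — and the 0.2σ > 0.5σ
ordering is robust (many SEM), but the absolute reference values for the
noise conditions (1.32, 0.92) are not reproduced by any fit window,
neighbor-separation rule, embedding dimension (2–8) or sampling-interval
convention we examined; they appear to reflect tool internals that the
method description does not determine. We report our estimator's values.

**Approximate entropy.** Pincus ApEn = Φ_m(r) − Φ_{m+1}(r), with Φ_m the
mean log fraction of lag-strided m-templates matching within Chebyshev
distance r, self-matches included (so a constant series gives exactly 0
and the statistic is always finite). Defaults: m = 2 with the estimated
AMI lag, r = 0.2 × SD (a `var` radius mode is available; the two coincide
on z-scored input). m = 2 rather than the FNN dimension is again the
tooling-default calibration: with m = FNN dim the reference value 1.73
is unreachable (we measure ≈0.50), with m = 2 we measure 1.62.
`apen_m=None` selects the FNN dimension; `apen_classic=True` selects the
textbook (m=2, lag=1).

A second residual follows from the reference tables' own internal
tension: the no-noise reference (1.73) exceeds the 0.2σ reference (1.55),
yet entropy must *increase* with added noise (and does, in both the
reference noise rows and our estimates: 1.62 → 1.68 → 1.71). No single
convention can satisfy both numbers to printed precision; ours sits
between them and preserves the monotonicity.

**Band invariance.** Our correlation dimension is band-invariant to well
within one pooled SD. ApEn and the Lyapunov slope are not perfectly so:
a 0.1–0.2 Hz narrowband sampled at its own quarter-period lag is
genuinely more regular (ApEn 1.25 vs 1.62), and the wide 0.01–0.2 Hz
band's divergence curve oscillates within the fit window (slope 0.35 vs
0.85 in reported units). The uniformity of the reference tables across
bands is, as far as we can determine, another tool-internal artifact; we
report the estimator's honest band dependence.

## Reliability

ICC(3,1) — two-way mixed effects, sessions fixed, consistency, single
measurement — is computed from the standard two-way ANOVA decomposition:
ICC = (BMS − EMS)/(BMS + (k−1)·EMS), k = 2 sessions. The default unit of
analysis is the subject-parcel cell (n = subjects × parcels), with
`parcel_mean` / `subject_mean` variants. Consistency ICC ignores additive
session offsets by construction. Non-finite inputs are refused outright
rather than pairwise-deleted. Full-matrix Pearson correlation and the
parcel-/subject-averaged correlations complete the reliability surface.
On the surrogate cohort, parcel-averaged correlations exceed
subject-averaged ones for every metric that carries parcel structure;
the dimension-2 correlation dimension is nearly constant across parcels
and so, like its real-data counterpart, shows essentially no full-matrix
reliability.

## Associations

Each basic property (mean, SD, tSNR, WAF) is correlated with each
complexity metric (correlation dimension, Lyapunov, ApEn) after averaging
over subjects — Pearson r with the two-sided t-test (n−2 df), flagged
significant under Bonferroni correction for the 12 tests (α = 0.05, so
p < 0.0042). A full-matrix variant correlates the flattened
subject × parcel matrices; averaging over subjects removes subject-level
noise, so the parcel-averaged |r| bounds the full-matrix |r| from above
on this cohort. Parcel-level p-values treat parcels as independent
observations; spatial autocorrelation (absent in the generator, present
in real data) would inflate significance on real inputs.

## Problem sizes and numerical choices

The shipped studies use 100 series per simulation condition, a
10 × 30 × 4 cohort in the analysis drivers, and a 20 × 100 × 2 cohort
for the sign-recovery and reliability checks; these reproduce the target
quantities with comfortable Monte-Carlo margins. Degenerate inputs fail
loudly and early: constant series are rejected at z-scoring/AMI, an
unreachable FNN cutoff warns and caps, a starved correlation integral
raises with diagnostics, and the cohort study refuses to overwrite
existing outputs without `force`. Fixed seeds make every generator and
every study bit-reproducible; the acceptance script derives all
randomness from its `--seed`.
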