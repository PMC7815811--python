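# Methods

`dfcpipe` re-implements a resting-state dynamic functional connectivity
(dFC) analysis as a tested pipeline, exercised end-to-end on synthetic
multi-region BOLD-like cohorts. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish about real data.

## Connectivity model

Let `x_i(t)` be the signal of region `i` over `T` volumes sampled at
repetition time TR (2.2 s in the emulated protocol, 197 usable volumes
after discarding the first 5 of 202).

**Static FC.** `sFC(i,j) = |r(x_i, x_j)|`, the absolute Pearson
correlation over the whole series. Absolute values put anti-correlated and
correlated pairs on the same footing; entries lie in [0, 1].

**Tapered sliding windows.** Windows of `L = 27` volumes (59.4 s) advance
in steps of `S = 5` volumes (11 s), giving `W = floor((T - L)/S) + 1`
windows (35 at T = 197). A rectangular window of ones is convolved with a
Gaussian kernel (sd 9 volumes, truncated at ±3 sd); the full convolution
is evaluated at the L in-window positions and renormalized to sum to one.
The resulting weights `w` are symmetric, strictly positive, and maximal at
the window centre; they damp the contribution of samples near the window
edges and hence high-frequency estimation noise.

**Weighted correlation.** Within a window, with weights summing to one:
`m_i = Σ w x_i`, `c_ij = Σ w (x_i - m_i)(x_j - m_j)`,
`r_ij = c_ij / sqrt(c_ii c_jj)`. With uniform weights this reduces exactly
to Pearson correlation (asserted to 1e-12).

**dFC statistics.** Per connection across the window stack:

- *summed difference* (dFC-diff): `Σ_w |r_{w+1} - r_w|`, computed on
  signed window correlations — only the window-to-window differences are
  absolutized;
- *coefficient of variation* (dFC-cv): `σ/µ` of the **absolutized**
  window correlations, with the sample (`ddof=1`) standard deviation.
  Population sd is available via a flag; the convention is stated because
  the two differ by `sqrt(W/(W-1))` ≈ 1.5% at W = 35.

Global values average the unique off-diagonal cells; undefined cells
(zero variance, zero mean strength) become NaN, are excluded from means
and counted, never imputed.

**Subnetwork values.** A subnetwork is two disjoint label sets — here the
bilateral basal ganglia (caudate, putamen, globus pallidus) and three
default-mode regions (medial prefrontal cortex, posterior cingulate
cortex, precuneus). The default mode averages every pair among the union
(between-set *and* within-set connections), the reading most consistent
with "connectivity between all selected regions"; a between-sets-only mode
is available. Normalized values divide the subnetwork mean by the
subject's global mean of the same measure, correcting inter-subject global
connectivity differences.

## Preprocessing and QC

- **Volume discarding**: the first 5 volumes are dropped (scanner
  equilibration).
- **Framewise displacement**: sum of absolute frame-to-frame deltas of the
  three translations plus the three rotations converted to arc length on a
  50 mm sphere. The source protocol names no FD formula; this is the
  standard auditable choice.
- **Motion exclusion**: a subject is excluded when the fraction of
  transitions with FD > 0.5 mm reaches 20%. The boundary is inclusive
  (≥ 20% excludes); both threshold and fraction are configurable.
- **Nuisance regression**: OLS residuals against an intercept plus
  caller-supplied signals (e.g. white-matter/CSF means). Tissue
  segmentation is out of scope; signals are inputs.
- **High-pass filter** (0.01 Hz): regression against a discrete-cosine
  drift basis containing every DCT function with period longer than
  1/cutoff, then mean-centring. A basis projection was chosen over a
  recursive filter for exact reproducibility and absence of edge
  transients; pass-band amplitude is preserved within 5% and a linear
  drift is attenuated below 1% of its variance.
- **Region extraction**: voxels whose temporal-mean intensity falls below
  `robust_min + 0.25 × (robust_max − robust_min)` are excluded, with the
  robust range the [2nd, 98th] percentile of the mean image over the whole
  grid — background/dropout anchors the low end, as in FSL-style robust
  ranges. Regions keeping fewer than 50% of their voxels (configurable;
  the source protocol does not state its coverage criterion) are dropped
  with a warning. Retained regions are averaged over surviving voxels.

## Surrogate null model

Sliding windows register sampling fluctuations as apparent dynamics, so
observed dFC is compared against phase-randomization surrogates: the
discrete Fourier transform of each region's series keeps its amplitudes
while **one** random phase sequence is added identically to every region's
spectrum (DC and Nyquist bins untouched so the inverse transform is real).
The common-phase construction is essential: it preserves the full-series
cross-correlation matrix (and each region's autocovariance) exactly, so
the surrogate distribution answers "how much dFC would a stationary
process with this sFC and autocorrelation produce?". Independent
per-region phases would destroy sFC and invalidate the null; tests assert
the preservation to 1e-10 (spectra) and 1e-8 (correlations).

Per subject, 100 surrogates (default) yield a distribution of global and
subnetwork dFC (subnetwork values un-normalized for this comparison); a
paired t-test across subjects compares real values against per-subject
surrogate means. For efficiency the ensemble path computes windowed
weighted correlations as sliding weighted sums of pair products, batched
over surrogates; its equality with the per-window matrix path is asserted
to 1e-10.

Calibration and power, measured by the test suite at 20 subjects,
T = 1970, 100 surrogates, 50 cohort replicates, on 8-region networks
(dFC and its null act per connection, so these properties do not depend on
network size): null rejection ≤ 12% at α = 0.05 on stationary cohorts;
rejection with the correct (real > surrogate) direction in ≥ 95% of
modulated cohorts at amplitude 0.3.

## Clinical statistics

- **CIS-20r scoring**: 20 items on 1–7, four subscales (8/4/3/5 items in
  order), total = subscale sum ∈ [20, 140], severe fatigue at total ≥ 76.
  The instrument's exact item keying and reverse-scored items are not
  public in the emulated protocol; the in-order mapping with no reversal is
  a documented stand-in and fully configurable.
- **Normality gate**: one-sample Kolmogorov–Smirnov against a normal with
  plug-in sample mean/sd (the common statistics-package behaviour),
  α = 0.05; constant samples are degenerate/non-normal.
- **Two-group comparisons**: t-test when both samples pass the gate
  (pooled variance, switching to Welch when the variance ratio exceeds
  4:1), otherwise Mann–Whitney U. Paired comparisons gate the differences:
  paired t vs. Wilcoxon signed-rank.
- **Hierarchical forward regression**: three ordered blocks —
  demographics/clinical, volumetrics, dFC predictors (global and
  subnetwork, both measures). Within each block the candidate with the
  smallest partial-t p enters while p < 0.05; entered predictors are never
  removed. Variables are z-scored so coefficients are standardized β; ΔR²
  is reported per entry; incomplete rows are dropped listwise and counted.
  Forward selection inflates family-wise error — under a pure-noise
  outcome each candidate enters with roughly per-test α-level probability;
  the pipeline reports uncorrected results by design (matching the
  exploratory analysis it emulates) and logs this.
- **Post-hoc**: Spearman correlations of selected predictors with the
  fatigue total and subscales (uncorrected), and a Kruskal–Wallis omnibus
  with pairwise Mann–Whitney tests across controls / non-fatigued /
  fatigued patients, split at the cutoff of 76.

## Synthetic cohorts

The generator emulates the target study's dimensions: 224 regions,
202 volumes at TR 2.2 s, 35 patients and 19 controls.

- **Signal model**: zero-mean multivariate Gaussian with an instantaneous
  correlation target `C_t = C_0 + o_t · M`, where `C_0` is a random PSD
  profile with off-diagonals near 0.3 (jitter sd `0.1/sqrt(R)`, keeping the
  profile comfortably PSD at R = 224), `o_t` a unit sinusoid (period
  120 s) or a supplied piecewise-constant state sequence, and `M` a
  per-pair amplitude mask. No haemodynamic convolution is applied by
  default (`bold_lowpass` adds mild temporal smoothing). The sinusoid is
  discretized to 0.05-amplitude steps in cohort simulation so Cholesky
  factors are reused; the ≤ 0.025 target error is far below estimation
  noise. The modulation period default (120 s) is deliberately slower than
  the 59.4 s window: a modulation near the window length is averaged out
  by the window and would be invisible to the estimator.
- **Groups**: patients carry the full global modulation amplitude (0.15)
  plus a per-subject subnetwork amplitude ~ U(0, 0.3) on basal
  ganglia–DMN pairs; controls get half the global amplitude and no
  subnetwork boost.
- **Fatigue link**: for patients,
  `total = 46 + 9·EDSS − 240·(driver − 1) + N(0, 14)`, clipped to
  [20, 140], where the driver is the subject's realized normalized
  subnetwork dFC-cv (values sit near 1, hence the centring). Effect sizes
  were fixed at design time so each true predictor has a standardized
  effect ≈ 0.5–0.6 — clearly detectable at n = 35 — while patient totals
  centre near 74 with sd ≈ 25. Controls draw totals around 45 with the
  same noise and no dynamics link. Totals are expanded into 20 item
  responses in [1, 7] that sum exactly to the total.
- **Covariates**: age ~ N(42, 10) truncated to [18, 65]; sex Bernoulli
  (57% female); education ordinal 3–7; EDSS uniform on {1.0, …, 6.0} in
  0.5 steps; disease duration ~ N(11, 7) truncated positive; medication
  50/50 first/second line; volumetrics (normalized GM/WM volume, log
  lesion volume) as noise covariates with a mild patient atrophy shift.
- **Motion**: per-transition displacement around a 0.1 mm baseline with
  0.8 mm spikes at probability 0.02, split across the six rigid-body
  channels so the implied FD reproduces the drawn values exactly.
- **Seeding**: one master seed expands into independent per-subject
  substreams (`numpy` SeedSequence spawning), so cohorts are
  bit-reproducible and subjects independent.

**What passing tests show — and don't.** The synthetic data are Gaussian,
stationary-or-sinusoidally-modulated, free of haemodynamic convolution,
physiological noise, scanner drift and motion artefacts in the signal
itself, and the fatigue link is exactly linear in the realized driver.
Passing tests therefore establish the *correctness* of the computations
and the *statistical behaviour* of the null model and regression under
known ground truth — not that real MS resting-state data satisfy those
generative assumptions, and not the effect sizes of any real cohort.

## Numerical choices and degenerate inputs

- Windows are 0-based half-open; trailing volumes not covered by a full
  window are dropped.
- Weighted correlations are clipped to [−1, 1] against rounding excursions.
- Zero-variance regions/windows and zero-mean-strength connections yield
  NaN with a warning; summaries skip NaN and log counts.
- The ensemble fast path centres each series before forming moment sums to
  avoid cancellation in `E[x²] − m²`.
- Identical samples short-circuit to (statistic 0, p 1) in the paired and
  two-group tests where the underlying rank tests are undefined.
- Pipeline failures write a `FAILED` marker naming the stage and preserve
  partial outputs.

## Problem sizes used by the test and acceptance runs

Calibration/power: 50 replicates × 20 subjects × 100 surrogates at
T = 1970 on 8-region networks. Regression recovery: 20 pipeline replicates
at the full default scale (224 regions, 35 + 19 subjects, 197 usable
volumes). The acceptance script reports the same quantities at a reduced
25 × 12 × 60 null/power design and 10 recovery replicates.

## Known limitations

- No state-based (k-means), frequency-resolved, or graph-theoretic dFC.
- No motion correction, registration, segmentation or ICA denoising; the
  pipeline starts from denoised series or labelled image fixtures.
- The CIS-20r item mapping is a stand-in, not the published instrument key.
- Forward selection's error inflation is reported, not corrected.
- The surrogate comparison assumes the analyzed series are (approximately)
  stationary Gaussian under the null; heavy-tailed or strongly nonlinear
  signals would call for amplitude-adjusted surrogates, which are out of
  scope.
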