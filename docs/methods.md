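# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `neoconn`.

## Connectivity model

Each ROI series is z-scored with the sample SD (denominator T−1); a
constant series raises rather than being silently zeroed. The global
nuisance regressor *g* is the z-score of the across-ROI mean of the
**raw** (relative-signal-change) series — "mean, then normalize". The
alternative reading (z-score each ROI, then average) is exposed as
`normalize_global_first=True` in `compute_rsfc`; with homogeneous
synthetic amplitudes the two differ negligibly, but the switch matters
for real data with heterogeneous ROI variances.

The connectivity coefficient B_{i→j} is the slope on *z_i* in the
least-squares fit of *z_j* on {intercept, *z_i*, *g*}. An intercept is
always included as numerical hygiene; because every variable has
exactly zero mean it is exactly zero, which lets the implementation use
centered Gram products (one matrix product per subject instead of
N(N−1) explicit solves) while remaining bit-consistent with the
explicit design-matrix fit — the test suite asserts agreement with an
explicit (XᵀX)⁻¹Xᵀy oracle to 1e−10. The fit is not symmetric in
(i, j); the reported edge is the average of the two directed
coefficients. A source ROI collinear with the global signal makes the
design rank-deficient and raises an error naming the ROI.

Nodal strength is implemented exactly as the mean of squared edge
values. Because the name "strength" suggests a root-mean-square, an
opt-in `rms=True` switch returns the square root; results are flagged
by the caller. The positive-connectivity control zeroes negative edges
after symmetrization.

## Spectral model

fALFF uses the raw one-sided periodogram (boxcar window, mean removal,
no Welch averaging, no taper): analytically simple, exactly
Parseval-consistent (the non-DC power sums to the population variance),
and therefore testable against closed forms. Band membership is closed
on both ends with a 1e−12 Hz tolerance so that band edges placed
exactly on a DFT bin (e.g. Nyquist itself) include that bin regardless
of floating-point representation. The DC bin is always excluded. The
default total-power floor is the series' own fundamental 1/(T·TR) —
this keeps short test series valid and evaluates to the conventional
0.0039 Hz at the default scan length (164 volumes, TR 1.555 s).
Whether a tapered or detrended spectrum would better match any given
acquisition pipeline is left to a config hook; only the ratio is
consumed downstream, which is invariant to overall scaling.

## Univariate statistics

Feature-wise association is the Pearson correlation with GA, tested
with t = r·√(df/(1−r²)), df = n−2, two-sided. p-values are clipped
into (0, 1e−300] ∪ (0,1] before FDR so that perfectly collinear
features (p = 0 to double precision) remain inside the BH domain.
Constant features get NaN statistics, a warning, and are excluded from
the FDR family size. BH (not BY) is used: the standard reading of
"false discovery rate" without a dependence argument.

Group contrasts of mean edge–GA correlation resample **subjects** with
replacement (preserving inter-feature dependence), recompute all
per-feature correlations, and summarize the difference of group mean
Fisher-z values as z = mean/SD across resamples with one-sided
p = 1−Φ(|z|); one-sided because the contrasts are directional. A
feature-resampling mode exists for sensitivity analysis. When the two
groups are numerically identical the bootstrap SD is pure float noise;
an SD below 1e−10 reports z = 0 / p = 0.5 rather than noise-amplified
garbage. The default iteration count is 10⁵; tests and the desk-scale
study configuration use 10³–2·10³, which changes z by O(1/√n_boot).

## PLS nested cross-validation

`PlsModel` standardizes features (training data only; parameters
stored) and centers the response, then delegates the core decomposition
to scikit-learn's NIPALS `PLSRegression` with `scale=False`. NIPALS
components are computed sequentially, so the first k components of an
order-K fit equal an order-k fit; `coef_at(k)` rebuilds the submodel
coefficients as W(PᵀW)⁻¹Qᵀ, letting one fit per inner fold score the
entire component path (verified against fresh per-k fits to 1e−10).
β-weights are reported per SD of feature, comparable across metrics;
raw-unit weights are also stored.

The outer loop is a seeded shuffled 10-fold partition (stratification
optional for classification); each inner loop is a 10-fold CV on the
outer training set selecting k ∈ [1, min(20, n_train−1, p)] by minimum
mean squared prediction error in both modalities — classification is
PLS regression on 0/1 labels scored continuously, no threshold is ever
applied, and ROC analysis consumes the raw scores. Ties in inner error
go to the smaller k. The final model is one full-data fit at the
rounded (half-up) mean of the ten per-fold optima.

AUC is the tie-corrected Mann–Whitney statistic; its z-score uses the
null-variance normal approximation SE₀ = √((n₁+n₂+1)/(12n₁n₂)). This
is one defensible choice among several; published z values for AUCs
are often not reproducible from AUC and group sizes alone, so AUC
z-scores should be compared across methods with care. Comparison of
classification performance between feature sets uses a subject-level
bootstrap of the AUC difference on out-of-fold scores; regression
performances are compared with the two-sample Fisher-z test
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), which ignores the
dependence induced by shared subjects (a dependent-correlations
variant is out of scope).

Subgroup contrasts equalize feature numerosity: the smaller group is
analysed once, the larger is subsampled to the smaller size with
`n_repeats` independent nested-CV runs whose correlations are averaged
on the Fisher-z scale (AUCs arithmetically) before comparison.
Prematurity labels follow the "at-or-above 32 weeks → 1" convention;
the threshold is a parameter.

## Synthetic cohort generator

The generator emulates a neonatal cohort of 88 infants born between 25
and 40 weeks GA, all scanned at PMA 40 weeks, with 90-ROI time series
of 164 volumes at TR 1.555 s (164 = round(255 s / 1.555 s)).

**Phenotypes.** GA is a truncated normal on [25, 40]. The parent
location and scale are solved numerically so the *truncated*
distribution has mean 33 and SD 3.75 weeks — using the target moments
as parent parameters would shrink the realized SD to ≈3.29.

**Latent maturity.** All GA-dependent brain effects are driven by a
latent maturational age = GA + N(0, 2.5 wk), shared between the
time-series and volume generators through a dedicated seed stream.
This is the biological-variability floor: it caps attainable inference
at corr(GA, latent) ≈ 0.83, keeping simulations out of the saturated
r→1 regime where directional comparisons become meaningless.

**Time series.** Each subject's target correlation matrix is
R = R_base + δ·E + subject noise, where R_base is block-structured
(within-lobe 0.30, homotopic pairs +0.20, floor 0.05), E carries signed
slopes (|slope| ~ U(0.01, 0.04)/week, random sign) on a random 10% of
edges, δ is the subject's latent maturity deviation in weeks, and the
subject noise perturbs every edge with SD 0.08. R is repaired to the
nearest valid correlation matrix by eigenvalue clipping at 1e−6 and
diagonal re-normalization (exactly symmetric, exactly unit diagonal).
Gaussian draws through the Cholesky factor are smoothed with an AR(1)
kernel (φ = 0.3, 24-sample burn-in) — BOLD-like autocorrelation
without a hemodynamic model — then re-weighted in the frequency domain
so that 10 effect ROIs get a low-band (≤0.1 Hz) variance fraction of
0.5 + 0.012·δ (clipped to [0.05, 0.95]); finally a shared AR(1) global
component with weight 0.5 is added to every ROI, giving the
global-signal regression something real to remove.

**Volumes.** V = (μ_j + b_j·δ)·(1 + 0.05·ε)·s, with per-lobe baselines
(2,500–5,200 mm³, ±30% per-ROI variation), b_j = +1.5%/week of baseline
for subcortical and medial temporal ROIs, −1.0%/week for medial
frontal ROIs, 0 elsewhere, and s a per-subject log-normal head-size
factor (CV 10%) shared across ROIs. Any non-positive volume raises.
The fALFF effect (10 ROIs, 0.012/week) is deliberately weaker than the
volume effect, so the designed ordering "Volume inference beats fALFF
inference" is part of the default conditions.

`null_mode=True` zeroes every slope, making the generator a calibrated
null: ~5% of univariate tests reject at α = 0.05, nested-CV AUC
averages 0.5 and out-of-fold r averages ≈0 over seeds.

All randomness flows from one master seed via named
`numpy.random.SeedSequence` child streams (atlas, cohort, timeseries,
volumes, maturation), so identical configs give byte-identical outputs
and each stage can be regenerated independently.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: head motion and its artifacts, hemodynamic
response shape, spatially smooth (distance-dependent) noise, arousal or
sedation state, non-Gaussian BOLD amplitude distributions, and any
realistic covariance between metrics beyond the shared maturity latent.
Effect sizes are chosen for a well-conditioned testbed, not fitted to
any empirical cohort.

## Numerical choices and degenerate inputs

- Atlas centroids receive 0.4 mm Gaussian jitter after mirroring:
  exact mirror symmetry would tie every within-hemisphere distance
  with its contralateral twin and make the long/short median split
  ambiguous. With distinct distances the median element (assigned to
  "short") yields the 2,003/2,002 split.
- Median-split ties, if present in user-supplied atlases, all go to
  "short" (documented; counts then deviate).
- Subcortical–subcortical edges count as "subcortico-cortical", so the
  two cortico classes partition the edge set.
- Edge vectorization is upper-triangle row-major (i < j), 0-based
  internally, 1-based ROI ids in all files.
- Bootstrap resamples with a constant response are redrawn and
  counted in the log.
- Cross-validated null predictions are slightly anti-correlated with
  the held-out response (training folds exclude the test points from
  their mean); the bias shrinks with n and is negligible at n = 88.
  Chance-level guarantees are therefore stated at the cohort size.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the simulation-based
checks at the cohort's own scale (n = 88, 90 ROIs) but with shortened
scans (64 volumes) where only calibration — not spectral resolution —
is under test, 2,000-iteration bootstraps instead of 10⁵, and 3–20
seeds per property. These sizes are the package's desk-scale defaults;
publication-grade runs should restore 10⁵ bootstrap iterations and
full-length scans via the exposed parameters.

## Known limitations

- The GLM connectivity estimator is pairwise; no partial-correlation or
  regularized-precision alternative is provided.
- No graph-theoretic metrics beyond nodal strength.
- Volumes are consumed as inputs; deformation-based volume estimation
  from images is out of scope.
- The AUC z-score approximation and the independent-samples Fisher-z
  comparison both ignore within-cohort dependence.
- The MATLAB loader is a thin convenience adapter; it assumes the
  deposited array layout and does no unit conversion.
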