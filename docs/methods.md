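# Methods

## The measurement problem

Regional brain recordings (here: source-localized MEG amplitude envelopes,
90 regions, 2-s epochs at 200 Hz) carry directional information that
ordinary functional connectivity discards: if activity in region A
systematically precedes correlated activity in region B, the A→B and B→A
lagged correlations differ, and the joint statistics of the recording are
not invariant under time reversal. This package quantifies that
irreversibility and two derived hierarchy summaries, and provides the
inference machinery (permutation tests, cross-validated lag selection,
recurrence-network dynamics, classifier comparisons, spatial null models)
needed to compare experimental conditions.

## Irreversibility from lagged correlations

For demeaned per-epoch envelopes x_i(t), the forward lagged correlation at
lag τ (samples) is

    Cf[i, j](τ) = Σ_{t=1..n−τ} x_i(t) x_j(t+τ) / sqrt(Σ x_i² · Σ x_j²),

a truncated-overlap sum with a fixed denominator, so every zero-lag
autocorrelation is exactly 1. Reversing both series and lagging one of
them is algebraically identical to lagging the other series forward, so
the time-reversed matrix satisfies Cr = Cfᵀ exactly under this estimator;
the package computes Cr via the transpose and keeps an explicit-reversal
estimator as a verification path (they agree to 1e−12 in the test suite —
the identity is tested, not assumed). The irreversibility matrix is the
elementwise square

    R(τ) = (Cf(τ) − Cr(τ))^∘2,

symmetric with zero diagonal; a time-reversible stationary process (any
process with exchange-symmetric lagged correlations, e.g. a linear process
with symmetric coupling) has R = 0 in expectation.

Summaries: the scalar r(τ) is the mean of the entries of the upper
triangle that survive thresholding at the matrix's own 95th percentile
(survivor mean — entries strictly above the linear-interpolation
percentile; ties dropped; if nothing survives, the plain mean). Regional
values use each region's full off-diagonal row. Per-epoch values are
averaged across epochs. Design choices the estimator definition leaves
open, resolved here once: the diagonal is excluded from all percentiles
(self-pairs are identically zero and would dilute the threshold);
whole-brain statistics use the upper triangle only (R is symmetric);
thresholding averages survivors rather than zero-filling (the threshold
exists to discard noise, not to shrink the mean); the unthresholded
variant remains available (`threshold_mode="none"`).

A partial-correlation variant regresses each member of an ordered pair on
the contemporaneous values of all other regions (its own time index) over
the overlap window before correlating residuals, removing common-drive
confounds; with two regions it reduces exactly to the plain estimator.

A `circular=True` estimator computes the periodic (wrap-around) lagged
correlation via the FFT. It exists because phase-randomization surrogates
preserve cross-spectra, hence circular cross-correlations, *exactly*; the
truncated-sum estimator is only approximately preserved. Surrogate
invariance checks therefore use the circular form; all headline analyses
use the truncated form.

## Incoming–outgoing asymmetry and hierarchy summaries

For each region, the squared forward-row entries (region leading its
partners: outgoing components) and squared reversed-row entries (partners
leading the region: incoming) are concatenated into one 2(N−1)-vector,
thresholded at its own 95th percentile, surviving outgoing entries
negated, and averaged — the signed asymmetry A_region (0 if nothing
survives; thresholds are per region per epoch). Hierarchical coherence
H_c is the mean of f(A_region) across regions and hierarchical
inhomogeneity H_i the standard deviation, with f = |·| by default: in a
network where one node only sends and its partner only receives, the
signed asymmetries are equal and opposite and a signed mean cancels
exactly the imbalance the summary is meant to expose. The signed variant
(`mode="signed"`) is retained. A fully balanced network (every node's
in-strength equals its out-strength, with symmetric lagged correlations)
has A_region ≡ 0 and hence H_c = H_i = 0 even when individual connections
are strongly directed — the four-node toy networks in
`insideout.synthetic.toy_networks` illustrate exactly this dissociation,
and the test suite asserts the balanced-ring < flipped-edge ordering of
both summaries. Orderings among the remaining two toy variants depend on
unstated weight conventions and are not asserted.

## Choosing the lag τ

Three routes, all over a grid of positive lags (a 2-s epoch at 200 Hz
admits 1..399 samples):

1. **Curve integration** — r(τ) over the whole grid, with the trapezoidal
   area over τ in seconds as "total" irreversibility; cluster-based
   permutation over the τ axis (pointwise paired t at α = .05, cluster
   mass = Σ|t|, max-mass sign-flip null) locates contiguous lag ranges
   where two conditions differ.
2. **Orthogonal contrast** — the τ maximizing the grand-mean r(τ) across
   all datasets; ties break to the smallest lag.
3. **Counter-balanced cross-validation** — participants are blocked into
   folds (whole participants, so each fold automatically contains both
   drug levels and all conditions; the 16 × 2 × 4 study grid in 8 folds
   gives 16 datasets per fold). Training folds yield argmax_τ
   |mean_drug − mean_control|; the held-out fold's difference at that τ is
   recorded; the final τ is the winning τ of the fold with the largest
   held-out difference (an argmax over the mean held-out curve is
   available as `final_rule="pooled"`). Significance comes from a paired
   sign-flip permutation of per-participant means at the selected τ.

Permutation p-values use (1 + exceedances)/(n_perm + 1) throughout and
can never be zero. Repeated-measures ANOVA (drug × condition, optionally
× region) delegates the F computation to a standard within-subject
routine after this package's own balance checking; Tukey HSD post-hocs
and Benjamini–Hochberg FDR adjustment are provided likewise. The
normality battery runs Shapiro–Wilk, D'Agostino K², Anderson–Darling and
Jarque–Bera at α = .05 with a majority verdict; the panel composition is
a package choice and configurable.

## Recurrence-network dynamics

Each hierarchy metric is re-estimated in 1-s windows with 80% overlap,
confined to single epochs (epochs are temporally discontinuous after
artifact rejection, so windows never straddle boundaries). The resulting
1-D metric timeseries is delay-embedded: the delay is the first local
minimum of the histogram mutual information (10 equal-width bins per axis;
the τ=0 self-information serves as the left neighbour of the first lag;
if no interior minimum exists the global argmin is used with a warning),
and the dimension comes from the false-nearest-neighbour rule — a point's
nearest neighbour in dimension m is false if the same pair's distance in
dimension m+1 exceeds twice its distance in dimension m. The default
selection is the argmin of the false-neighbour count. On chaotic data at
finite density that count keeps creeping downward with m, so the argmin
drifts toward the upper bound; the common plateau rule — smallest m whose
false-neighbour *fraction* falls below a tolerance — is available via
`tol`, and on a noiseless Lorenz x-coordinate the fraction drops from
~99% at m = 1 to below 10% by m = 3.

The recurrence network connects embedded points whose Euclidean distance
is at most ε*, the smallest pairwise distance at which the graph becomes a
single connected component (binary search over the sorted unique
distances); the recurrence rate RR is the edge density 2E/(T(T−1)).
Identical points give ε* = 0 and RR = 1.

Surrogates: `common_phase` multiplies one random phase per frequency into
every channel's spectrum (DC untouched; the Nyquist bin gets a common
random sign), preserving every sample cross-spectrum — and therefore the
circular cross-correlation function and any functional of it — to machine
precision while destroying the temporal evolution. `cholesky_csd` draws
new realizations from randomly phased Cholesky factors of the
epoch-averaged cross-spectral density (preserving cross-spectra in
expectation); a rank-deficient CSD is ridge-regularized with an escalating
logged delta. Surrogates are generated at the envelope level — that is
the level at which "preserving the cross-correlation function" is
meaningful — and comparing drug-vs-control recurrence rates on true and
surrogate series separates genuine dynamics from sampling variability of
the windowed estimates (the "static null").

## Classifier comparison

One observation per (participant, drug) session; default features are the
per-condition scalar metric (a regional mode gives condition × region
features). Repeated 80/20 splits assign whole participants to one side,
so no within-participant information leaks across the split (an
observation-level split is available for comparison); splits depend only
on the seed and run index, so runs are paired across feature sets. The
classifier is a bagged forest of 100 trees with library defaults; held-out
performance is AUROC. Undirected FC (mean pairwise zero-lag correlation)
and the mean forward lagged correlation serve as undirected baselines;
paired Wilcoxon signed-rank tests with FDR adjustment compare AUROC
distributions. A nested variant lets an inner 5-fold CV (grouped by
participant) choose τ per outer run from a 1..100-sample grid.

## Spatial null models for map correlations

Regional maps (value per region plus 3-D centroid) are compared by
Pearson correlation; significance comes from surrogates that preserve
spatial autocorrelation: permute the map, smooth each region's value with
an exponential-distance kernel over its k nearest neighbours (kernel
scale = the k-th neighbour distance, so smoothing is self-normalizing),
rescale to the empirical mean and variance, and keep the k (from
{3, 5, 8, 13, 21, 34}) whose surrogate variogram — semivariance in
equal-count distance bins — best matches the empirical one in summed
squared difference. Rescaling precedes the variogram comparison because
smoothing shrinks amplitude and the objective must compare like for like.
The p-value counts surrogates whose |r| with the other map reaches the
observed |r|. The calibration contrast in the test suite shows naive
permutation inflating the false-positive rate on smooth maps (~0.18 at
α = .05) while the variogram-matched ensemble stays within [0.02, 0.09].

## The synthetic cohort generator

Ground-truth cohorts come from a linear vector autoregression
x(t) = a·x(t−1) + W·x(t−L) + η(t) with Gaussian innovations, followed by
the magnitude of the analytic signal (an envelope-like non-negative
series) and epoch segmentation. The directed coupling W is built from a
symmetric non-negative base S by giving a random preferred direction of
each connected pair the fraction (1+κ) of its weight and the opposite
direction (1−κ): κ = 0 is exactly symmetric (time-reversible), κ = 1
fully directed, |W − Wᵀ| = 2κS, and the matrix is rescaled to a fixed
companion spectral radius (default 0.65–0.8) so overall coupling strength
is matched across κ. The coupling delay L (default 1 sample) is the
ground truth that lag-selection procedures should recover.

Cohorts mirror the study grid: per subject a coupling structure and an
asymmetry level κ_s ~ N(0.5, 0.1) (clipped to [0, 1]) are drawn; control
datasets use κ_s and drug datasets κ_s·(1−δ) with δ the drug effect
(δ = 0.8 in power analyses, δ = 0 for null calibration), all else
matched. Defaults keep the study geometry (16 subjects, two drug levels,
four conditions, fs = 200 Hz, 2-s epochs) at a reduced region count
(default 10; tests use 6) — the marginal distribution of real MEG
envelopes is not targeted, only the lagged-correlation structure whose
asymmetry the pipeline measures.

What passing tests show — and what they do not: the generator produces
stationary linear dynamics with exact ground-truth asymmetry, so the
tests demonstrate estimator correctness, calibration and power under
known conditions. They do not demonstrate robustness to nonstationarity,
1/f spectra, volume-conduction leakage or non-Gaussian envelope marginals
of real recordings; the optional front-end (band-pass, symmetric
orthogonalization, Hilbert envelopes) addresses leakage on real data but
is exercised here only on synthetic signals.

## Problem sizes and numerical choices

Simulation-based checks are sized for a routine single-CPU run: type-I
calibration uses 200 null cohorts of 8 subjects × 2 conditions × 6
regions × 8 one-second epochs; power analyses use 20 replicates of
16-subject cohorts (20 epochs); lag-recovery uses 8-subject cohorts with
30 two-second epochs at strong asymmetry (kappa 0.9, base radius 0.85) —
the longer window and stronger coupling are needed for the contrast curve
to peak above the finite-sample floor of the thresholded estimator, which
grows with τ as the truncated overlap shrinks; the classifier contrast uses 12
subjects and 50 paired runs; spatial calibration uses 200 map pairs with
150 surrogates each. The finite-sample bias of r (thresholded squared
differences are positive even for reversible processes) grows with τ
under the truncated estimator as the overlap shrinks — condition
*differences* cancel this bias, which is why contrast-based τ selection
is reliable at scales where raw-curve peaks are not.

Degenerate inputs are handled explicitly: zero-variance regions raise
with the offending label; constant arrays fall back to plain means in
thresholded summaries; constant metric timeseries are rejected by the
mutual-information scan; all-identical embedded points yield a complete
recurrence network (RR = 1); rank-deficient inputs to orthogonalization
raise naming the collinear channels. Ties break deterministically
(smallest lag, smallest dimension). All stochastic stages require
explicit seeds; a missing seed is an error, never a silent default.

## Known limitations

- The linear-VAR generator cannot produce asymmetry that is invisible to
  lagged correlations but visible to higher-order statistics; estimator
  comparisons on such processes are out of scope.
- The FNN argmin rule degenerates on long noisy series (see above); the
  plateau tolerance is the practical selector there.
- The Cholesky-CSD surrogate preserves cross-spectra only in expectation
  and inherits estimation error of the epoch-averaged CSD when epochs are
  few.
- Repeated-measures ANOVA requires a complete balanced grid; cohorts with
  undeclared missing cells are rejected rather than imputed.
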