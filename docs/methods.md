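# Methods

This note documents the models, the numerical choices, and the open design
decisions behind the package, in the spirit of a methods appendix.

## Signal model and pre-processing

The detector operates on a single EEG channel, nominally Cz-A1 sampled at
200 Hz, in microvolts. Pre-processing is a Butterworth band-pass at
0.5–30 Hz. The filter is specified by its *design order* (default 4), the
convention of MATLAB's and scipy's `butter`: a band-pass of design order N
is an overall order-2N transfer function (here order 8, |H| ≈ 0.064 at
50 Hz, ≈ 0.998 at 10 Hz). This is what practitioners produce when they
write "4th-order Butterworth band-pass", and it is the reading consistent
with the attenuation this package's tests assert. The filter is applied
causally (forward only) by default; a `zero_phase` flag switches to
forward–backward filtering, which doubles the effective order and removes
phase distortion at the cost of non-causality.

Windows are half-open `[start, start + W)` intervals in samples, 0-based;
annotations are half-open intervals in seconds. Window length 0.5 s and
step 0.1 s give `floor((N_total − W)/S) + 1` windows. A window is labeled
k-complex when the fraction of it inside any single annotated event is at
least `min_overlap` (default 0.5). The threshold is a genuine free choice —
no standard exists for converting event annotations to window labels — and
is exposed in the configuration; labeling is monotone in it by
construction.

## Features

**Time domain (f1–f12).** Formulas are evaluated verbatim from their
definitions: the standard deviation uses the N−1 denominator; skewness and
kurtosis are plain moment ratios of the standardized window with that
standard deviation as scale (kurtosis is *not* excess kurtosis — no −3);
crest, impulse and margin factors use the peak-to-peak range `max − min` in
the numerator rather than the textbook peak value; the zero-crossing count
treats `sgn(0) = +1`; the time centroid is 1-based, `Σ n·x(n) / Σ x(n)`.
Degenerate windows (zero variance, zero sum) return 0 for the affected
features together with a flag rather than NaN, so feature matrices stay
finite for the selectors.

**Spectral domain (f13–f19).** The per-window spectrum is the one-sided
FFT energy spectrum `E(k) = |X(k)|²` scaled so Parseval's identity holds
exactly (`Σ_k E(k) = Σ_n x(n)²`); the DC bin is included by default and no
taper is applied (a Hann window is available behind a flag). Choices the
formulas leave open: the band-energy-ratio band defaults to 0.5–4 Hz, the
delta band where k-complex energy concentrates; the roll-off fraction C
defaults to 0.85 (top of the conventional 0.6–0.85 range); the bandwidth
about the centroid uses the absolute deviation `Σ |f_SC − f_k| E(k) / Σ
E(k)`; the geometric mean inside the flatness measure floors zero bins at
10⁻¹² of the spectral maximum, keeping the dB value finite.

**Chaotic (f20–f22).** The correlation dimension is the Grassberger–
Procaccia estimate on delay-embedded windows: embedding dimension m = 3 by
default, delay τ chosen per window as the first zero crossing of the
autocorrelation (capped at N/8), Chebyshev metric, C(r) = fraction of
distinct point pairs closer than r. The theoretical r → 0 limit is
meaningless on 100-sample windows, so every dimension is the least-squares
slope over an automatically selected scaling region: the radius grid is 16
log-spaced radii between the 5th and 50th percentile of pairwise
distances, and the fitted window is the run of ≥ 5 consecutive grid points
maximizing the fit r² (ties to the wider window). Box and generalized
dimensions normalize the signal graph to the unit square and count dyadic
boxes (sizes 2⁻¹ … 2⁻⁶) occupied by a densely interpolated polyline of the
graph (8192 points), so the *curve* is counted, not just the samples; the
fit uses runs of ≥ 4 of the 6 scales. The generalized dimension is the
Rényi D_q with q = 2 by default (q = 1 is the information-dimension
singularity and is rejected); its scaling window is the one selected on
the q = 0 curve and is shared across q, which makes D_0 agree with the box
dimension structurally and keeps the Rényi ordering D_0 ≥ D_2 ≥ D_4 stable
— exactly only in the r → 0 limit, to within a few hundredths for
finite-scale fits. Degenerate inputs (identical points, single occupied
box) return slope 0 with a flag; a constant signal's graph is a horizontal
line and correctly reports dimension ≈ 1, flagged.

## Feature selection

Continuous features are discretized by equal-frequency binning (default 10
bins) before any consistency or entropy computation; the bin count is in
the configuration.

- **ReliefF** uses k = 10 nearest hits and misses (Manhattan distance on
  range-normalized features), with `diff` the range-normalized absolute
  difference. Raw ReliefF weights rarely approach the conventional 0.7
  selection threshold, so the threshold is applied to min–max-normalized
  weights; this divergence from the raw-weight reading is deliberate and
  documented here.
- **CFS** computes Pearson correlations on standardized features (the
  point-biserial correlation against the binary label is Pearson and needs
  no special case), merit `k·mean|corr(f,y)| / sqrt(k + k(k−1)·mean|corr(f,f')|)`,
  and searches by best-first expansion with a five-stale-expansion stop.
  Zero-variance features get zero correlations with a warning.
- **Search-based selection** minimizes either the inconsistency rate or a
  seeded 5-fold internal cross-validation error of the configured
  classifier. All 2^F − 1 subsets are enumerated up to 15 features (ties
  resolved toward smaller, then lexicographically earlier subsets); beyond
  that an exhaustive search is not desk-scale and the implementation falls
  back to best-first search with the same measure, logged loudly.
- **INTERACT** ranks features by symmetrical uncertainty
  `SU = 2[H(f)+H(l)−H(f,l)]/[H(f)+H(l)]` and scans from the tail, removing
  a feature when its consistency contribution (increase of the
  inconsistency rate caused by removing it) is ≤ 10⁻⁴; the threshold has
  no conventional value and is exposed in the configuration.

## Detection and evaluation

Classifiers are LDA, a linear SVM (C = 1), and a CART decision tree (gini,
unlimited depth), each behind a standardizer fit on the training fold
only. Cross-validation is stratified 5-fold with a global seed; feature
selection, when active, is re-fit inside every training fold, so the test
fold never influences the selected subset. Whether folds should group by
subject is a real question on multi-subject data; pooled stratified folds
are the default and grouped folds can be built by the caller.

Metrics come from the per-fold confusion matrix: sensitivity, specificity,
accuracy, F_β (β = 1 by default; β > 1 weights recall of true k-complexes),
and Cohen's kappa in the standard `(p_o − p_e)/(1 − p_e)` form.
Division-by-zero branches return 0 with an explanatory flag. Screening
statistics per feature are the Spearman correlation with the label, the
one-way ANOVA p-value (flagged at 0.05 and 0.005), and the Fisher
criterion J1 = tr(S_w⁻¹ S_m) with both scatter matrices normalized by n so
J1 is stable across sample sizes; a singular S_w is ridge-regularized and
flagged.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated: a 15-minute, 200 Hz recording with 60 non-overlapping
k-complexes whose negative peak is 8× the background standard deviation
(15 µV), durations uniform on 0.5–2 s. The background is an AR(2) process
(coefficients 1.7, −0.81: spectral peak in the delta band) band-limited to
0.5–30 Hz — an N2-like colored-noise floor. The transient is two
raised-cosine lobes, negative over the first 40 % of the duration and
positive over the rest, amplitude ratio 1.5:1, which balances the areas to
zero exactly. Event onsets are placed by a seeded Dirichlet split of the
free time, so any feasible event count is placed without rejection
sampling and identical seeds give bit-identical recordings and
annotations.

What passing tests on this fixture do and do not show: they demonstrate
that the features carry the intended contrast, that the selectors find a
compact informative subset, and that the cross-validated detector recovers
planted events at high signal-to-noise. They do not demonstrate
performance on real N2/N3 sleep, where slow waves mimic k-complexes,
artifacts abound, amplitude varies across subjects, and expert labels
disagree — none of which the generator emulates (optional 12–14 Hz
spindle-like distractor bursts are available but off by default).

Fixtures are written as minimal standard-header 16-bit EDF (one-second
data records, physical units µV) plus plain-text annotations; the EDF
writer is part of this package and its round-trip against the MNE reader
is tested to within 16-bit quantization.

## Pipeline defaults and problem sizes

The end-to-end study arm balances classes by seeded undersampling of
negatives to 3:1 negatives-per-positive before selection and
cross-validation (the full pipeline on the 15-minute recording then
operates on ~3000 of ~9000 windows). Balancing is optional and off-switchable
(`balance_ratio=None`); 3:1 keeps the negative class dominant while
preventing the tree's splits from being driven by the 11:1 raw imbalance.
All randomness flows through per-stage generators derived from the single
run seed; reports are sorted-key JSON without timestamps, so identical
configuration and seed reproduce byte-identical artifacts. Test and
validation problem sizes (60–900 s recordings, 100–400-point geometry
fixtures) were chosen as the smallest sizes at which each property is
stable and are stated alongside each computed number.

## Known limitations

- The scaling-region search makes the fractal features robust on short
  windows but means they are *relative* dimension estimates; absolute
  values depend on the grid and fit-window conventions above.
- Best-first fallbacks (CFS, search-based selection beyond 15 features)
  are heuristics and can return local optima; the exhaustive path is exact
  and is what the oracle-equivalence tests certify.
- The wrapper (classifier-error) measure is quadratically more expensive
  than the consistency measure and is practical only on small feature
  counts or with the best-first fallback.
- Resampling of non-200 Hz recordings, artifact rejection beyond the
  band-pass, and multi-channel fusion are out of scope.
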