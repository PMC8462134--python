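# Methods

## Data model

A dataset is a matrix of even-length accelerometer segments: one row per
segment, samples interleaved per axis (`x, y, z, x, y, z, ...`), one
behavior label per row, plus the axis count (1–3) and sampling frequency
(Hz). Even-length segmentation is the only supported scheme; detecting
behavior change points for variable-length segments is a different problem
and out of scope, as is raw-signal denoising (any preprocessing must be
applied consistently at training and prediction time by the user).

Stream conversion blocks a raw stream into consecutive non-overlapping
segments and **drops** a trailing partial block — padding would fabricate
samples. Timestamps of long-format streams are validated for monotonicity
but not for gaps; gap-aware segmentation is a non-goal. All values must be
finite at read time, because every downstream stage assumes it.

## Features

Time domain, per axis: mean, variance, sd, max, min, range. Variance uses
the n−1 (sample) denominator, the common statistical default. ODBA is
computed across axes: per axis the *static* (gravity) component is
estimated by a centered moving average of `winlen_dba` samples, the
*dynamic* component is the residual, and ODBA is the per-sample sum over
axes of |dynamic| averaged over the segment.

The ODBA smoothing window keeps its full length at the segment edges by
sliding inward (clamping) instead of shrinking. Consequences we consider
desirable: the estimate always averages exactly `winlen_dba` samples, and
with `winlen_dba = seg_len` the static component is the segment mean —
the "segment-mean static" convention is the limiting case rather than a
separate mode. `winlen_dba` has no universal default; a window spanning
roughly one second of data (e.g. 11 samples at ~10.5 Hz) is recommended, so
that postural (sub-Hz) variation goes to the static part and locomotory
oscillation to the dynamic part.

Frequency domain, per axis: the one-sided amplitude spectrum of the
mean-removed signal (`2|Xₖ|/N`, Nyquist bin `|Xₖ|/N`, DC excluded), from
which we take the **main frequency** (bin of maximum amplitude; ties break
to the lowest frequency — deterministic), the **main amplitude** (so an
on-bin sinusoid of amplitude A reports A), and the **spectral entropy**
`−Σ pₖ ln pₖ` over normalized spectral *power* `pₖ = aₖ²/Σaⱼ²`, in nats.
A numerically dead spectrum (total power < 1e−12) reports entropy 0,
amplitude 0 and the first bin as main frequency. Entropy is low for
periodic signals (wingbeats) and high for noise-like ones; for pure
Gaussian noise the *expected* per-segment entropy is `ln(N/2) − (1 − γ)`
(γ = Euler–Mascheroni), a constant ~0.423 below the flat-spectrum bound
`ln(N/2)`, because the spectral weights of a single noise realization are
exponentially distributed rather than flat. Frequency features are only
meaningful when the sampling rate comfortably exceeds twice the behavior's
dominant frequency; at ~10.5 Hz a 3.1 Hz wingbeat is resolvable, at 1 Hz it
is not.

Feature tables are plain pandas DataFrames (unique named columns,
row-aligned to segments); `combine_features` lets users append custom
feature columns, which all later stages treat identically.

## Feature selection

The correlation filter iterates: while any remaining pair has |Pearson r|
above the cutoff (default 0.9), examine the largest-|r| pair and remove the
member with the larger mean absolute correlation to all other remaining
features; on ties the earlier column is retained. Zero-variance features
have undefined correlations; they are treated as uncorrelated (never
removed by the filter). The filter is off by default.

SFS scores every candidate each round by the mean accuracy of the default
classifier under seeded stratified 5-fold cross-validation; the evaluation
protocol for candidate scoring is not uniquely determined by the procedure
itself, and CV was chosen for consistency with the rest of the package (a
resubstitution score would favor overfitting features). Fold assignment is
computed once per dataset and shared by all candidates and rounds, so
per-round accuracies are comparable. Ties take the leftmost column. The
accuracy matrix keeps one row per round; entries of already-selected
features are zero in later rows.

## Classifier

XGBoost with the softmax multiclass objective (two-class tasks use the
equivalent logistic objective). "Default" hyperparameters freeze
`nrounds = 10`, `colsample_bytree = min_child_weight = subsample = 1`, and
the library defaults `max_depth = 6, eta = 0.3, gamma = 0`; all seven are
recorded in the model artifact. The tuning grid is
`nrounds ∈ {5,10,50,100} × max_depth ∈ {2..6} × eta ∈ {0.01,0.1,0.2,0.3} ×
gamma ∈ {0,0.1,0.5}` (240 points), scored by 5-fold stratified CV repeated
3 times; ties return the first point in row-major order.

All splits and folds are **stratified by label**: behavior datasets are
strongly unbalanced (the default ethogram's rarest class has 77 of 1,746
segments) and unstratified partitions could starve or drop a class.
Trees are grown with the exact greedy method: split thresholds land midway
between adjacent feature values, so a validation point marginally outside
its class's training range still falls on the correct side — the
histogram method places thresholds on data quantiles and does not guarantee
this. Exact growth is also fully deterministic; together with
single-threaded fits and explicit seeds for every split, fold, and fit,
identical seeds give bit-identical results.

Evaluation: confusion matrix with predicted behaviors in rows and observed
in columns (over the union of label sets, sorted), accuracy = trace/total,
Cohen's kappa from the row/column marginals, one-vs-rest sensitivity,
specificity, precision (0 when undefined) and balanced accuracy per class,
and gain-share importances (each feature's fraction of total split-gain,
summing to 1). Persistence stores the boosted ensemble in XGBoost's
portable JSON format plus a sidecar with feature names, the label
dictionary, hyperparameters, seed and library version; prediction requires
exactly the stored feature names (order is normalized, mismatches raise a
schema error listing the difference).

## Reporting

Figures are static (matplotlib) and each writes its underlying data table
as CSV, so numerical content is testable without pixel comparison and can
be re-rendered elsewhere; interactive pan/zoom browsing is a UI concern
deliberately left out. The misclassification report sorts segments by
observed behavior (lexicographic, stable — the same order as
`order_by_label`), draws block boundaries, and marks every wrongly
predicted segment (one bout per segment; the bout count equals the
off-diagonal confusion total). The UMAP embedding standardizes columns,
drops constant ones with a warning, and exposes `n_neighbors` (15),
`min_dist` (0.1) and the metric (Euclidean) as configuration; a fixed seed
makes it deterministic at the cost of parallelism.

## Synthetic data

Each behavior class is generated per segment as: a gravity unit vector
(posture) jittered by a small random rotation (sd 5°, per segment — so
noiseless static classes are constant *within* a segment but vary across
segments), plus an optional sinusoid with class frequency/amplitude and a
uniform random phase, applied to the heave (z) axis with N(0, 0.1·amp)
leakage into x/y, plus Gaussian noise. Rows are shuffled deterministically
by seed.

The default ethogram has five classes at field-like imbalance (77 / 96 /
437 / 863 / 273 segments), 40-sample segments at 10.54 Hz: active flight
(wingbeat 3.1 Hz, amplitude 1 g, noise 0.10 g), walking (2.0 Hz, 0.35 g,
0.08 g), passive flight (faint 0.8 Hz sway, 0.04 g, 0.05 g), standing and
sitting (static; noise 0.04/0.03 g) whose postures differ by ~15° — chosen
as the deliberately hardest pair so that residual confusion concentrates
where a field dataset's would (between visually similar resting postures).

What the generator does *not* emulate: behavior transitions inside a
segment, non-stationary or harmonic-rich gaits, sensor saturation/drift,
heavy-tailed noise (available as an option, not default), and
animal-to-animal variation. Passing tests on synthetic data therefore
demonstrate that the pipeline recovers planted structure correctly — not
that any particular field dataset will classify at the same accuracy.

## Numerical conventions and edge cases

- Degenerate spectra (total power < 1e−12): entropy 0, main amplitude 0,
  first bin as main frequency.
- Ties: main frequency → lowest bin; SFS and tuning argmax → earliest
  candidate/grid point; filter removal → later column removed; class
  probability ties → lowest class index.
- Empty dataset (0 segments) is representable and round-trips through I/O;
  single-class training raises a degenerate-task error; classes smaller
  than the fold count raise a stratification error naming the class.
- Values are written with 12 significant digits; read/write round-trips
  preserve labels exactly and values to that precision.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default ethogram's native size (1,746 segments × 28 features; five-fold CV,
six SFS rounds) and use reduced grids/subsets only where an operation's
check does not depend on scale (e.g. tuning plumbing is exercised on a
four-point grid, while the full 240-point grid is verified by enumeration).
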