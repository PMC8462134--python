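# accelbehave

Supervised animal behavior classification from accelerometry, for movement
ecologists and biologgers. Tracking tags increasingly record triaxial
acceleration alongside position; turning those raw signals into behavior
budgets (flying, walking, resting, ...) requires a classifier trained on
segments whose true behavior was observed. `accelbehave` covers that whole
workflow for *even-length* labeled segments:

1. **Segment I/O** — read/write wide segment tables (`x, y, z, x, y, z, …,
   behavior`, one row per segment) and convert the two common raw-tracker
   layouts (flat interleaved streams and long `timestamp, x, y, z` tables)
   into that format.
2. **Features** — per-axis time-domain statistics (mean, variance, sd, max,
   min, range) plus ODBA (Overall Dynamic Body Acceleration, an
   energy-expenditure proxy: the per-sample sum over axes of |dynamic
   acceleration| averaged over the segment, where the static gravity
   component is a `winlen_dba`-sample moving average), and per-axis
   FFT-based frequency features: main frequency, main amplitude, and
   spectral entropy `H = −Σ pₖ ln pₖ`, `pₖ = aₖ²/Σaⱼ²`.
3. **Feature selection** — a pairwise-|r| correlation filter (default
   cutoff 0.9, off by default) and stepwise forward selection (SFS): each
   round adds the candidate that maximizes seeded stratified 5-fold CV
   accuracy of an XGBoost classifier.
4. **Model** — multiclass XGBoost (softmax). Defaults fix `nrounds = 10`,
   `colsample_bytree = min_child_weight = subsample = 1`; the `tune` path
   grid-searches `nrounds × max_depth × eta × gamma` (240 combinations) by
   5-fold stratified CV repeated 3 times. Validation reports a confusion
   matrix (predicted in rows, observed in columns), accuracy, Cohen's kappa
   `κ = (p_o − p_e)/(1 − p_e)`, one-vs-rest per-class statistics and
   gain-share feature importances.
5. **Reporting** — selection-accuracy curve, per-behavior boxplots, a
   misclassification report that maps cross-validation errors back onto the
   raw traces, and a seeded 2-D UMAP embedding. Every figure also writes its
   underlying data table as CSV.
6. **Simulation** — a generator of labeled synthetic datasets (static
   gravity orientation + class-specific sinusoid + Gaussian noise) with a
   five-class soaring-bird default ethogram, so the entire pipeline is
   testable against planted ground truth without any field data.

## Worked example

```python
import accelbehave as ab

ds = ab.generate_dataset(ab.default_specs(), seg_len=40, samp_freq=10.54, seed=1)
features = ab.combine_features(
    ab.time_domain_features(ds, winlen_dba=11),  # 19 columns
    ab.freq_domain_features(ds),                 # 9 columns
)
cv = ab.crossval_predictions(features, ds.labels, k=5, seed=1)
report = ab.evaluate(cv["observed"], cv["predicted"])
print(round(report.accuracy, 3), round(report.kappa, 3))
```

prints `0.993 0.99`: five-fold cross-validated accuracy and chance-corrected
agreement of the default classifier on the 1,746-segment synthetic ethogram.
The confusion matrix shows 12 errors, 10 of them between the two near-static
postures (standing vs sitting) whose gravity orientations differ least —
exactly the hard pair the generator plants. The active-flight segments'
mean heave-axis main frequency comes out at 3.16 Hz, one bin away from the
planted 3.1 Hz wingbeat.

The scripts in `examples/` walk through each capability (simulation +
features, selection, training + persistence, cross-validation + error
mapping) and print annotated output; a thin CLI (`accelbehave convert |
features | select | train | crossval | simulate | report`) wraps the same
functions for shell use.

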