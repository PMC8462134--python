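"""Simulate a labeled accelerometer dataset and compute its features.

Generates the default five-class ethogram (active flight with a 3.1 Hz
wingbeat, passive flight, walking, standing, sitting), computes the
time-domain (19) and frequency-domain (9) features, and prints per-behavior
summaries of ODBA and the heave-axis main frequency.
"""

import accelbehave as ab

ds = ab.generate_dataset(ab.default_specs(), seg_len=40, samp_freq=10.54, seed=1)
print(f"{ds.n_segments} segments of {ds.seg_len} triaxial samples at "
      f"{ds.samp_freq} Hz; classes: {ds.class_counts()}")

time_ft = ab.time_domain_features(ds, winlen_dba=11)  # ~1 s static window
freq_ft = ab.freq_domain_features(ds)
features = ab.combine_features(time_ft, freq_ft)
print(f"feature table: {features.shape[0]} x {features.shape[1]}")

summary = features[["ODBA", "z_main_freq"]].groupby(ds.labels.astype(str)).mean()
print("\nper-behavior means:\n", summary.round(3))
print(
    "\nODBA (mean absolute dynamic acceleration, g) ranks behaviors by "
    "movement intensity;\nz_main_freq (Hz) recovers the planted 3.1 Hz "
    "wingbeat for active flight and is\nnoise-dominated for the near-static "
    "behaviors."
)
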