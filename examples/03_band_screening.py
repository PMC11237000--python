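"""Screen wavenumbers by pointwise t-tests and build band-ratio features.

A two-sample Student's t-test at every wavenumber flags the regions where
male and female mean spectra differ (p < 0.05); the minimal-p bands on each
side of the difference spectrum are paired into scale-invariant intensity
ratios.
"""

import chickspec as cs

pre = cs.preprocess_set(cs.simulate_cohort(cs.CohortConfig(seed=0)))

profile = cs.pointwise_ttest(pre, "sex")
print(f"fraction of significant wavenumbers (p < 0.05): {profile.mask.mean():.3f}")

bands = cs.select_bands(profile, k=4)
print(f"four minimal-p bands: {[f'{b:.0f}' for b in bands]} cm-1")

pairs = cs.select_paired_bands(profile, n_pairs=2)
print(f"male-stronger/female-stronger pairs: {pairs}")

features = cs.ratio_features(pre, pairs)
cols = [c for c in features.columns if c.startswith("R_")]
print(features[["sample_id", "sex"] + cols].head(4).to_string(index=False))
print("-> the selected bands sit on oxy/deoxy marker regions (~1640, ~1527, "
      "~1396, ~787 cm-1); each ratio divides a male-stronger band by a "
      "female-stronger one, amplifying the sex contrast.")
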