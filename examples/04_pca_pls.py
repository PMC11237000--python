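"""Decompose the cohort by PCA and by PLS against an artificial profile.

PCA finds the variance-ordered components; the discriminant component is
the one whose scores best separate the sexes.  PLS regresses the spectra on
a dummy response (male = 2, female = 1) so its leading factor is the
class-correlated spectral component; quality is reported as R² in
calibration and leave-one-out validation.
"""

import numpy as np

import chickspec as cs

pre = cs.preprocess_set(cs.simulate_cohort(cs.CohortConfig(seed=0)))
X = pre.intensity_matrix()
labels = pre.labels("sex")
contrast = cs.oxy_minus_deoxy_contrast().intensities

res = cs.pca(X, n_components=8)
pc = cs.select_discriminant_pc(res, labels)
r_pc = np.corrcoef(res.loadings[pc], contrast)[0, 1]
print(f"discriminant PC: index {pc} "
      f"(explains {res.explained_variance_ratio[pc]:.1%} of variance)")
print(f"|corr| of its loading with the oxy-minus-deoxy contrast: {abs(r_pc):.3f}")

y = cs.artificial_profile(labels)          # (male, female) -> (2, 1)
fit = cs.pls_fit(X, y, n_factors=6)
r_pls = np.corrcoef(fit.x_loadings[0], contrast)[0, 1]
r2_cal, r2_val, _ = cs.loocv_pls(X, y, n_factors=6)
print(f"PLS factor-1 loading |corr| with contrast: {abs(r_pls):.3f}")
print(f"PLS R2 calibration = {r2_cal:.2f}, R2 validation (LOOCV) = {r2_val:.2f}")
print("-> both decompositions recover the planted oxygenation signature: "
      "the class-separating loading is the oxy/deoxy difference spectrum.")
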