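# Methods

## The model

The package treats a whole-blood (or washed-RBC) Raman spectrum under
785-nm excitation as a linear mixture of pure-component spectra on a
smoothly varying fluorescence background:

    S(ν̃) = scale · [ f · S_oxy(ν̃) + (1 − f) · S_deoxy(ν̃) ]
            + plasma_fraction · S_plasma(ν̃) + b(ν̃) + ε(ν̃)

* `f ∈ [0, 1]` — the oxygenated-RBC signal fraction. This is the carrier of
  the sex effect: per sample, `f ~ N(μ_sex, σ_f)` clipped to [0, 1], with
  `μ_male > μ_female`. The biology behind the direction is the higher
  oxygen affinity of male hemoglobin; the model encodes it purely as a
  mixing-fraction shift.
* `S_oxy, S_deoxy, S_plasma` — sums of Lorentzian (optionally Gaussian)
  bands from preset catalogs. Catalog band positions are porphyrin,
  protein and carotenoid modes in 600–1800 cm⁻¹; relative amplitudes are
  free parameters constrained only by the documented ordinal contrasts
  (deoxy: 1544 > 1619 with an enhanced 1527 shoulder and 787; oxy:
  1621 ≈ 1544 with 1636/1579/1561 enhanced and 1396 exclusive; plasma:
  dominant carotenoid 1524/1157). The oxy and deoxy catalogs are
  normalized to equal integrated area, because oxygenation redistributes
  heme scattering between bands rather than changing the amount of
  hemoglobin — without this, area normalization would convert the area
  mismatch into a spurious spectral component and bias every
  loading-recovery analysis.
* `b(ν̃)` — a random polynomial of order ≤ 5 in the axis scaled to [−1, 1],
  coefficients uniform in ±`baseline_coeffs_range`, shifted to be
  non-negative. Order 5 matches what the preprocessing removes.
* `ε` — i.i.d. Gaussian intensity noise. Post-preprocessing residuals of
  averaged Raman acquisitions are approximately Gaussian; no shot-noise
  (Poisson) structure is modelled by default.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| grid | 600–1800 cm⁻¹, 1 cm⁻¹ step (ascending) | the fingerprint region the measurements cover; 1 cm⁻¹ is typical dispersion |
| band FWHM | 12 cm⁻¹ | conventional width for 785-nm blood Raman bands |
| μ_male, μ_female | 0.75, 0.65 | no numeric saturation values are published; Δf = 0.10 is the package's study condition for a "detectable but not trivial" effect |
| σ_f | 0.03 | per-sample biological spread; gives a Bayes error of ≈ 5 % at Δf = 0.10 (Φ(−Δf/2σ_f)), matching the 1-in-30 / 1-in-23 error rates the method is expected to produce on real cohorts |
| noise_sd | 0.005 (unit-peak spectra) | peak SNR ≈ 250, appropriate for 30 s × 10-accumulation resonance-enhanced acquisition; classification error is then dominated by the biological overlap in f, not by detector noise |
| plasma_fraction | 0.10 whole blood, 0 for the `rbc` preset | plasma contributes carotenoid/protein bands to whole blood; washed RBCs have none |
| baseline_coeffs_range | 0.3 | baseline excursions comparable to band heights, typical for blood fluorescence at 785 nm after background subtraction |
| cohort size | 15 + 15 | the scale of a realistic pilot cohort and of the published whole-blood set (14 + 16 spectra) |

## Preprocessing

Chain order: axis calibration → optional background subtraction → baseline
correction → crop → area normalization.

* **Calibration** rigidly shifts the axis so an observed silicon reference
  line lands on 520 cm⁻¹.
* **Baseline** uses iterative modified polynomial fitting ("modpoly"): fit
  an order-5 polynomial by least squares, clip the working spectrum to the
  pointwise minimum of itself and the fit, refit, and stop when the
  relative RMS change of the fit drops below `convergence_tol` (default
  1e-3) or after `max_iterations` (250; non-convergence returns the last
  iterate with a logged warning, never an exception). The least-squares
  projection is precomputed once per axis, so iterations are two matrix
  products. The stopping defaults were chosen by measuring recovery error
  against the generator's stored ground-truth baselines: on noisy spectra,
  iterating far beyond 1e-3 digs the fit below the noise floor and
  *increases* the error (≈ 6 % relative RMS at 1e-3 vs ≈ 9 % at 1e-5).
  On noiseless spectra with isolated bands the recovered baseline is
  within 2 % of the generating polynomial away from the bands.
* **Normalization** divides by the trapezoidal area over the closed
  600–1800 cm⁻¹ interval (positive area required; the area is computed on
  baseline-corrected intensities). The chain is therefore invariant to
  per-sample intensity rescaling to 1e-10, which also makes the
  crop-before-vs-after-normalization ordering immaterial downstream.

Intervals are closed everywhere; resampling (when a background is on a
different axis) is linear with extrapolation forbidden.

## Statistics and decomposition

* **Pointwise t-test** — pooled-variance Student's t by default (Welch
  optional) at every wavenumber, two-sided p, mask = p < α (α = 0.05),
  deliberately without multiple-testing correction: the mask is a
  *screening* display, and downstream inference never treats masked points
  as individually confirmed. A Benjamini–Hochberg-corrected workflow can
  be built from the returned p-values. Zero-variance conventions:
  identical constants → t = 0, p = 1; distinct constants → t = ±∞, p = 0.
* **Band intensities** — default `local_max` within ±4 cm⁻¹ (robust to
  ≤ grid-step calibration jitter); `nearest_point` and `window_mean`
  available. Overlapping shoulder pairs (e.g. 1222/1213 cm⁻¹) are handled
  by windowed extraction only, never by peak deconvolution.
* **Band selection** — `select_bands` returns the k smallest-p points with
  a greedy ≥ 10 cm⁻¹ spacing rule (one broad band cannot be picked twice),
  ties toward the lower wavenumber. For ratio building,
  `select_paired_bands` balances the selection by effect direction
  (smallest-p among t > 0 and among t < 0 separately) because a plain
  top-k can land entirely on one side of the difference spectrum, leaving
  nothing to take a ratio against.
* **PCA** — full-SVD scores/loadings with mean centering (no variance
  scaling, standard for spectra) and a deterministic sign convention: each
  loading's largest-|element| is positive. The discriminant component is
  chosen automatically as the one with the smallest between-class t-test
  p-value on the scores — the reproducible form of picking "the PC that
  separates the groups" by eye; a fixed index override exists.
* **PLS** — single-response NIPALS with deflation, mean-centered only. The
  response is an artificial concentration profile, (male, female) = (2, 1)
  by default, so factor 1 is the class-correlated spectral component.
  R²_calibration comes from the full fit, R²_validation from
  leave-one-out refits (each fold re-centers). A response exactly
  orthogonal to the data returns a zero-coefficient model with R² = 0
  rather than dividing by zero.

## Classifiers

* **PCA–LDA LOOCV** — per fold: PCA refit on the 29 training spectra,
  discriminant PC selected on training labels, a two-class Fisher
  discriminant (w ∝ S_w⁻¹(μ₁ − μ₂), equal priors, threshold at the
  midpoint of projected class means) fit on the training scores, and the
  held-out spectrum projected into the *training* PCA space. Refitting
  everything per fold avoids information leakage; a `refit_pca=False`
  compatibility mode reproduces the simpler global-PCA protocol. Singular
  within-class scatter falls back to a ridge-regularized solve; a
  singleton class contributes no scatter but is allowed (needed for
  minimal n = 4 cross-validation).
* **Ratio plane** — the same Fisher discriminant in the 2-D space of two
  band ratios, formalizing a hand-drawn separating line; the model stores
  the boundary (w, offset) for plotting and reporting.
* **Accuracy** — 100 × trace/total of the confusion matrix, reported to
  one decimal.

## What the tests do and do not show

The synthetic generator emulates the *statistical structure* the analysis
assumes — a single latent mixing fraction separating the classes, smooth
baselines, additive noise, shared band positions. It does not emulate
resonance-enhancement physics, instrument response, cosmic rays, focus
drift, white-cell/platelet contributions, or between-chick variation in
band positions. Passing tests therefore demonstrate that the pipeline
recovers a planted oxygenation effect of realistic size under realistic
noise and correctly calibrates its nulls — not that real chick blood
carries that effect.

Null-calibration details: with a fixed discriminant component, the
label-permutation LOOCV accuracy of both classifiers centres on 50 %
within Monte-Carlo error. With *adaptive* per-fold component selection the
permutation null centres slightly below chance (~46–47 % at n = 30): the
selection step overfits uninformative training labels, producing
anti-correlated held-out predictions. This effect is conservative (it can
only deflate, never inflate, an apparent accuracy), and the tests assert
exactly that: chance-level nulls for the fixed protocol, no optimism for
the adaptive one.

Problem sizes in the test and acceptance runs: cohorts of 15 + 15 spectra
at 1201 grid points; 50 simulation seeds for the recovery study; 200 label
permutations for the classifier nulls; 10 null cohorts for the mask-rate
calibration. These sizes keep Monte-Carlo standard errors a few times
smaller than the tolerances being asserted.

## Known limitations

* The oxy/deoxy catalogs are ordinal reconstructions, not fitted spectra;
  absolute band-amplitude ratios carry no quantitative meaning.
* The modpoly baseline is biased low near strong, dense band clusters;
  the 2 % recovery guarantee holds for isolated bands on a
  fluorescence-scale baseline.
* Classification assumes two classes with near-balanced sizes (equal
  priors, midpoint threshold); heavily unbalanced cohorts would need a
  prior-weighted threshold.
* Per-chick aggregation (majority vote over repeat spectra of one animal)
  is supported only by grouping sample metadata externally; the
  classifiers operate per spectrum.
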