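"""Spectral preprocessing chain for blood Raman spectra.

Implements the standard measurement-conditioning sequence: wavenumber-axis
calibration against a silicon reference (520 cm⁻¹), optional background
subtraction, fluorescence baseline removal by iterative fifth-order modified
polynomial fitting, cropping to the fingerprint region, and normalization by
the integrated area over 600–1800 cm⁻¹.

The baseline algorithm is the classic iterative peak-suppression scheme:
fit a polynomial to the full spectrum, clip the spectrum to the pointwise
minimum of itself and the fit, refit, and repeat until the fit stops
changing.  Peaks are progressively excluded from the fit while the smooth
fluorescence continuum is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "calibrate_axis",
    "subtract_background",
    "correct_baseline",
    "crop",
    "normalize_area",
    "preprocess_set",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    poly_order
        Order of the baseline polynomial (default 5).
    max_iterations, convergence_tol
        Stopping rule for the iterative modified polynomial fit: stop when
        the relative RMS change of the fitted baseline between iterations
        falls below ``convergence_tol``.
    normalization_region
        Closed wavenumber interval over which the trapezoidal area is
        computed and set to 1 (default 600–1800 cm⁻¹); also the default
        crop region.
    calibration_reference_cm1
        True position of the calibration line (silicon, 520 cm⁻¹).
    """

    poly_order: int = 5
    max_iterations: int = 250
    convergence_tol: float = 1e-3
    normalization_region: tuple[float, float] = (600.0, 1800.0)
    calibration_reference_cm1: float = 520.0

    def __post_init__(self) -> None:
        if self.poly_order < 0:
            raise ValueError("poly_order must be ≥ 0")
        lo, hi = self.normalization_region
        if not lo < hi:
            raise ValueError("normalization region must have low < high")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


def calibrate_axis(
    spectrum: Spectrum,
    observed_reference_cm1: float,
    config: PreprocessConfig = PreprocessConfig(),
) -> Spectrum:
    """Rigidly shift the axis so the observed reference lands on its true position."""
    if not np.isfinite(observed_reference_cm1):
        raise ValueError("observed reference position must be finite")
    shift = config.calibration_reference_cm1 - observed_reference_cm1
    return spectrum.with_axis(spectrum.wavenumbers + shift)


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise subtraction of a measured background (resampled if needed)."""
    if background.wavenumbers.shape != spectrum.wavenumbers.shape or not np.allclose(
        background.wavenumbers, spectrum.wavenumbers
    ):
        background = background.resample(spectrum.wavenumbers)
    return spectrum.with_intensities(spectrum.intensities - background.intensities)


def correct_baseline(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> tuple[Spectrum, Spectrum]:
    """Remove the fluorescence continuum by iterative modified polynomial fitting.

    Returns ``(corrected, baseline)`` with ``corrected + baseline`` equal to
    the input exactly.  Non-convergence within ``max_iterations`` returns the
    last iterate with a logged warning rather than raising.
    """
    x, y = spectrum.wavenumbers, spectrum.intensities
    if x.size < config.poly_order + 2:
        raise ValueError(
            f"need at least poly_order + 2 = {config.poly_order + 2} points, got {x.size}"
        )
    # Least-squares projection onto polynomials of the scaled axis; the
    # design pseudo-inverse is computed once and reused every iteration.
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(t, config.poly_order)
    pinv = np.linalg.pinv(V)
    work = y.copy()
    scale = np.ptp(y)
    fit_prev = None
    converged = False
    for _ in range(config.max_iterations):
        fit = V @ (pinv @ work)
        if fit_prev is not None:
            denom = max(float(np.sqrt(np.mean(fit_prev**2))), scale * 1e-30, 1e-300)
            change = float(np.sqrt(np.mean((fit - fit_prev) ** 2))) / denom
            if change < config.convergence_tol:
                converged = True
                fit_prev = fit
                break
        fit_prev = fit
        work = np.minimum(work, fit)
    if not converged:
        logger.warning(
            "baseline fit did not converge in %d iterations (sample %s); using last iterate",
            config.max_iterations,
            spectrum.meta.get("sample_id", "?"),
        )
    baseline = fit_prev
    corrected = spectrum.with_intensities(y - baseline)
    return corrected, spectrum.with_intensities(baseline)


def crop(spectrum: Spectrum, region: tuple[float, float]) -> Spectrum:
    """Keep the closed wavenumber interval ``[low, high]``."""
    lo, hi = region
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"crop region [{lo}, {hi}] contains no grid points")
    return Spectrum(
        spectrum.wavenumbers[mask], spectrum.intensities[mask], dict(spectrum.meta)
    )


def region_area(spectrum: Spectrum, region: tuple[float, float]) -> float:
    """Trapezoidal area of the intensity over the closed region."""
    lo, hi = region
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 2:
        raise ValueError(f"region [{lo}, {hi}] covers fewer than 2 grid points")
    return float(np.trapezoid(spectrum.intensities[mask], spectrum.wavenumbers[mask]))


def normalize_area(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Scale intensities so the trapezoidal area over the normalization region is 1."""
    area = region_area(spectrum, config.normalization_region)
    if area <= 0:
        raise ValueError(
            f"nonpositive area {area:g} for sample "
            f"{spectrum.meta.get('sample_id', '?')}; cannot normalize"
        )
    return spectrum.with_intensities(spectrum.intensities / area)


def preprocess_set(
    spectra: SpectrumSet,
    config: PreprocessConfig = PreprocessConfig(),
    backgrounds: list[Spectrum] | Spectrum | None = None,
    observed_reference_cm1: float | None = None,
) -> SpectrumSet:
    """Apply the full chain to every member of a set.

    Order: calibrate (if an observed reference is given) → subtract
    background (if given) → baseline-correct → crop to the normalization
    region → area-normalize.  Per-sample failures are re-raised with the
    sample id in the message.
    """
    if isinstance(backgrounds, Spectrum):
        backgrounds = [backgrounds] * len(spectra)
    if backgrounds is not None and len(backgrounds) != len(spectra):
        raise ValueError("backgrounds must match the number of spectra")
    out = []
    for i, s in enumerate(spectra):
        sid = s.meta.get("sample_id", f"#{i}")
        try:
            if observed_reference_cm1 is not None:
                s = calibrate_axis(s, observed_reference_cm1, config)
            if backgrounds is not None:
                s = subtract_background(s, backgrounds[i])
            s, baseline = correct_baseline(s, config)
            s = crop(s, config.normalization_region)
            s = normalize_area(s, config)
        except Exception as exc:
            raise type(exc)(f"sample {sid}: {exc}") from exc
        out.append(s)
    return SpectrumSet(out)
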