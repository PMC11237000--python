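"""Synthetic blood-Raman cohort generator.

Emulates 785-nm blood spectra of 1–2-day-old chicks as noisy mixtures of
pure-component band catalogs: each sample is

    S = scale · [f · S_oxy + (1 − f) · S_deoxy] + plasma_fraction · S_plasma
        + baseline(ν̃) + ε

where ``f`` is the per-sample oxygenated-RBC signal fraction, drawn from a
sex-specific normal (males centred higher — the only systematic sex
difference in the model), the baseline is a random polynomial of order ≤ 5
with bounded coefficients, and ε is i.i.d. Gaussian noise.  The drawn f and
the generating baseline are stored in the metadata as ground truth for
parameter-recovery tests.

Band catalogs encode the documented oxy/deoxy porphyrin contrasts: in
deoxy-RBCs the ν11 band near 1544 cm⁻¹ dominates the vinyl ν(C=C) band near
1620 cm⁻¹, whereas in oxy-RBCs the two are comparable; 1636/1579/1561 and
1396 cm⁻¹ are oxy-enhanced (1396 oxy-exclusive), 1527 and 787 cm⁻¹
deoxy-enhanced.  Plasma is dominated by the carotenoid C=C/C–C stretches at
1524 and 1157 cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "Band",
    "BandCatalog",
    "CohortConfig",
    "make_band_catalog",
    "render_component",
    "simulate_sample",
    "simulate_cohort",
    "oxy_minus_deoxy_contrast",
]

DEFAULT_FWHM = 12.0  # cm⁻¹, typical band width for 785-nm blood Raman


@dataclass(frozen=True)
class Band:
    center_cm1: float
    fwhm_cm1: float
    amplitude: float
    assignment: str = ""


@dataclass(frozen=True)
class BandCatalog:
    """An immutable list of bands defining a pure-component emission profile."""

    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        for b in self.bands:
            if not (600.0 <= b.center_cm1 <= 1800.0):
                raise ValueError(f"band center {b.center_cm1} outside [600, 1800]")
            if b.fwhm_cm1 <= 0:
                raise ValueError(f"band width must be positive, got {b.fwhm_cm1}")
            if b.amplitude < 0:
                raise ValueError(f"band amplitude must be ≥ 0, got {b.amplitude}")

    def amplitude_at(self, center_cm1: float, tol: float = 1.0) -> float:
        """Amplitude of the band nearest ``center_cm1`` within ``tol``; 0 if none."""
        for b in self.bands:
            if abs(b.center_cm1 - center_cm1) <= tol:
                return b.amplitude
        return 0.0

    def centers(self) -> np.ndarray:
        return np.array([b.center_cm1 for b in self.bands])


def _B(center: float, amp: float, assignment: str, fwhm: float = DEFAULT_FWHM) -> Band:
    return Band(center, fwhm, amp, assignment)


# Pure-component presets.  Within-catalog amplitudes are free parameters
# chosen to satisfy the ordinal oxy/deoxy/plasma contrasts documented above;
# absolute values carry no physical meaning.
_PRESETS: dict[str, tuple[Band, ...]] = {
    "oxy_rbc": (
        _B(1636, 0.35, "ν(C=C) vinyl, oxy-enhanced"),
        _B(1621, 1.00, "ν(Ca=Cb) vinyl"),
        _B(1579, 0.45, "ν37, oxy-enhanced"),
        _B(1561, 0.30, "ν2 region, oxy-enhanced"),
        _B(1544, 0.95, "ν11 ν(CβCβ)"),
        _B(1527, 0.10, "ν38 shoulder"),
        _B(1448, 0.35, "δ(CH2/CH3)"),
        _B(1396, 0.25, "ν20, oxy-exclusive"),
        _B(1338, 0.55, "ν41 pyr half-ring"),
        _B(1305, 0.40, "ν21 δ(CmH)"),
        _B(1222, 0.40, "ν13/ν42 δ(CmH)"),
        _B(1213, 0.25, "ν5+ν18 δ(CmH)"),
        _B(1128, 0.30, "ν5 ν(Cβ-methyl)"),
        _B(1003, 0.20, "phenylalanine"),
        _B(787, 0.20, "ν6 pyr breathing"),
        _B(754, 0.55, "ν15 pyr breathing"),
        _B(672, 0.50, "ν7 δ(pyr deform)"),
    ),
    # Deoxy amplitudes carry a uniform ×1.104 factor so the oxy and deoxy
    # catalogs integrate to the same area: deoxygenation redistributes heme
    # scattering between bands rather than changing its total (hemoglobin
    # content does not depend on oxygenation state).
    "deoxy_rbc": (
        _B(1636, 0.110, "ν(C=C) vinyl, weak in deoxy"),
        _B(1619, 0.662, "ν(Ca=Cb) vinyl"),
        _B(1579, 0.199, "ν37"),
        _B(1561, 0.110, "ν2 region"),
        _B(1544, 1.104, "ν11, dominant in deoxy"),
        _B(1527, 0.497, "ν38 shoulder, deoxy-enhanced"),
        _B(1448, 0.386, "δ(CH2/CH3)"),
        _B(1338, 0.607, "ν41 pyr half-ring"),
        _B(1305, 0.442, "ν21 δ(CmH)"),
        _B(1222, 0.276, "ν13/ν42 δ(CmH)"),
        _B(1213, 0.442, "ν5+ν18 δ(CmH)"),
        _B(1128, 0.331, "ν5 ν(Cβ-methyl)"),
        _B(1003, 0.221, "phenylalanine"),
        _B(787, 0.552, "ν6 pyr breathing, deoxy-enhanced"),
        _B(754, 0.607, "ν15 pyr breathing"),
        _B(672, 0.552, "ν7 δ(pyr deform)"),
    ),
    "plasma": (
        _B(1660, 0.35, "amide I"),
        _B(1524, 1.00, "carotenoid ν(C=C)"),
        _B(1444, 0.40, "δ(CH2/CH3)"),
        _B(1157, 0.90, "carotenoid ν(C-C)"),
        _B(1004, 0.35, "phenylalanine"),
    ),
    "protein_common": (
        _B(1655, 0.60, "amide I"),
        _B(1448, 0.50, "δ(CH2/CH3)"),
        _B(1088, 0.25, "δ(CH2/CH3)"),
        _B(1003, 0.45, "phenylalanine ring breathing"),
        _B(938, 0.20, "ν(C-C)"),
        _B(856, 0.25, "ν(C-C)"),
    ),
}


def make_band_catalog(preset: str) -> BandCatalog:
    """Return an immutable preset catalog (oxy_rbc, deoxy_rbc, plasma, protein_common)."""
    try:
        bands = _PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return BandCatalog(preset, bands)


def _lineshape(x: np.ndarray, band: Band, kind: str) -> np.ndarray:
    # Both shapes are parameterised so the peak height equals the amplitude.
    half = 0.5 * band.fwhm_cm1
    d = x - band.center_cm1
    if kind == "lorentzian":
        return band.amplitude * half**2 / (d**2 + half**2)
    if kind == "gaussian":
        return band.amplitude * np.exp(-4.0 * np.log(2.0) * d**2 / band.fwhm_cm1**2)
    raise ValueError(f"unknown lineshape {kind!r}")


def grid_axis(grid: tuple[float, float, float]) -> np.ndarray:
    start, stop, step = grid
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def render_component(
    catalog: BandCatalog,
    grid: tuple[float, float, float] = (600.0, 1800.0, 1.0),
    lineshape: Literal["lorentzian", "gaussian"] = "lorentzian",
) -> Spectrum:
    """Noiseless, baseline-free pure-component spectrum on the given grid."""
    if not catalog.bands:
        raise ValueError("cannot render an empty catalog")
    x = grid_axis(grid)
    y = np.zeros_like(x)
    for band in catalog.bands:
        y += _lineshape(x, band, lineshape)
    return Spectrum(x, y, {"component_name": catalog.name, "state": "n/a"})


@lru_cache(maxsize=64)
def _cached_component(preset: str, grid: tuple[float, float, float], lineshape: str) -> np.ndarray:
    return render_component(make_band_catalog(preset), grid, lineshape).intensities


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    The default encodes the modelled sex effect: the mean oxygenated-RBC
    fraction is higher in males (0.75) than in females (0.65), with a
    per-sample spread of 0.03; drawn fractions are clipped to [0, 1].
    """

    n_male: int = 15
    n_female: int = 15
    oxy_fraction_male_mean: float = 0.75
    oxy_fraction_female_mean: float = 0.65
    oxy_fraction_sd: float = 0.03
    plasma_fraction: float = 0.10
    baseline_coeffs_range: float = 0.3
    baseline_order: int = 5
    noise_sd: float = 0.005
    scale: float = 1.0
    grid: tuple[float, float, float] = (600.0, 1800.0, 1.0)
    lineshape: str = "lorentzian"
    component: str = "whole_blood"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("oxy_fraction_male_mean", "oxy_fraction_female_mean", "plasma_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.oxy_fraction_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be ≥ 0")

    @classmethod
    def rbc(cls, **overrides) -> "CohortConfig":
        """Washed-RBC preset: no plasma contribution."""
        overrides.setdefault("plasma_fraction", 0.0)
        overrides.setdefault("component", "rbc")
        return cls(**overrides)


def _draw_baseline(config: CohortConfig, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    b = config.baseline_coeffs_range
    coeffs = rng.uniform(-b, b, size=config.baseline_order + 1)
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0  # scale axis to [-1, 1]
    baseline = np.polynomial.polynomial.polyval(t, coeffs)
    return baseline - baseline.min()  # constant shift keeps order, ensures ≥ 0


def simulate_sample(
    sex: str,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    oxy_fraction: float | None = None,
    sample_id: str = "S00",
) -> Spectrum:
    """Draw one sample spectrum; metadata records sex and the drawn f.

    ``oxy_fraction`` overrides the random draw (used by linearity tests).
    The rng is consumed in a fixed order (f, baseline coefficients, noise)
    so that identical generator states give bit-identical spectra.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    mean = config.oxy_fraction_male_mean if sex == "male" else config.oxy_fraction_female_mean
    f_drawn = float(np.clip(rng.normal(mean, config.oxy_fraction_sd), 0.0, 1.0))
    f = f_drawn if oxy_fraction is None else float(oxy_fraction)

    x = grid_axis(config.grid)
    s_oxy = _cached_component("oxy_rbc", config.grid, config.lineshape)
    s_deoxy = _cached_component("deoxy_rbc", config.grid, config.lineshape)
    s_plasma = _cached_component("plasma", config.grid, config.lineshape)

    signal = config.scale * (f * s_oxy + (1.0 - f) * s_deoxy)
    signal = signal + config.plasma_fraction * s_plasma
    baseline = _draw_baseline(config, x, rng)
    noise = rng.normal(0.0, config.noise_sd, size=x.size) if config.noise_sd > 0 else 0.0
    y = signal + baseline + noise
    meta = {
        "sample_id": sample_id,
        "sex": sex,
        "component": config.component,
        "state": "ambient",
        "true_oxy_fraction": f,
        "true_baseline": baseline,
    }
    return Spectrum(x, y, meta)


def simulate_cohort(config: CohortConfig) -> SpectrumSet:
    """Seeded labeled cohort on a shared axis; reproducible from the config alone."""
    if config.n_male < 1 or config.n_female < 1:
        raise ValueError("need at least one sample per sex")
    rng = np.random.default_rng(config.seed)
    spectra = []
    for i in range(config.n_male):
        spectra.append(simulate_sample("male", config, rng, sample_id=f"M{i + 1:02d}"))
    for i in range(config.n_female):
        spectra.append(simulate_sample("female", config, rng, sample_id=f"F{i + 1:02d}"))
    return SpectrumSet(spectra)


def oxy_minus_deoxy_contrast(
    grid: tuple[float, float, float] = (600.0, 1800.0, 1.0),
    lineshape: str = "lorentzian",
) -> Spectrum:
    """The oxy-RBC minus deoxy-RBC pure-component difference spectrum.

    This is the spectral signature the sex effect injects into cohorts: the
    between-sex mean difference of noiseless mixtures is Δf times this.
    """
    oxy = _cached_component("oxy_rbc", grid, lineshape)
    deoxy = _cached_component("deoxy_rbc", grid, lineshape)
    return Spectrum(grid_axis(grid), oxy - deoxy, {"component_name": "oxy_minus_deoxy"})
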