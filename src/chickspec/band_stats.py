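"""Group-wise spectral statistics and band-feature construction.

Mean ± SD spectra per group, male-minus-female difference spectra,
pointwise two-sample t-tests with a p < α significance mask, windowed
band-intensity extraction, minimal-p-value band selection with a spacing
constraint, and scale-invariant band-ratio features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "GroupSummary",
    "TTestProfile",
    "group_summary",
    "difference_spectrum",
    "pointwise_ttest",
    "band_intensity",
    "select_bands",
    "pair_bands_by_sign",
    "ratio_features",
]


@dataclass(frozen=True)
class GroupSummary:
    """Pointwise mean and sample SD (ddof=1; 0 when n=1) of one group."""

    mean: Spectrum
    sd: Spectrum
    n: int
    label: object


@dataclass(frozen=True)
class TTestProfile:
    """Per-wavenumber two-sample t statistics with significance mask (p < alpha)."""

    wavenumbers: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    alpha: float = 0.05

    @property
    def mask(self) -> np.ndarray:
        return self.p_value < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber_cm1": self.wavenumbers,
                "t_statistic": self.t_statistic,
                "p_value": self.p_value,
                "significant": self.mask,
            }
        )


def group_summary(spectra: SpectrumSet, by: str, value) -> GroupSummary:
    group = spectra.subset(by, value)  # raises if empty
    mat = group.intensity_matrix()
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(group) > 1 else np.zeros(mat.shape[1])
    axis = group.wavenumbers
    meta = {by: value, "n": len(group)}
    return GroupSummary(
        mean=Spectrum(axis, mean, {**meta, "statistic": "mean"}),
        sd=Spectrum(axis, sd, {**meta, "statistic": "sd"}),
        n=len(group),
        label=value,
    )


def difference_spectrum(spectra: SpectrumSet, group_a, group_b, by: str = "sex") -> Spectrum:
    """mean(group_a) − mean(group_b); metadata records the subtraction order."""
    a = group_summary(spectra, by, group_a)
    b = group_summary(spectra, by, group_b)
    return Spectrum(
        a.mean.wavenumbers,
        a.mean.intensities - b.mean.intensities,
        {"difference": f"{group_a} - {group_b}", "n_a": a.n, "n_b": b.n},
    )


def _ttest_matrix(
    a: np.ndarray, b: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sample t-test with explicit zero-variance conventions."""
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "student"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # Zero pooled variance: identical constants → no evidence (t=0, p=1);
    # distinct constants → infinitely strong evidence (p→0).
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    if degenerate.any():
        mean_diff = a.mean(axis=0) - b.mean(axis=0)
        same = degenerate & (mean_diff == 0)
        diff = degenerate & (mean_diff != 0)
        t[same], p[same] = 0.0, 1.0
        t[diff] = np.sign(mean_diff[diff]) * np.inf
        p[diff] = 0.0
    return t, p


def pointwise_ttest(
    spectra: SpectrumSet,
    label_key: str = "sex",
    groups: tuple = ("male", "female"),
    alpha: float = 0.05,
    variant: Literal["student", "welch"] = "student",
) -> TTestProfile:
    """Two-sample t-test at every wavenumber (pooled-variance Student's by default).

    Two-sided p-values; no multiple-testing correction is applied — the mask
    flags raw p < alpha.
    """
    a = spectra.subset(label_key, groups[0]).intensity_matrix()
    b = spectra.subset(label_key, groups[1]).intensity_matrix()
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(
            f"each group needs ≥ 2 samples, got {a.shape[0]} and {b.shape[0]}"
        )
    t, p = _ttest_matrix(a, b, variant)
    return TTestProfile(spectra.wavenumbers, t, p, alpha)


def band_intensity(
    spectrum: Spectrum,
    center_cm1: float,
    window_cm1: float = 4.0,
    mode: Literal["nearest_point", "local_max", "window_mean"] = "local_max",
) -> float:
    """Scalar band intensity at ``center_cm1``.

    ``local_max`` (default) takes the maximum within ±window, robust to
    calibration jitter up to the grid step; ``nearest_point`` reads the
    stored value at the closest axis point; ``window_mean`` averages the
    window.
    """
    x, y = spectrum.wavenumbers, spectrum.intensities
    if not (x[0] <= center_cm1 <= x[-1]):
        raise ValueError(f"band center {center_cm1} outside axis [{x[0]}, {x[-1]}]")
    if mode == "nearest_point":
        return float(y[np.argmin(np.abs(x - center_cm1))])
    sel = np.abs(x - center_cm1) <= window_cm1
    if not sel.any():
        raise ValueError(f"±{window_cm1} cm⁻¹ window around {center_cm1} contains no grid point")
    if mode == "local_max":
        return float(y[sel].max())
    if mode == "window_mean":
        return float(y[sel].mean())
    raise ValueError(f"unknown extraction mode {mode!r}")


def select_bands(
    profile: TTestProfile, k: int = 4, min_separation_cm1: float = 10.0
) -> list[float]:
    """The k wavenumbers of smallest p, greedily spaced ≥ min_separation apart.

    The spacing rule prevents one broad significant band from being picked
    several times.  Ties break toward the lower wavenumber.  If fewer than k
    significant (masked) points exist, all significant points are returned
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    order = np.lexsort((profile.wavenumbers, profile.p_value))
    selected: list[float] = []
    masked_only = profile.mask
    for idx in order:
        if not masked_only[idx]:
            continue
        wn = float(profile.wavenumbers[idx])
        if all(abs(wn - s) >= min_separation_cm1 for s in selected):
            selected.append(wn)
        if len(selected) == k:
            return selected
    warnings.warn(
        f"only {len(selected)} significant bands available (requested {k})",
        stacklevel=2,
    )
    return selected


def select_paired_bands(
    profile: TTestProfile, n_pairs: int = 2, min_separation_cm1: float = 10.0
) -> list[tuple[float, float]]:
    """Minimal-p bands balanced by effect direction, paired across directions.

    Picks the ``n_pairs`` smallest-p significant wavenumbers where the first
    group is stronger (t > 0) and likewise where it is weaker (t < 0), then
    pairs them rank by rank.  This is the robust form of minimal-p band
    selection for ratio building: a plain top-k can land entirely on one
    side of the difference spectrum, leaving nothing to take a ratio
    against.
    """
    out: dict[int, list[float]] = {1: [], -1: []}
    order = np.lexsort((profile.wavenumbers, profile.p_value))
    for idx in order:
        if not profile.mask[idx]:
            continue
        sign = 1 if profile.t_statistic[idx] > 0 else -1
        wn = float(profile.wavenumbers[idx])
        chosen = out[1] + out[-1]
        if len(out[sign]) < n_pairs and all(
            abs(wn - s) >= min_separation_cm1 for s in chosen
        ):
            out[sign].append(wn)
        if len(out[1]) == n_pairs and len(out[-1]) == n_pairs:
            break
    if len(out[1]) < n_pairs or len(out[-1]) < n_pairs:
        warnings.warn(
            f"only {len(out[1])} stronger / {len(out[-1])} weaker significant "
            f"bands available (requested {n_pairs} pairs)",
            stacklevel=2,
        )
    return list(zip(out[1], out[-1]))


def pair_bands_by_sign(
    bands: Sequence[float], difference: Spectrum, window_cm1: float = 4.0
) -> list[tuple[float, float]]:
    """Pair male-stronger bands with female-stronger bands.

    Bands are split by the sign of the male-minus-female difference spectrum
    at each band (windowed extraction of the extreme value), then paired
    across the two groups in order of decreasing |difference|.
    """
    signed = []
    for wn in bands:
        sel = np.abs(difference.wavenumbers - wn) <= window_cm1
        vals = difference.intensities[sel]
        v = vals[np.argmax(np.abs(vals))]
        signed.append((wn, float(v)))
    stronger_male = sorted((x for x in signed if x[1] > 0), key=lambda x: -abs(x[1]))
    stronger_female = sorted((x for x in signed if x[1] <= 0), key=lambda x: -abs(x[1]))
    return [
        (m[0], f[0]) for m, f in zip(stronger_male, stronger_female)
    ]


def ratio_features(
    spectra: SpectrumSet,
    pairs: Sequence[tuple[float, float]],
    window_cm1: float = 4.0,
    mode: str = "local_max",
    label_key: str = "sex",
) -> pd.DataFrame:
    """One row per sample: extracted band intensities I_λ plus ratios R = I_a/I_b.

    Ratios are invariant to per-sample intensity rescaling, which is what
    makes them usable as biomarker features across normalization choices.
    """
    centers = sorted({c for pair in pairs for c in pair})
    rows = []
    for i, s in enumerate(spectra):
        row: dict = {
            "sample_id": s.meta.get("sample_id", f"#{i}"),
            label_key: s.meta.get(label_key),
        }
        for c in centers:
            row[f"I_{c:g}"] = band_intensity(s, c, window_cm1, mode)
        for num, den in pairs:
            d = row[f"I_{den:g}"]
            if d == 0:
                raise ZeroDivisionError(
                    f"zero denominator intensity at {den:g} cm⁻¹ for sample "
                    f"{row['sample_id']}"
                )
            row[f"R_{num:g}/{den:g}"] = row[f"I_{num:g}"] / d
        rows.append(row)
    return pd.DataFrame(rows)
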