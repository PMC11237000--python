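"""Core containers for one-dimensional Raman spectra.

A :class:`Spectrum` couples a strictly increasing wavenumber axis (cm⁻¹)
with an intensity vector (arbitrary counts) and sample metadata; a
:class:`SpectrumSet` is an axis-aligned collection with group labels
accessible by metadata key.  These are the universal units of I/O for the
whole package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np

SEXES = ("male", "female", "unknown")
COMPONENTS = ("whole_blood", "rbc", "plasma")
STATES = ("ambient", "oxy", "deoxy", "n/a")


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum on a strictly increasing wavenumber grid.

    Parameters
    ----------
    wavenumbers : array of float
        Raman shift axis in cm⁻¹, strictly increasing, length ≥ 2.
    intensities : array of float
        Intensity counts, same length as the axis.
    meta : dict
        Free-form sample metadata.  Conventional keys: ``sample_id``,
        ``sex`` (male/female/unknown), ``component`` (whole_blood/rbc/
        plasma), ``state`` (ambient/oxy/deoxy/n/a), and simulation ground
        truth such as ``true_oxy_fraction``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if wn.size != it.size:
            raise ValueError(
                f"axis length {wn.size} != intensity length {it.size}"
            )
        if wn.size < 1:
            raise ValueError("a spectrum needs at least 1 point")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray, **meta_updates: Any) -> "Spectrum":
        """Copy with new intensities on the same axis (metadata carried over)."""
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.wavenumbers, np.asarray(intensities, dtype=float), meta)

    def with_axis(self, wavenumbers: np.ndarray) -> "Spectrum":
        return Spectrum(np.asarray(wavenumbers, dtype=float), self.intensities, dict(self.meta))

    def resample(self, new_axis: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``new_axis``; extrapolation is refused."""
        new_axis = np.asarray(new_axis, dtype=float)
        lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
        if new_axis[0] < lo - 1e-9 or new_axis[-1] > hi + 1e-9:
            raise ValueError(
                f"resampling would extrapolate: target [{new_axis[0]}, {new_axis[-1]}] "
                f"outside source [{lo}, {hi}]"
            )
        return Spectrum(new_axis, np.interp(new_axis, self.wavenumbers, self.intensities), dict(self.meta))


class SpectrumSet:
    """An ordered collection of spectra sharing one wavenumber axis."""

    def __init__(self, spectra: Sequence[Spectrum], resample: bool = False):
        spectra = list(spectra)
        if not spectra:
            raise ValueError("SpectrumSet requires at least one spectrum")
        axis = spectra[0].wavenumbers
        aligned = [spectra[0]]
        for s in spectra[1:]:
            if s.wavenumbers.shape == axis.shape and np.allclose(s.wavenumbers, axis):
                aligned.append(s)
            elif resample:
                aligned.append(s.resample(axis))
            else:
                raise ValueError(
                    "spectra do not share a common axis (pass resample=True to interpolate)"
                )
        self.spectra: list[Spectrum] = aligned

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def intensity_matrix(self) -> np.ndarray:
        """Samples × wavenumbers matrix of intensities."""
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self, key: str) -> list[Any]:
        """Per-sample metadata values for ``key`` (None where absent)."""
        return [s.meta.get(key) for s in self.spectra]

    def subset(self, key: str, value: Any) -> "SpectrumSet":
        members = [s for s in self.spectra if s.meta.get(key) == value]
        if not members:
            raise ValueError(f"no spectra with {key}={value!r}")
        return SpectrumSet(members)

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra])
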