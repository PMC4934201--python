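"""Core spectral containers.

A :class:`Spectrum` pairs a strictly increasing wavelength grid (nm, air)
with sampled values and a unit tag.  Wavelength grids are plain numpy
arrays validated by :func:`check_grid`; the working range of the toolkit
is 400–1000 nm, which covers the red/far-red fluorescence emission and
both telluric oxygen bands (O2-B near 687 nm, O2-A near 760 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "AbsorptionBand",
    "check_grid",
    "uniform_grid",
    "nearest_index",
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
]

WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 1000.0

#: Valid unit tags.  "irradiance" is spectral irradiance (mW m-2 nm-1),
#: "radiance" is spectral radiance (mW m-2 sr-1 nm-1), "reflectance" is
#: unitless in [0, 1], "counts" are raw detector counts.
UNITS = ("irradiance", "radiance", "reflectance", "counts")


def check_grid(wavelengths: np.ndarray) -> np.ndarray:
    """Validate a wavelength grid: finite, strictly increasing, in range.

    Returns the grid as a float64 array.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(wl)):
        raise ValueError("wavelength grid contains non-finite values")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
        raise ValueError(
            f"wavelengths must lie within [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
        )
    return wl


def uniform_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Uniform wavelength grid from `start` to at most `stop` with spacing `step`."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return check_grid(start + step * np.arange(n))


def nearest_index(wavelengths: np.ndarray, target: float) -> int:
    """Index of the grid sample nearest `target`; ties go to the shorter wavelength."""
    wl = np.asarray(wavelengths)
    i = int(np.searchsorted(wl, target))
    if i == 0:
        return 0
    if i >= wl.size:
        return wl.size - 1
    # left neighbour wins on exact ties
    if target - wl[i - 1] <= wl[i] - target:
        return i - 1
    return i


@dataclass(frozen=True)
class Spectrum:
    """Sampled spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        wl = check_grid(self.wavelengths)
        v = np.asarray(self.values, dtype=float)
        if v.shape != wl.shape:
            raise ValueError("values and wavelengths must have the same length")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if self.unit == "reflectance" and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("reflectance values must lie in [0, 1]")
        if self.unit == "counts" and v.min() < 0.0:
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.wavelengths.size

    def nearest_index(self, target: float) -> int:
        return nearest_index(self.wavelengths, target)

    def value_at(self, target: float) -> float:
        """Value at the grid sample nearest `target` (no interpolation)."""
        return float(self.values[self.nearest_index(target)])

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Spectrum":
        """New spectrum on the same grid with replaced values (and optionally unit)."""
        return Spectrum(self.wavelengths, values, unit or self.unit)

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum with lo <= wavelength <= hi (inclusive bounds)."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not m.any():
            raise ValueError(f"no samples in window [{lo}, {hi}] nm")
        return Spectrum(self.wavelengths[m], self.values[m], self.unit)


@dataclass(frozen=True)
class AbsorptionBand:
    """Gaussian telluric absorption feature.

    Transmittance is ``T(lam) = 1 - depth * exp(-(lam-center)^2 / (2 width^2))``,
    which stays in (0, 1] for depth in [0, 1).
    """

    center: float  # nm
    depth: float  # fraction of continuum removed at the band bottom
    width: float  # Gaussian sigma, nm

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth < 1.0):
            raise ValueError("band depth must be in [0, 1)")
        if self.width <= 0:
            raise ValueError("band width must be positive")

    def transmittance(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return 1.0 - self.depth * np.exp(-((wl - self.center) ** 2) / (2.0 * self.width**2))
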