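"""Vegetation indices computed from reflectance spectra.

Two indices accompany the SIF retrievals: the Photochemical Reflectance
Index ``PRI = (R531 - R570) / (R531 + R570)`` and the Red-Edge
Chlorophyll Index ``CI = R_NIR / R_rededge - 1``.  Band reflectances are
means over configurable wavelength windows; both forms are invariant to
a positive rescaling of the reflectance spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = ["IndexResult", "pri", "ci_rededge"]


@dataclass(frozen=True)
class IndexResult:
    name: str  # "PRI" or "CI_rededge"
    value: float


def _band_mean(R: Spectrum, lo: float, hi: float) -> float:
    mask = (R.wavelengths >= lo) & (R.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"reflectance grid does not cover [{lo}, {hi}] nm")
    return float(R.values[mask].mean())


def pri(R: Spectrum, half_width: float = 1.5) -> IndexResult:
    """Photochemical Reflectance Index from the 531 and 570 nm bands.

    Band reflectances are means over ±`half_width` nm windows.
    """
    r531 = _band_mean(R, 531.0 - half_width, 531.0 + half_width)
    r570 = _band_mean(R, 570.0 - half_width, 570.0 + half_width)
    return IndexResult("PRI", (r531 - r570) / (r531 + r570))


def ci_rededge(
    R: Spectrum,
    nir_window: tuple[float, float] = (760.0, 800.0),
    rededge_window: tuple[float, float] = (690.0, 710.0),
) -> IndexResult:
    """Red-Edge Chlorophyll Index: NIR over red-edge reflectance minus one."""
    r_nir = _band_mean(R, *nir_window)
    r_re = _band_mean(R, *rededge_window)
    if r_re == 0:
        raise ZeroDivisionError("red-edge reflectance is zero")
    return IndexResult("CI_rededge", r_nir / r_re - 1.0)
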