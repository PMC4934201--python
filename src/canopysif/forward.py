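"""Parametric forward simulator for canopy spectra.

Generates high-resolution (0.01 nm) downwelling irradiance, canopy
reflectance, two-peak chlorophyll fluorescence emission and the composed
upwelling radiance.  The generator is deliberately parametric rather than
a radiative-transfer model: the retrieval algorithms only respond to the
local spectral shape near the O2-A and O2-B bands, so the simulator
emulates the features that drive retrieval accuracy —

* a smooth (Planck-like) solar continuum multiplied by Gaussian telluric
  oxygen bands and by cos(solar zenith angle);
* a vegetation reflectance whose red-edge position and red trough depend
  on chlorophyll content (Cab), blended with a bright, slowly varying
  soil line through a leaf-area-index (LAI) cover fraction, so that the
  reflectance trend-line slope near O2-A grows with Cab, the slope near
  O2-B shrinks with Cab, and the curvature near O2-B grows with LAI;
* fluorescence as two Gaussian peaks (red ~687 nm, far-red ~740 nm)
  scaling with cos(SZA) and with canopy cover.

Upwelling radiance is composed as ``L = E * R / pi + F``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import AbsorptionBand, Spectrum, check_grid, uniform_grid

__all__ = [
    "O2A_BAND",
    "O2B_BAND",
    "DEFAULT_BANDS",
    "CanopyScene",
    "default_hires_grid",
    "solar_continuum",
    "simulate_downwelling",
    "soil_reflectance",
    "simulate_reflectance",
    "simulate_fluorescence",
    "compose_upwelling",
    "bare_land_scene",
]

# Band bottoms placed at the retrieval anchor wavelengths; O2-A is the
# deeper of the two oxygen features.
O2A_BAND = AbsorptionBand(center=760.519, depth=0.70, width=1.5)
O2B_BAND = AbsorptionBand(center=687.276, depth=0.40, width=1.0)
DEFAULT_BANDS = (O2B_BAND, O2A_BAND)

_H_C_K = 14387768.775  # h*c/k in nm*K, for the Planck continuum shape


def default_hires_grid(start: float = 475.0, stop: float = 863.0, step: float = 0.01) -> np.ndarray:
    """0.01 nm working grid over-covering the instrument range plus kernel margins."""
    return uniform_grid(start, stop, step)


@dataclass(frozen=True)
class CanopyScene:
    """Biophysical drivers plus reflectance/fluorescence shape parameters.

    Parameters
    ----------
    cab : chlorophyll a+b concentration, ug/cm^2 (>= 0)
    lai : leaf area index, unitless (>= 0); lai == 0 forces zero fluorescence
    sza : solar zenith angle, degrees in [0, 90)
    f_red_peak, f_farred_peak : fluorescence peak radiance amplitudes at
        ~687 and ~740 nm for overhead sun (mW m-2 sr-1 nm-1)
    red_edge_pos : logistic red-edge inflection wavelength, nm
    red_edge_width : logistic slope scale, nm
    red_trough : leaf-level reflectance floor in the red
    nir_plateau : leaf-level NIR plateau reflectance
    nir_slope : linear tilt of the NIR plateau (per nm), growing with Cab;
        this is the trend-line slope near O2-A that drives FLD's
        overestimation
    extinction : canopy gap-fraction extinction coefficient per unit LAI
    o2b_curvature : local curvature coefficient near O2-B per unit cover
        fraction (sign configurable; positive bends the reflectance upward)
    o2b_curvature_width : Gaussian envelope sigma (nm) localizing the
        curvature feature around the O2-B band
    """

    cab: float
    lai: float
    sza: float
    f_red_peak: float
    f_farred_peak: float
    red_edge_pos: float = 708.0
    red_edge_width: float = 9.0
    red_trough: float = 0.05
    nir_plateau: float = 0.50
    nir_slope: float = 4.0e-4
    extinction: float = 0.6
    o2b_curvature: float = 1.0e-4
    o2b_curvature_width: float = 6.0

    def __post_init__(self) -> None:
        if self.cab < 0:
            raise ValueError("cab must be >= 0")
        if self.lai < 0:
            raise ValueError("lai must be >= 0")
        if not (0.0 <= self.sza < 90.0):
            raise ValueError("sza must lie in [0, 90) degrees")
        if self.f_red_peak < 0 or self.f_farred_peak < 0:
            raise ValueError("fluorescence amplitudes must be >= 0")
        if self.lai == 0 and (self.f_red_peak > 0 or self.f_farred_peak > 0):
            raise ValueError("lai == 0 implies zero fluorescence amplitudes")

    @property
    def cover_fraction(self) -> float:
        """Canopy cover fraction 1 - exp(-k * LAI)."""
        return 1.0 - float(np.exp(-self.extinction * self.lai))

    @classmethod
    def from_conditions(cls, cab: float, lai: float, sza: float, **overrides) -> "CanopyScene":
        """Scene with shape parameters and fluorescence amplitudes derived
        from (Cab, LAI, SZA).

        The red edge shifts to longer wavelengths and the red trough
        deepens with Cab; fluorescence amplitudes scale with canopy cover,
        and the red peak is attenuated by chlorophyll reabsorption.
        """
        fc = 1.0 - float(np.exp(-0.6 * lai))
        scene = cls(
            cab=cab,
            lai=lai,
            sza=sza,
            f_red_peak=1.0 * fc * float(np.exp(-cab / 80.0)),
            f_farred_peak=1.8 * fc,
            red_edge_pos=700.0 + 0.20 * cab,
            red_trough=0.02 + 0.10 * float(np.exp(-cab / 25.0)),
            nir_slope=1.0e-5 * cab,
        )
        return replace(scene, **overrides) if overrides else scene


def solar_continuum(wavelengths: np.ndarray, e0: float = 1200.0, t_sun: float = 5800.0) -> np.ndarray:
    """Smooth solar continuum (Planck shape) normalized to `e0` at 700 nm.

    Units: mW m-2 nm-1 for overhead sun before telluric absorption.
    """
    wl = np.asarray(wavelengths, dtype=float)

    def planck(lam):
        return lam**-5 / np.expm1(_H_C_K / (lam * t_sun))

    return e0 * planck(wl) / planck(700.0)


def simulate_downwelling(
    sza: float,
    bands: tuple[AbsorptionBand, ...] | list[AbsorptionBand],
    grid: np.ndarray,
    e0: float = 1200.0,
) -> Spectrum:
    """Downwelling irradiance: continuum x band transmittances x cos(sza)."""
    wl = check_grid(grid)
    if not (0.0 <= sza < 90.0):
        raise ValueError("sza must lie in [0, 90) degrees")
    for band in bands:
        if not (wl[0] <= band.center <= wl[-1]):
            raise ValueError(
                f"grid [{wl[0]}, {wl[-1]}] nm does not cover band center {band.center} nm"
            )
    values = solar_continuum(wl, e0=e0) * np.cos(np.radians(sza))
    for band in bands:
        values = values * band.transmittance(wl)
    return Spectrum(wl, values, "irradiance")


def soil_reflectance(grid: np.ndarray) -> Spectrum:
    """Bright, slowly and linearly increasing bare-soil reflectance.

    Dry-soil level (~0.26 in the red): brighter than a closed canopy in
    the red/O2-B region, darker in the NIR, so sparse canopies are the
    noisier targets at O2-B.
    """
    wl = check_grid(grid)
    return Spectrum(wl, 0.22 + 2.0e-4 * (wl - 475.0), "reflectance")


def _leaf_reflectance(scene: CanopyScene, wl: np.ndarray) -> np.ndarray:
    """Leaf/canopy-level logistic red edge controlled by Cab."""
    s = 1.0 / (1.0 + np.exp(-(wl - scene.red_edge_pos) / scene.red_edge_width))
    # NIR tilt switched on through the red edge, so the plateau keeps a
    # Cab-dependent positive trend-line slope past 740 nm
    return scene.red_trough + (scene.nir_plateau - scene.red_trough) * s + scene.nir_slope * (wl - 740.0) * s


def simulate_reflectance(scene: CanopyScene, grid: np.ndarray) -> Spectrum:
    """Top-of-canopy reflectance: soil/vegetation blend plus O2-B curvature term.

    The logistic tail makes the trend-line slope near O2-A increase with
    Cab (the red edge sits closer to the band) and the slope near O2-B
    decrease with Cab; the cover-fraction blend makes the curvature near
    O2-B grow with LAI while LAI -> 0 degenerates to the linear soil line.
    """
    wl = check_grid(grid)
    fc = scene.cover_fraction
    veg = _leaf_reflectance(scene, wl)
    soil = soil_reflectance(wl).values
    r = soil * (1.0 - fc) + veg * fc
    # localized curvature near O2-B, proportional to canopy cover; the
    # short-range envelope keeps the feature non-polynomial over wide
    # fitting windows, as the chlorophyll absorption shoulder is in Fig.-3
    # style canopy reflectances
    d = wl - O2B_BAND.center
    r = r + scene.o2b_curvature * fc * d**2 * np.exp(-(d**2) / (2.0 * scene.o2b_curvature_width**2))
    return Spectrum(wl, np.clip(r, 1e-6, 1.0 - 1e-6), "reflectance")


def simulate_fluorescence(scene: CanopyScene, grid: np.ndarray) -> Spectrum:
    """Two-Gaussian SIF emission (687 nm sigma 10 nm; 740 nm sigma 35 nm).

    Amplitudes are the scene's overhead-sun peak values scaled by
    cos(sza), so emission decreases monotonically as the sun lowers.
    """
    wl = check_grid(grid)
    mu = np.cos(np.radians(scene.sza))
    f = scene.f_red_peak * np.exp(-((wl - 687.0) ** 2) / (2.0 * 10.0**2))
    f = f + scene.f_farred_peak * np.exp(-((wl - 740.0) ** 2) / (2.0 * 35.0**2))
    return Spectrum(wl, mu * f, "radiance")


def compose_upwelling(E: Spectrum, R: Spectrum, F: Spectrum) -> Spectrum:
    """Upwelling radiance ``L = E * R / pi + F`` on a shared grid."""
    if not (np.array_equal(E.wavelengths, R.wavelengths) and np.array_equal(E.wavelengths, F.wavelengths)):
        raise ValueError("E, R and F must share the same wavelength grid")
    if E.unit != "irradiance":
        raise ValueError("E must be tagged 'irradiance'")
    if R.unit != "reflectance":
        raise ValueError("R must be tagged 'reflectance'")
    if F.unit != "radiance":
        raise ValueError("F must be tagged 'radiance'")
    return Spectrum(E.wavelengths, E.values * R.values / np.pi + F.values, "radiance")


def bare_land_scene(grid: np.ndarray) -> tuple[Spectrum, Spectrum]:
    """Bare-land target: soil reflectance and identically zero fluorescence."""
    wl = check_grid(grid)
    return soil_reflectance(wl), Spectrum(wl, np.zeros_like(wl), "radiance")
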