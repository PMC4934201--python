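"""Scene -> instrument pipeline.

Composes the forward simulator and the instrument model into the
observation a retrieval algorithm actually sees: high-resolution
downwelling/upwelling spectra generated at 0.01 nm, smoothed with the
Gaussian spectral-response kernel, resampled onto the instrument grid,
and optionally expanded into paired noisy ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import (
    DEFAULT_BANDS,
    CanopyScene,
    bare_land_scene,
    compose_upwelling,
    default_hires_grid,
    simulate_downwelling,
    simulate_fluorescence,
    simulate_reflectance,
)
from .instrument import (
    DEFAULT_INSTRUMENT,
    InstrumentSpec,
    NoiseModel,
    SmoothingKernelSpec,
    noise_ensemble,
    smooth_and_resample,
)
from .spectra import Spectrum

__all__ = ["SimulatedObservation", "simulate_observation", "noisy_pair_ensembles"]

# distinct noise substreams for the two measured spectra of a pair
DOWNWELLING_STREAM = 0
UPWELLING_STREAM = 1


@dataclass(frozen=True)
class SimulatedObservation:
    """Noiseless instrument-grid observation of one scene.

    `truth_*` are the smoothed-and-resampled injected fluorescence
    radiances at the snapped band-bottom wavelengths — the reference
    values bias is measured against.
    """

    scene: CanopyScene | None
    downwelling: Spectrum  # irradiance on the instrument grid
    upwelling: Spectrum  # radiance on the instrument grid
    fluorescence: Spectrum  # injected SIF on the instrument grid
    reflectance: Spectrum  # hi-res reflectance resampled to instrument grid
    truth_o2a: float
    truth_o2b: float


def simulate_observation(
    scene: CanopyScene | None,
    instrument: InstrumentSpec = DEFAULT_INSTRUMENT,
    kernel: SmoothingKernelSpec | None = None,
    bands=DEFAULT_BANDS,
    hires_grid: np.ndarray | None = None,
) -> SimulatedObservation:
    """Simulate one noiseless paired observation on the instrument grid.

    ``scene=None`` simulates the bare-land target (soil reflectance,
    zero fluorescence) at a 30 degree solar zenith angle; pass a scene
    with ``lai=0`` to control the zenith angle of a bare target.
    """
    wl = default_hires_grid() if hires_grid is None else hires_grid
    if scene is None:
        scene_for_sun = CanopyScene(cab=0.0, lai=0.0, sza=30.0, f_red_peak=0.0, f_farred_peak=0.0)
    else:
        scene_for_sun = scene
    E_hi = simulate_downwelling(scene_for_sun.sza, bands, wl)
    if scene is None or scene.lai == 0:
        R_hi, F_hi = bare_land_scene(wl)
    else:
        R_hi = simulate_reflectance(scene, wl)
        F_hi = simulate_fluorescence(scene, wl)
    L_hi = compose_upwelling(E_hi, R_hi, F_hi)

    E = smooth_and_resample(E_hi, instrument, kernel)
    L = smooth_and_resample(L_hi, instrument, kernel)
    F = smooth_and_resample(F_hi, instrument, kernel)
    R = smooth_and_resample(R_hi, instrument, kernel)
    o2b, o2a = bands if bands[0].center < bands[1].center else (bands[1], bands[0])
    return SimulatedObservation(
        scene=scene,
        downwelling=E,
        upwelling=L,
        fluorescence=F,
        reflectance=R,
        truth_o2a=F.value_at(o2a.center),
        truth_o2b=F.value_at(o2b.center),
    )


def noisy_pair_ensembles(
    obs: SimulatedObservation, n: int, model: NoiseModel
) -> tuple[np.ndarray, np.ndarray]:
    """Paired noisy ensembles (E_set, L_set), each of shape (n, n_wl).

    Downwelling and upwelling draws use distinct deterministic
    substreams of the model seed; realization i of E pairs with
    realization i of L.
    """
    E_set = noise_ensemble(obs.downwelling, n, model, stream=DOWNWELLING_STREAM)
    L_set = noise_ensemble(obs.upwelling, n, model, stream=UPWELLING_STREAM)
    return E_set, L_set
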