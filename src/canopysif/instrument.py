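"""Spectrometer emulation.

Covers the four instrument-side operations of the observation system:

* Gaussian spectral-response smoothing of 0.01 nm data and resampling to
  the instrument grid (the QE65pro-like array spectrometer: 475.921 to
  862.227 nm, ~0.4 nm sampling, ~0.9 nm resolution);
* the shot-noise SNR model ``SNR(lam) = SNR_ref * sqrt(counts(lam) /
  counts_ref)`` and Gaussian noise injection with per-spectrum stretching
  of the peak count to a target value;
* single-step integration-time optimization
  ``IT_opt = IT_init * counts_opt / counts_init``;
* a linear detector-count model with saturation clipping, the measured
  3-adjacent-wavelength averaging, and the measurement-sequence
  simulation (panel / target acquisition with rotation latencies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, check_grid, uniform_grid

__all__ = [
    "InstrumentSpec",
    "SmoothingKernelSpec",
    "NoiseModel",
    "IntegrationTimeState",
    "DEFAULT_INSTRUMENT",
    "DEFAULT_KERNEL",
    "build_kernel",
    "smooth_and_resample",
    "snr_at",
    "add_noise",
    "noise_ensemble",
    "optimize_integration_time",
    "detector_counts",
    "adjacent_average",
    "AcquisitionReport",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """Array-spectrometer description.

    The real instrument grid is only approximately uniform; a uniform
    grid at the nominal sampling interval is the reproducible emulation.
    """

    grid_start: float = 475.921  # nm
    grid_end: float = 862.227  # nm
    ssi: float = 0.4  # spectral sampling interval, nm
    fwhm_d: float = 0.9  # spectral resolution after smoothing, nm
    saturation_counts: float = 65000.0
    dark_counts: float = 1500.0
    snr_ref: float = 1000.0
    counts_ref: float = 65000.0
    counts_opt_fraction: float = 0.80
    calibration: float = 5.0e-4  # radiance units per count per second

    def __post_init__(self) -> None:
        if self.grid_start >= self.grid_end:
            raise ValueError("grid_start must be < grid_end")
        if self.ssi <= 0 or self.fwhm_d <= 0:
            raise ValueError("ssi and fwhm_d must be positive")
        if not (0 < self.counts_ref <= self.saturation_counts):
            raise ValueError("counts_ref must lie in (0, saturation_counts]")
        if self.dark_counts > 3000:
            raise ValueError("dark_counts must not exceed 3000")

    @property
    def grid(self) -> np.ndarray:
        return uniform_grid(self.grid_start, self.grid_end, self.ssi)

    @property
    def counts_opt(self) -> float:
        """Target peak count for integration-time optimization."""
        return self.counts_opt_fraction * self.saturation_counts


@dataclass(frozen=True)
class SmoothingKernelSpec:
    """Tabulation of the Gaussian spectral-response filter kernel.

    The kernel broadens data sampled at `ssi_o` to resolution `fwhm_d`;
    it is tabulated every `step` nm over [-half_range, +half_range].
    """

    fwhm_d: float = 0.9
    ssi_o: float = 0.01
    step: float = 0.01
    half_range: float = 0.45

    def __post_init__(self) -> None:
        if self.fwhm_d <= self.ssi_o:
            raise ValueError("fwhm_d must exceed ssi_o (degenerate kernel)")
        if self.step <= 0 or self.half_range <= 0:
            raise ValueError("step and half_range must be positive")
        n_half = self.half_range / self.step
        if abs(n_half - round(n_half)) > 1e-9:
            raise ValueError("step must divide half_range")


DEFAULT_INSTRUMENT = InstrumentSpec()
DEFAULT_KERNEL = SmoothingKernelSpec()


def build_kernel(spec: SmoothingKernelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate the Gaussian smoothing kernel.

    ``K(lam) = 2 sqrt(2 ln 2) / sqrt(2 pi (FWHM_d^2 - SSI_o^2))
    * exp(-4 ln 2 lam^2 / (FWHM_d^2 - SSI_o^2))``

    i.e. a unit-mass Gaussian of FWHM ``sqrt(FWHM_d^2 - SSI_o^2)``.
    Returns (offsets, raw weights); the default tabulation (0.9 nm FWHM,
    0.01 nm step, +-0.45 nm) has 91 points.  Convolution normalizes the
    weights so constants are preserved; the raw tabulation is what this
    function returns.
    """
    n_half = round(spec.half_range / spec.step)
    offsets = spec.step * np.arange(-n_half, n_half + 1)
    f2 = spec.fwhm_d**2 - spec.ssi_o**2
    weights = (2.0 * math.sqrt(2.0 * math.log(2.0)) / math.sqrt(2.0 * math.pi * f2)) * np.exp(
        -4.0 * math.log(2.0) * offsets**2 / f2
    )
    return offsets, weights


def smooth_and_resample(
    hi_res: Spectrum,
    spec: InstrumentSpec = DEFAULT_INSTRUMENT,
    kernel_spec: SmoothingKernelSpec | None = None,
) -> Spectrum:
    """Convolve a high-resolution spectrum with the normalized Gaussian
    kernel, then resample onto the instrument grid.

    The input must be uniformly sampled at the kernel step and must
    over-cover the instrument grid by the kernel half-range on each side;
    there is no padding or extrapolation.
    """
    if kernel_spec is None:
        kernel_spec = SmoothingKernelSpec(fwhm_d=spec.fwhm_d)
    wl = hi_res.wavelengths
    d = np.diff(wl)
    if not np.allclose(d, kernel_spec.step, rtol=0, atol=1e-6):
        raise ValueError("hi-res input must be uniformly sampled at the kernel step")
    out_grid = spec.grid
    margin = kernel_spec.half_range
    if wl[0] > out_grid[0] - margin or wl[-1] < out_grid[-1] + margin:
        raise ValueError(
            "hi-res input must cover the instrument grid plus the kernel half-range"
        )
    _, weights = build_kernel(kernel_spec)
    w = weights / weights.sum()
    smoothed = np.convolve(hi_res.values, w, mode="valid")
    wl_valid = wl[(weights.size - 1) // 2 : wl.size - (weights.size - 1) // 2]
    resampled = np.interp(out_grid, wl_valid, smoothed)
    return Spectrum(out_grid, resampled, hi_res.unit)


@dataclass(frozen=True)
class NoiseModel:
    """Shot-noise model: SNR scales with the square root of counts.

    `snr_ref` is the SNR at the reference count level `counts_ref`
    (1000:1 at saturation for the emulated spectrometer).  Simulated
    radiances are converted to counts by stretching each spectrum's peak
    to `stretch_target` counts (~80% of saturation), then perturbed with
    zero-mean Gaussian noise of sd ``L(lam)/SNR(lam)``.  Dark noise
    (a few counts) is ignored.
    """

    snr_ref: float = 1000.0
    counts_ref: float = 65000.0
    stretch_target: float = 50000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_ref <= 0 or self.counts_ref <= 0 or self.stretch_target <= 0:
            raise ValueError("snr_ref, counts_ref and stretch_target must be positive")


def snr_at(counts: float | np.ndarray, model: NoiseModel) -> float | np.ndarray:
    """SNR at a given count level: ``SNR_ref * sqrt(counts / counts_ref)``."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    out = model.snr_ref * np.sqrt(c / model.counts_ref)
    return float(out) if np.isscalar(counts) else out


def _noise_sd(values: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Per-wavelength noise sd for one spectrum under the stretch convention."""
    vmax = values.max()
    if vmax <= 0:
        return np.zeros_like(values)
    counts = values / vmax * model.stretch_target
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = model.snr_ref * np.sqrt(counts / model.counts_ref)
        sd = np.where(counts > 0, values / np.where(snr > 0, snr, 1.0), 0.0)
    return sd


def _realization_rng(model: NoiseModel, stream: int, index: int) -> np.random.Generator:
    """Deterministic, order-independent substream for one realization."""
    ss = np.random.SeedSequence(entropy=model.seed, spawn_key=(stream, index))
    return np.random.default_rng(ss)


def add_noise(
    spectrum: Spectrum,
    model: NoiseModel,
    rng: np.random.Generator | None = None,
    stream: int = 0,
    index: int = 0,
) -> Spectrum:
    """One noisy realization of a radiance/irradiance spectrum.

    An all-zero spectrum is returned unchanged (zero signal, zero noise).
    Without an explicit `rng`, the draw comes from the deterministic
    substream addressed by (model.seed, stream, index).
    """
    if spectrum.values.min() < 0:
        raise ValueError("noise model requires non-negative spectra")
    sd = _noise_sd(spectrum.values, model)
    if not sd.any():
        return spectrum
    if rng is None:
        rng = _realization_rng(model, stream, index)
    return spectrum.with_values(spectrum.values + rng.standard_normal(sd.size) * sd)


def noise_ensemble(
    spectrum: Spectrum, n: int, model: NoiseModel, stream: int = 0
) -> np.ndarray:
    """(n, n_wavelengths) array of noisy realizations.

    Realization i is drawn from substream (seed, stream, i), so any
    subset of realizations is reproducible independently of n.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    sd = _noise_sd(spectrum.values, model)
    out = np.empty((n, spectrum.values.size))
    for i in range(n):
        rng = _realization_rng(model, stream, i)
        out[i] = spectrum.values + rng.standard_normal(sd.size) * sd
    return out


@dataclass(frozen=True)
class IntegrationTimeState:
    """Inputs of one single-step integration-time optimization."""

    it_init: float  # seconds
    counts_init: float  # max dark-subtracted count at it_init
    counts_opt: float  # target max count

    def __post_init__(self) -> None:
        if self.it_init <= 0:
            raise ValueError("it_init must be positive")
        if self.counts_opt <= 0:
            raise ValueError("counts_opt must be positive")
        if self.counts_init < 0:
            raise ValueError("counts_init must be non-negative")


def optimize_integration_time(state: IntegrationTimeState) -> float:
    """Single-step optimization ``IT_opt = IT_init * counts_opt / counts_init``.

    Assumes a linear detector response; no iteration.  A zero initial
    count means the target is unmeasurable.
    """
    if state.counts_init == 0:
        raise ValueError("counts_init is zero: target signal is unmeasurable")
    return state.it_init * state.counts_opt / state.counts_init


def detector_counts(
    radiance: Spectrum, it: float, spec: InstrumentSpec = DEFAULT_INSTRUMENT
) -> Spectrum:
    """Linear detector: ``counts = dark + radiance / calibration * it``,
    clipped at saturation."""
    if it <= 0:
        raise ValueError("integration time must be positive")
    counts = spec.dark_counts + radiance.values / spec.calibration * it
    return radiance.with_values(np.minimum(counts, spec.saturation_counts), unit="counts")


def adjacent_average(spectrum: Spectrum, window: int = 3) -> Spectrum:
    """Centered moving average; edge windows shrink to the available samples."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return spectrum
    half = window // 2
    v = spectrum.values
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(v.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, v.size - 1)
    avg = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return spectrum.with_values(avg)


@dataclass(frozen=True)
class AcquisitionReport:
    """Per-stage timing and count diagnostics of one measurement group."""

    panel_it: float
    target_it: float
    panel_peak_fraction: float  # peak counts / saturation after optimization
    target_peak_fraction: float
    total_duration: float  # seconds, including rotation/switch latencies
    stages: dict


def simulate_acquisition(
    panel_radiance: Spectrum,
    target_radiance: Spectrum,
    spec: InstrumentSpec = DEFAULT_INSTRUMENT,
    probe_it: float = 0.05,
    rotation_latency: float = 3.5,
    switch_latency: float = 0.15,
) -> AcquisitionReport:
    """Run the measurement sequence against the simulated detector.

    Stages: optimize the panel integration time from a probe exposure,
    measure the panel, rotate to the target, optimize and measure the
    target, rotate back.  Durations combine the integration times with
    the fixed configurable latencies.
    """

    def optimize(radiance: Spectrum) -> tuple[float, float]:
        probe = detector_counts(radiance, probe_it, spec)
        init = probe.values.max() - spec.dark_counts
        it = optimize_integration_time(
            IntegrationTimeState(it_init=probe_it, counts_init=init, counts_opt=spec.counts_opt)
        )
        measured = detector_counts(radiance, it, spec)
        return it, measured.values.max() / spec.saturation_counts

    panel_it, panel_frac = optimize(panel_radiance)
    target_it, target_frac = optimize(target_radiance)
    stages = {
        "panel_optimize": probe_it,
        "panel_measure": panel_it,
        "rotate_to_target": rotation_latency,
        "target_optimize": probe_it,
        "target_measure": target_it,
        "rotate_back": rotation_latency,
        "channel_switch": switch_latency,
    }
    return AcquisitionReport(
        panel_it=panel_it,
        target_it=target_it,
        panel_peak_fraction=panel_frac,
        target_peak_fraction=target_frac,
        total_duration=sum(stages.values()),
        stages=stages,
    )
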