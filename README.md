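# canopysif

Simulation and retrieval toolkit for automated canopy observation of
sun-induced chlorophyll fluorescence (SIF).

Field systems that monitor vegetation photosynthesis measure paired
downwelling irradiance (off a Lambertian reference panel) and canopy
upwelling radiance with an array spectrometer, and retrieve the faint
fluorescence radiance (~1 mW m⁻² sr⁻¹ nm⁻¹, against reflected radiance
two orders of magnitude larger) inside the telluric oxygen absorption
bands — O₂-B at 687.276 nm and the deeper O₂-A at 760.519 nm. Designing
such a system raises questions this package answers by simulation:
which retrieval algorithm and wavelength parameters are most accurate at
a given spectral resolution, sampling and SNR; how retrieval precision
depends on chlorophyll content, leaf area index and sun angle; and how
to set detector integration times on the fly.

The package provides:

* a **parametric forward simulator** — solar continuum with Gaussian O₂
  bands, canopy reflectance whose red-edge slope and O₂-B curvature
  respond to chlorophyll (Cab) and leaf area index (LAI), two-peak
  fluorescence emission, composed as `L = E·R/π + F` at 0.01 nm;
* an **instrument emulation** — Gaussian spectral-response smoothing
  (0.9 nm FWHM, 91-point kernel) and resampling to the 0.4 nm instrument
  grid, shot-noise SNR model `SNR(λ) = SNR_ref·√(counts(λ)/counts_ref)`,
  and the single-step integration-time optimization
  `IT_opt = IT_init·counts_opt/counts_init`;
* the three standard **retrieval algorithms** with bundled operational
  and candidate wavelength parameterizations:
  - FLD: `F = (E_out·L_in − E_in·L_out)/(E_out − E_in)`,
  - 3FLD: left/right shoulders interpolated to the band bottom,
  - SFM: least-squares fit of `L(λ) = E(λ)·r(λ)/π + F(λ)` with
    polynomial `r` and `F`;
* **vegetation indices** (PRI, red-edge chlorophyll index) and
  **Monte-Carlo experiments** (1000-member paired noise ensembles) that
  quantify each algorithm's bias and standard deviation across Cab, LAI
  and solar-zenith sweeps, plus a diurnal SIF-vs-PAR analogue.

## Worked example

```python
from canopysif import CanopyScene, retrieve, selected_window, simulate_observation

obs = simulate_observation(CanopyScene.from_conditions(cab=40, lai=4, sza=30))
for band, truth in (("O2A", obs.truth_o2a), ("O2B", obs.truth_o2b)):
    for alg in ("FLD", "3FLD", "SFM"):
        res = retrieve(obs.downwelling, obs.upwelling, selected_window(band, alg))
        print(band, alg, f"{res.f_value:.4f}  truth {truth:.4f}  bias {res.f_value-truth:+.4f}")
```

prints (noiseless retrieval, radiances in mW m⁻² sr⁻¹ nm⁻¹):

```
O2A FLD  1.3057  truth 1.1976  bias +0.1082
O2A 3FLD 1.2584  truth 1.1976  bias +0.0608
O2A SFM  1.1716  truth 1.1976  bias -0.0260
O2B FLD  5.1395  truth 0.9302  bias +4.2093
O2B 3FLD 0.6457  truth 0.9302  bias -0.2845
O2B SFM  0.9030  truth 0.9302  bias -0.0272
```

FLD overestimates wherever reflectance slopes across its two channels —
mildly at O₂-A, severely at the shallow O₂-B band — while 3FLD and SFM
stay close to the injected truth; under noise, SFM also has the smallest
ensemble standard deviation. The `examples/` directory holds short
narrative scripts for each capability (scene simulation, retrieval,
integration-time optimization, Monte-Carlo precision, diurnal course),
and the `canopysif` command-line tool exposes the same operations
(`simulate`, `retrieve`, `indices`, `evaluate`, `acquire-sim`).

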