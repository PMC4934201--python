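# Methods

`canopysif` simulates and evaluates the computational core of an automated
canopy observation system for sun-induced chlorophyll fluorescence (SIF):
the paired measurement of downwelling irradiance (via a Lambertian
reference panel) and canopy upwelling radiance with a single array
spectrometer, and the retrieval of the fluorescence radiance filling in
the telluric oxygen bands O₂-B (687.276 nm) and O₂-A (760.519 nm).

## Forward model

The upwelling radiance is composed as

    L(λ) = E(λ) · R(λ) / π + F(λ)

with `E` the downwelling irradiance, `R` the top-of-canopy reflectance and
`F` the fluorescence radiance. All spectra are generated on a 0.01 nm
working grid (475–863 nm) and then passed through the instrument model.
The generator is parametric, not a radiative-transfer model: the retrieval
algorithms respond only to the local spectral shape near the oxygen bands,
so those shapes are what the generator controls explicitly.

**Solar continuum and absorption.** The continuum is a 5800 K Planck shape
normalized to 1200 mW m⁻² nm⁻¹ at 700 nm, multiplied by cos(SZA) and by
one Gaussian transmittance per band, `T(λ) = 1 − d·exp(−(λ−λ₀)²/2w²)`.
Defaults: O₂-A depth 0.70, σ 1.5 nm; O₂-B depth 0.40, σ 1.0 nm, with the
band bottoms at the retrieval anchors. Real oxygen bands have line-by-line
structure; a single Gaussian reproduces the two features that matter at
0.9 nm resolution — the in-band/shoulder contrast and the fact that O₂-A
is much deeper than O₂-B.

**Reflectance.** A leaf-level logistic red edge (inflection 700 + 0.2·Cab
nm, slope scale 9 nm; trough 0.02 + 0.10·e^(−Cab/25), plateau 0.50) with a
linear NIR tilt of 10⁻⁵·Cab per nm, blended with a bright linear soil line
(0.22 + 2·10⁻⁴·(λ−475)) through the cover fraction `fc = 1 − e^(−0.6·LAI)`,
plus a localized curvature feature near O₂-B (coefficient 10⁻⁴·fc per nm²,
Gaussian envelope σ 6 nm). These choices were calibrated once, at design
time, so the structure the retrievals are known to respond to is present:
the trend-line slope near O₂-A grows with chlorophyll (the source of FLD's
overestimation), the slope near O₂-B shrinks with chlorophyll, the
curvature near O₂-B grows with leaf area, and LAI → 0 degenerates to the
linear soil spectrum. The curvature sign and scale are scene parameters,
not constants, since the direction of the O₂-B curvature–chlorophyll
relation is an observational question the generator should not hard-code.

**Fluorescence.** Two Gaussians: red peak at 687 nm (σ 10 nm) and far-red
peak at 740 nm (σ 35 nm), scaled by cos(SZA). Scene-derived amplitudes are
`1.8·fc` (far-red) and `1.0·fc·e^(−Cab/80)` (red, attenuated by
reabsorption), giving SIF(760) ≈ 1.2 and SIF(687) ≈ 0.9 mW m⁻² sr⁻¹ nm⁻¹
for a dense canopy at a 30° sun — typical mid-season canopy values — with
SIF687 < SIF760. LAI = 0 forces both amplitudes to zero.

## Instrument model

**Spectral response.** High-resolution spectra are convolved with the
Gaussian kernel

    K(λ) = [2√(2 ln2) / √(2π (FWHM_d² − SSI_o²))] · exp(−4 ln2 · λ² / (FWHM_d² − SSI_o²))

tabulated every 0.01 nm over ±0.45 nm (91 points for the default 0.9 nm
resolution), then linearly resampled onto a uniform instrument grid
(475.921–862.227 nm, 0.4 nm sampling; the real detector grid is only
approximately uniform and is unpublished). As printed, the kernel is a
unit-mass Gaussian truncated at ±½ FWHM and integrates to ≈ 0.761 over the
tabulated range; the weights are renormalized to sum to one before
convolution so constants pass through exactly. The raw tabulation remains
available from `build_kernel`. Convolution requires the input to over-cover
the output grid by the kernel half-range; there is no padding.

**Noise.** Shot-noise scaling `SNR(λ) = SNR_ref·√(counts(λ)/counts_ref)`
with SNR 1000:1 at the 65 000-count saturation level. Each simulated
spectrum is stretched so its peak sits at 50 000 counts (≈ 80% of
saturation, the operating point of the exposure optimizer), then perturbed
per wavelength with zero-mean Gaussian noise of sd `L(λ)/SNR(λ)`; the
few-count dark noise is neglected. The stretch is applied per spectrum.
Realization *i* of an ensemble draws from the dedicated substream
`SeedSequence(seed, spawn_key=(stream, i))`, so any subset of realizations
is reproducible independently of the ensemble size, and downwelling and
upwelling ensembles use distinct streams.

**Exposure control.** The single-step optimization
`IT_opt = IT_init · counts_opt / counts_init` assumes a linear detector;
`counts_init` is the peak dark-subtracted count of a probe exposure and
`counts_opt` defaults to 0.80 × saturation = 52 000 counts. (Published
descriptions of the operating point mix "80–85%" with "≈ 50 000 counts",
which is 77%; the fraction is a configuration parameter.) On the simulated
linear detector the closure is exact in one step. The acquisition
simulator chains panel probe → panel measurement → rotation → target probe
→ target measurement with configurable latencies.

**Measured-data smoothing.** The 3-adjacent-wavelength average is a
centered 3-point moving mean (edges shrink to the available samples); the
window is configurable because "averaged with three adjacent wavelengths"
admits a 3- or 4-point reading.

## Retrieval algorithms

All three estimate `F` at the band bottom (`λ_in`) from a paired `(E, L)`
observation. `E` may be irradiance (divided by π internally — the
reference panel is modelled as perfectly Lambertian with unit reflectance)
or panel-equivalent radiance; FLD-family estimates are invariant to that
constant. Anchors snap to the nearest grid sample (ties toward shorter
wavelengths); the snap distance must stay below half the sample spacing.

* **FLD** uses `λ_in` and a single left shoulder:
  `F = (E_out·L_in − E_in·L_out)/(E_out − E_in)`. Exact for constant R and
  F across the channels; a reflectance slope toward the shoulder produces
  the characteristic overestimation.
* **3FLD** interpolates left and right shoulders to `λ_in` with weights
  `w_left = (λ_right−λ_in)/(λ_right−λ_left)`, `w_right = 1 − w_left`
  (computed from the snapped wavelengths) before applying the FLD formula.
  It removes the linear reflectance error; residual bias tracks the local
  curvature. The estimator is exact when R is linear, F constant and the
  two shoulders see equal continuum irradiance.
* **SFM** solves `L(λ) = E(λ)·r(λ)/π + F(λ)` by linear least squares over
  all samples in `[λ_left, λ_right]`, with `r` and `F` polynomials in
  `(λ − λ_in)` of configurable degrees — (1,1) at O₂-A, (2,1) at O₂-B for
  the operational windows. Centering on `λ_in` conditions the design
  matrix; the solver is SVD-based least squares (`lstsq`), with the
  normal-equations construction reserved for cross-checking. Rank
  deficiency (e.g. constant E with reflectance degree ≥ 1) raises a
  warning.

Window parameterizations — three candidate sets per algorithm and band
plus the operational selection — ship in `canopysif/data/windows.csv`.
Candidate shoulder lists are paired in printed order (3FLD pairs are
near-symmetric about the band bottom; SFM pairs form strictly widening
windows). Retrieved values may be negative under noise and are never
clipped, so ensemble statistics stay unbiased.

## Monte-Carlo experiments

Experiments pair realization *i* of the noisy downwelling ensemble with
realization *i* of the upwelling ensemble (n = 1000 by default) and report
mean, sd and bias against the injected truth — defined as the smoothed,
resampled fluorescence at the snapped band bottom. The standard studies:
candidate-window comparison on the Cab 40 / LAI 4 / SZA 30° reference
scene; chlorophyll sweep (10/30/50/70 µg/cm², LAI 4); LAI sweep (0–4,
Cab 40, with an additional SFM(1,1) variant at O₂-B); SZA sweep (10–70° in
5° steps) for vegetation and bare land; and a diurnal analogue in which
PAR follows cos(SZA) scaled to a configurable midday maximum and SIF is
retrieved along a latitude/declination-driven zenith trajectory. Every
experiment is reproducible from its config and seed; per-scene noise seeds
are derived deterministically from the experiment seed.

## What the generator does and does not establish

Passing the simulation suite shows that the retrieval implementations
respond correctly to the spectral structure the generator encodes — band
depth and width, reflectance slope/curvature, fluorescence in-filling,
count-proportional noise. It does not validate retrieval accuracy on real
canopies: the generator has no line-by-line absorption, no BRDF or
atmospheric path radiance, no wavelength-dependent instrument response or
stray light, and its reflectance trends, while directionally realistic,
are stylized. Two known behavioural limits:

* The noiseless bias crossover between SFM(1,1) and SFM(2,1) across the
  LAI sweep at O₂-B does not emerge here: the generator's O₂-B curvature
  grows smoothly with cover fraction, so the quadratic reflectance model
  dominates the linear one at every vegetated LAI. What does reproduce is
  the noise-robustness motivation for low-degree fitting — SFM(1,1) has
  a uniformly smaller ensemble sd than SFM(2,1).
* FLD's positive O₂-A bias at low chlorophyll (≈ +0.02) is smaller than
  the Monte-Carlo standard error of a 1000-member ensemble mean
  (≈ 0.013), so sign assertions on the stochastic estimate use a
  standard-error bound; the noiseless sweep carries the strict claim.

## Numerical choices

Degenerate inputs fail loudly: zero absorption contrast (FLD/3FLD),
underdetermined SFM windows, anchors farther than half a sample from the
grid, insufficient hi-res coverage for convolution, zero probe counts in
exposure optimization. An all-zero spectrum passes through the noise model
unchanged. Ensemble sd uses the n−1 normalization. Problem sizes in the
test suite and acceptance script are the study defaults (1000-member
ensembles; 10 000 for noise-moment checks).
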