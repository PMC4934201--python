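"""Simulate one vegetated scene and inspect what the spectrometer sees.

Builds a canopy with chlorophyll 40 ug/cm^2, LAI 4 under a 30 degree sun,
composes the upwelling radiance L = E*R/pi + F at 0.01 nm, then smooths
and resamples to the instrument grid (475.921-862.227 nm, 0.4 nm).
"""

from canopysif import CanopyScene, simulate_observation

scene = CanopyScene.from_conditions(cab=40.0, lai=4.0, sza=30.0)
obs = simulate_observation(scene)

E, L = obs.downwelling, obs.upwelling
print(f"instrument grid: {E.wavelengths[0]:.3f}-{E.wavelengths[-1]:.3f} nm, {len(E)} samples")
print(f"downwelling at O2-A bottom: {E.value_at(760.519):8.2f} mW m-2 nm-1")
print(f"downwelling on the shoulder: {E.value_at(770.0):8.2f} mW m-2 nm-1")
print(f"upwelling radiance at O2-A:  {L.value_at(760.519):8.2f} mW m-2 sr-1 nm-1")
print(f"injected SIF at O2-A bottom: {obs.truth_o2a:8.4f} mW m-2 sr-1 nm-1")
print(f"injected SIF at O2-B bottom: {obs.truth_o2b:8.4f} mW m-2 sr-1 nm-1")
# The irradiance dip at 760.5 nm is the telluric oxygen band; the
# fluorescence "fills in" the corresponding dip of the upwelling radiance,
# which is what every retrieval algorithm exploits.
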