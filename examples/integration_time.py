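"""Single-step integration-time optimization on the simulated detector.

A probe exposure measures the peak count rate; one linear rescaling
IT_opt = IT_init * counts_opt / counts_init then lands the peak
dark-subtracted count on the target (80% of saturation).
"""

import numpy as np

from canopysif import (
    DEFAULT_INSTRUMENT,
    CanopyScene,
    IntegrationTimeState,
    detector_counts,
    optimize_integration_time,
    simulate_observation,
)

spec = DEFAULT_INSTRUMENT
obs = simulate_observation(CanopyScene.from_conditions(40.0, 4.0, 30.0))
target = obs.upwelling

probe_it = 0.02
probe = detector_counts(target, probe_it, spec)
counts_init = probe.values.max() - spec.dark_counts
print(f"probe exposure {probe_it*1e3:.0f} ms -> peak dark-subtracted counts {counts_init:.0f}")

it_opt = optimize_integration_time(
    IntegrationTimeState(it_init=probe_it, counts_init=counts_init, counts_opt=spec.counts_opt)
)
remeasured = detector_counts(target, it_opt, spec)
peak = remeasured.values.max() - spec.dark_counts
print(f"optimized exposure {it_opt*1e3:.1f} ms -> peak {peak:.0f} (target {spec.counts_opt:.0f})")
print(f"peak/saturation = {remeasured.values.max()/spec.saturation_counts:.3f}")
# The closure is exact on a noiseless linear detector: one step, no iteration.
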