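"""Monte-Carlo retrieval precision under the shot-noise model.

Generates 1000 paired noisy downwelling/upwelling realizations of the
reference scene and reports mean, standard deviation and bias of each
algorithm's retrieved SIF, mirroring how retrieval parameters are
benchmarked before field deployment.
"""

from canopysif import CanopyScene, NoiseModel, retrieve_ensemble, selected_window, simulate_observation
from canopysif.pipeline import noisy_pair_ensembles

obs = simulate_observation(CanopyScene.from_conditions(cab=40.0, lai=4.0, sza=30.0))
E_set, L_set = noisy_pair_ensembles(obs, n=1000, model=NoiseModel(seed=0))

print(f"{'band':5s} {'algorithm':10s} {'mean':>8s} {'sd':>8s} {'bias':>8s}   (n=1000)")
for band, truth in (("O2A", obs.truth_o2a), ("O2B", obs.truth_o2b)):
    for alg in ("FLD", "3FLD", "SFM"):
        stats = retrieve_ensemble(
            E_set, L_set, selected_window(band, alg), truth, wavelengths=obs.downwelling.wavelengths
        )
        print(f"{band:5s} {alg:10s} {stats.mean:8.4f} {stats.sd:8.4f} {stats.bias:+8.4f}")
# SFM averages noise over ~25 samples and has the smallest sd; the
# two-channel FLD is noisiest, especially at the shallow O2-B band.
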