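"""Single-neuron response metrics: responsiveness, tuning, OSI, correlations.

Cuts dF/F into a neuron x direction x trial tensor, classifies visually
responsive neurons, and summarizes tuning and pairwise correlation structure.
"""

import numpy as np

import popcode as pc

session = pc.simulate_session(pc.SimulationConfig.control(50, seed=2), "gratings")
dff = pc.compute_dff(session.recording)

tensor = pc.build_trial_tensor(dff.dff, session.protocol, window_s=2.0)
blanks = pc.blank_responses(dff.dff, session.protocol, window_s=2.0)
responsive = pc.classify_visually_responsive(tensor, blanks)
tuning = pc.compute_tuning(tensor, baseline=blanks.mean(axis=1))

print(f"visually responsive: {responsive.sum()} / 50")
print(f"median OSI (responsive): {np.median(tuning.osi[responsive]):.3f}")
print(f"mean max response (dF/F): {tuning.max_response[responsive].mean():.3f}")

hits = (
    tuning.preferred_direction[session.truth.is_tuned] * 45.0
    == session.truth.preferred_direction[session.truth.is_tuned]
)
print(f"preferred-direction recovery on tuned neurons: {hits.mean():.2f}")

sig = pc.signal_correlation(tensor)
noise = pc.noise_correlation(tensor)
print(f"signal correlation mean: {np.nanmean(sig.values):+.3f}")
print(f"noise correlation mean:  {np.nanmean(noise.values):+.3f}")
# Signal correlations reflect shared tuning (positive for same-preference
# pairs, negative for orthogonal ones); noise correlations reflect the shared
# latent and population gain fluctuations the generator plants.
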