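"""Predict the next posture by fusing the transition prior with a heartbeat
observation.

Fits an order-2 transition model on a simulated night, then shows how a bpm
reading reweights the sequential prior: anatomy forbids supine -> prone, so
that entry stays exactly zero no matter what the sensor says.
"""

from ppbn import (
    GeneratorConfig,
    Posture,
    build_calibrated_matrix,
    fit_transition_model,
    heartbeat_likelihood,
    predict_next,
    simulate_sequence,
)

gen = GeneratorConfig()
matrix = build_calibrated_matrix(gen)
night = simulate_sequence(matrix, n_epochs=5000, seed=3)
model = fit_transition_model([night], order=2, alpha=1.0)

history = [Posture.SUPINE, Posture.SUPINE]
prior_only = predict_next(model, history)
print("prior after two supine epochs:")
for label, p in prior_only.posterior.items():
    print(f"  {label.value:7s} {p:.4f}")

# a high bpm reading is more typical of the lateral postures here
obs = heartbeat_likelihood(observed_bpm=68.0, cfg=gen)
fused = predict_next(model, history, obs_likelihood=obs)
print("\nposterior after observing 68 bpm:")
for label, p in fused.posterior.items():
    print(f"  {label.value:7s} {p:.4f}")
print(f"\npredicted next posture: {fused.predicted.value}")
print("PRONE stays at 0 in both: a structural zero of the transition model.")
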