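"""Run the full recognition pipeline on a synthetic night.

Simulates frames and postures, preprocesses and featurises every frame,
trains the centroid classifier, fits the transition model, predicts each
epoch with Bayesian fusion, and prints the evaluation report.
"""

from ppbn import RunConfig, run_pipeline

report = run_pipeline(RunConfig(epochs=600, noise=0.05, seed=7))

print(f"epochs evaluated : {report['n_epochs']}")
print(f"accuracy         : {report['accuracy']:.4f}")
print(f"shifts per hour  : {report['shifts_per_hour']:.2f}")
print("occupancy        :", {k: round(v, 3) for k, v in report["occupancy"].items()})
print("per-posture prediction rate:")
for label, rate in report["prediction_rate_per_posture"].items():
    shown = "  n/a" if rate != rate else f"{rate:5.3f}"
    print(f"  {label:7s} {shown}")
print("\nWith noise 0 the accuracy is exactly 1.0; rising noise degrades the "
      "frame observations and the transition prior carries more weight.")
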