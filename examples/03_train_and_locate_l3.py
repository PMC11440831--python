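"""Train a small L3-detection U-net on a phantom cohort and locate L3.

This is a miniature of the full study (fewer phantoms) so it runs in a
couple of minutes on a laptop CPU; `bodycomp.experiments.run_l3_experiment`
is the full-size version."""

from bodycomp.experiments import run_l3_experiment

result = run_l3_experiment(seed=42, n=60, n_test=12, n_val=8, augment_factor=4)

print(f"held-out MAE: {result['mae_mm']:.2f} mm")
print(f"correct-slice rate (within 20 mm): {100 * result['correct_rate']:.0f} %")
print("signed errors (mm):", [float(round(e, 1)) for e in result["errors_mm"]])

# MAE is the mean absolute distance between the predicted and true L3
# z-positions; a prediction within 20 mm (half a vertebral body) still
# falls inside the L3 vertebra.
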