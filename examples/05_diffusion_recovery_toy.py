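"""End-to-end MRI-guided latent-diffusion resolution recovery (toy scale).

Runs the full experiment: generate a phantom dataset, simulate acquisition,
train the three modality autoencoders and the conditional diffusion U-Net,
recover held-out scans and compare recovery coefficients against the
uncorrected scans and the Richardson-Lucy baseline.

Runs for several minutes on one CPU (reduce n_train/train_steps for a faster,
rougher demonstration).
"""

from petrr.workbench import run_experiment

report = run_experiment({"seed": 1})

print("recovery coefficients (mean over held-out phantoms, SE):")
for method, s in report["summary"].items():
    print(f"  {method:12s} {s['rc_mean']:.3f} ({s['rc_se']:.3f})")
loss = report["ldm_loss"]
print(f"diffusion loss: first-20 mean {loss['first20_mean']:.3f} "
      f"-> last-20 mean {loss['last20_mean']:.3f}")
print("-> the diffusion recovery should land closest to RC = 1, with the\n"
      "   training loss decreasing over the run")
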