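"""Compare decoder accuracy across noise levels on simulated blocks.

For each noise scale sigma, simulates a few 40-target blocks (1 s analysis
windows) and prints the identification accuracy of each method.  Accuracy
falls with sigma for every method; the temporally local and filter-bank
variants degrade more slowly than plain MSI because they suppress the
steep 1/f^2 background that dominates the stimulus band.
"""

import numpy as np

import fbtmsi as fb
from fbtmsi.evaluation import accuracy, predict_epochs

methods = ("msi", "tmsi", "fbmsi", "fbtmsi")
sigmas = (3.0, 6.0, 9.0)
n_seeds = 3

print(f"{'sigma':>6} " + " ".join(f"{m:>7}" for m in methods) +
      f"   ({n_seeds} blocks x 40 trials each)")
for sigma in sigmas:
    accs = {m: [] for m in methods}
    for seed in range(n_seeds):
        cfg = fb.SimConfig(noise_sigma=sigma, duration=1.2, subjects=1,
                           blocks=1, seed=seed)
        epochs = fb.simulate_dataset(cfg)
        truths = np.array([e.frequency for e in epochs])
        for m in methods:
            accs[m].append(accuracy(predict_epochs(epochs, m, tw=1.0), truths))
    print(f"{sigma:6.1f} " +
          " ".join(f"{np.mean(accs[m]):7.3f}" for m in methods))
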