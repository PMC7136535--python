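"""Generate synthetic heme-O2 conformations and look at the charge structure.

Builds a small dataset with the default generator (uniform Fe-O2 binding
coordinate, Gaussian geometry jitter, 0.01 e charge noise) and prints the
per-atom charge spreads and the Fe spin-state offsets.
"""

import numpy as np

import spincharge as sc

dataset = sc.generate_dataset(sc.GeneratorParams(n_frames=500, seed=0))

charges = np.stack([t.charges for t in dataset.tables])  # (frames, 14, 3)
spread = charges.max(axis=0) - charges.min(axis=0)

print("per-atom charge spread over 500 frames (e), singlet column:")
for i in range(14):
    print(f"  {sc.ATOM_NAMES[i]:>4s}  {spread[i, 0]:.3f}")

fe = charges[:, sc.ATOM_LABELS["Fe"], :]
print(f"\nFe mean charge singlet/triplet/quintuplet: "
      f"{fe[:, 0].mean():.3f} / {fe[:, 1].mean():.3f} / {fe[:, 2].mean():.3f} e")
print("Fe spans ~1.7 e with conformation; each ligand atom ~0.5-0.7 e.")
print("The spin offsets (+0.1, +0.2 e) mirror the multi-spin charge split.")
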