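"""Spin-to-spin charge differences: where the multi-spin structure lives.

For each atom, D31 = q_triplet - q_singlet and D53 = q_quintuplet -
q_triplet are histogrammed over conformations. For Fe the distributions
concentrate at +0.1 e and +0.2 e — the systematic charge reorganization
between spin states that a single fixed-charge force field cannot express.
"""

import spincharge as sc

dataset = sc.generate_dataset(sc.GeneratorParams(n_frames=1000, seed=2))
stats = sc.spin_differences(dataset.tables, bin_width=0.02)

print("modal spin-difference per atom (e):")
print(f"  {'atom':>4s}  {'D31 mode':>8s}  {'D53 mode':>8s}")
for i in range(14):
    print(f"  {sc.ATOM_NAMES[i]:>4s}  {stats.mode_center(i, 'd31'):+8.2f}"
          f"  {stats.mode_center(i, 'd53'):+8.2f}")

fe = sc.ATOM_LABELS["Fe"]
hist = stats.histogram(fe, "d31")
peak = hist.sort_values("count", ascending=False).head(3)
print("\nFe D31 histogram, top bins:")
print(peak.to_string(index=False, float_format="%.3f"))
print("\nFe gains ~0.1 e going singlet->triplet and ~0.2 e triplet->quintuplet.")
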