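"""Train the 42-forest charge model and predict charges for a new conformation.

One random forest per (atom, spin state): 14 heavy atoms x 3 spin states.
Prediction returns the ensemble-mean charge and the tree-spread uncertainty
for every atom in all three spin states.
"""

import spincharge as sc

dataset = sc.generate_dataset(sc.GeneratorParams(n_frames=600, seed=1))
train, test = sc.split_dataset(dataset, fraction=0.5, seed=1)

spec = sc.FeaturizerSpec.symmetry_functions(dataset.structures[0].composition())
config = sc.ForestConfig(n_trees=100, m_spec=5, seed=1)
model = sc.train_all(train, spec, config)
print(f"trained {model.n_models} forests "
      f"({len(model.atom_indices)} atoms x 3 spin states)")

report = sc.evaluate_model(model, test)
print("\nheld-out performance (mean over atoms):")
print(report.per_spin.to_string(index=False, float_format="%.4f"))

frame = test.structures[0]
result = sc.predict(model, frame)
fe = sc.ATOM_LABELS["Fe"]
print(f"\nframe {frame.frame_id}, Fe predictions (charge ± tree spread, e):")
for spin in sc.SPIN_STATES:
    print(f"  {spin.label:>10s}: {result.mean(fe, spin):+.3f} "
          f"± {result.std(fe, spin):.3f}")
print("reference Fe charges:", dict(zip(
    [s.label for s in sc.SPIN_STATES],
    [round(float(q), 3) for q in test.tables[0].charges[fe]],
)))
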