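"""Featurize a conformation two ways: symmetry functions vs internal coordinates.

Symmetry functions give every atom a 19-component rotation/translation/
permutation-invariant view of its chemical environment; the internal-
coordinate scheme describes the whole conformation with 11 hand-picked
distances, angles and dihedrals.
"""

import numpy as np

import spincharge as sc

frame = sc.build_template(fe_o_distance=2.4, fe_o_o_angle=130.0)

layout = sc.build_layout(frame.composition())
print(f"symmetry-function layout: {layout.size} components")
print(f"  radial:  {layout.radial_components}")
print(f"  dropped: {layout.dropped_components}  (a single Fe has no Fe-Fe pair)")

features = sc.featurize(frame, layout)
fe_row = dict(zip(layout.component_names(), features[sc.ATOM_LABELS["Fe"]]))
print("\nFe radial components (larger = closer/more neighbors of that element):")
for name in ("radial_N", "radial_O", "radial_C", "radial_H"):
    print(f"  {name:>9s} = {fe_row[name]:.4f}")

internal = sc.internal_descriptors(frame, sc.default_internal_definition())
names = sc.default_internal_definition().component_names()
print("\n11 internal coordinates (Å / degrees):")
for name, value in zip(names, internal):
    print(f"  {name:>16s} = {value:8.3f}")

# invariance: a rigid rotation + translation changes nothing
rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
moved = sc.Structure(frame.elements, frame.coords @ rot.T + [5, -3, 2], 0)
delta = np.abs(sc.featurize(moved, layout) - features).max()
print(f"\nmax descriptor change under a rigid motion: {delta:.2e} (invariant)")
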