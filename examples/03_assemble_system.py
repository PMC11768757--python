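"""Assemble slab + polymer + ions into the periodic simulation box.

Placement rules: polymer COM 3 nm above the slab with a random in-plane
orientation (rejection-sampled so the chain clears its periodic image),
NaCl pairs from the 0.006 M nominal molarity in the ~1000 nm^3 fluid
volume, all ions at least 0.5 nm from everything, and the box extended by
15 nm in z so the chain only ever sees the one surface below it.
"""

import polysurf as ps

slab = ps.build_slab(ps.make_brucite_cell(), (20, 32, 2))
chain = ps.build_chain("HPAM", 48, seed=7)
state = ps.assemble(slab, chain, ps.PlacementRules(), seed=7)

print(f"box: {state.box[0]:.2f} x {state.box[1]:.3f} x {state.box[2]:.2f} nm")
print(f"atoms: {state.n_atoms} "
      f"(surface {int(state.mask('surface').sum())}, "
      f"polymer {int(state.mask('polymer').sum())}, "
      f"Na+ {int(state.mask('cation').sum())}, "
      f"Cl- {int(state.mask('anion').sum())})")
print(f"salt pairs from 0.006 M: {state.metadata['n_salt_pairs']}, "
      f"counterions: {state.metadata['n_counterions']}")
print(f"total charge: {state.total_charge:+.1e} e")
print(f"initial polymer-surface min distance: {ps.min_distance(state):.2f} nm")

# HPAM(48) carries -12 e, so sodium exceeds chloride by exactly 12; the
# minimum distance starts near 3 nm minus the slab-top protrusion.
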