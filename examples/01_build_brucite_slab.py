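"""Build the brucite (001) slab and verify its crystal chemistry.

Constructs the orthorhombic Mg(OH)2 unit cell, replicates it into the
20 x 32 x 2 supercell used for the adsorption study, and checks the
octahedral coordination (each Mg bonded to 6 hydroxyl oxygens, each O to
3 Mg).  The printed in-plane dimensions are what fix the simulation box.
"""

import polysurf as ps

cell = ps.make_brucite_cell()
print(f"unit cell: a={cell.a} nm, b={cell.b} nm, c={cell.c} nm, "
      f"{len(cell.sites)} sites (2 formula units)")

slab = ps.build_slab(cell, (20, 32, 2))
coord = ps.check_coordination(slab)

print(f"supercell 20x32x2: {slab.n_atoms} atoms")
print(f"in-plane box: {slab.box_xy[0]:.2f} x {slab.box_xy[1]:.3f} nm "
      f"(surface area {slab.surface_area:.2f} nm^2)")
print(f"thickness: lattice {slab.lattice_thickness:.3f} nm, "
      f"atomic {slab.atomic_thickness:.3f} nm")
print(f"coordination verified: Mg-{coord['Mg']}, O-{coord['O_hydroxyl']}")
print(f"total charge: {slab.charges.sum():+.1e} e (neutral at pH 11)")

# The box dimensions 11.08 x 10.25 match the study geometry; the surface
# area fixes how much polymer/ion material the fluid volume above holds.
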