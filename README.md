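# polysurf

Coarse-grained construction, steered Langevin dynamics, and adsorption
statistics for flocculant polymers on a brucite (001) surface.

High-molecular-weight water-soluble polymers (cellulose, guar gum,
alginate, polyacrylamide and its hydrolyzed/acrylate variants) are used as
flocculants in mineral processing: they adsorb onto suspended particles
such as brucite, Mg(OH)₂, and aggregate them into fast-settling flocs.
Whether and how a given polymer adsorbs — through hydrogen bonds, through
sodium-mediated cationic bridges, end-on ("end-grafted") or through a
central loop ("u-shaped") — controls flocculation efficiency.  `polysurf`
is a toolkit for studying exactly these questions at coarse-grained
resolution:

* **crystal** — builds the layered Mg(OH)₂ (001) slab from its
  orthorhombic unit cell, (a, b, c) = (0.5540, 0.3205, 0.4840) nm, and
  replicates it into a 20 × 32 × 2 supercell (11.08 × 10.25 nm in-plane,
  113.63 nm² surface area), validating the octahedral crystal chemistry
  (every Mg bonded to six hydroxyl oxygens, every O to three Mg).
* **polymers** — six chain builders at pH-11 protonation states:
  neutral cellulose/guar gum/PAM, fully charged alginate (−1 e per
  uronate) and PAA, and the strictly periodic 3:1 acrylamide:acrylate
  copolymer HPAM.  Default lengths are 12 monomers (polysaccharides) and
  48 (polyacrylamides), both ≈ 12 nm.
* **assembly** — places the slab at the bottom of a periodic box, the
  polymer 3 nm above it with a random in-plane orientation, Na⁺/Cl⁻ at
  0.006 M plus counterions, extends the box to 25 nm in z, and can fill
  with inert solvent sites using a 0.2 nm overlap-removal rule.
* **dynamics** — a BAOAB Langevin engine (rigid slab, mobile polymer and
  ions) executing a staged protocol: minimization → ion equilibration →
  steering with a flat-bottom restraint that plants an end-grafted or
  u-shaped pose → unrestrained release.  `plant_configuration` poses a
  chain geometrically with an exactly known contact set for validation.
* **metrics** — the analysis layer: minimum-distance approach curves,
  contact counts (polymer atoms with a surface atom within 0.5 nm),
  geometric hydrogen bonds (donor–acceptor < 0.35 nm, optional angle
  criterion), cationic bridges (Na⁺ within 0.30 nm of both a surface O
  and a polymer O), pose classification, and the Lennard-Jones/Coulomb
  split of the short-range (< 1.2 nm) polymer–surface interaction energy.
* **pipeline / CLI** — a polymers × modes × replicates run matrix with
  full per-row provenance, figure-style markdown/CSV reports, and a thin
  `polysurf` command with `build / simulate / analyze / report / matrix`
  subcommands.

## Worked example

```python
import polysurf as ps

slab  = ps.build_slab(ps.make_brucite_cell(), (20, 32, 2))
chain = ps.build_chain("HPAM", 48, seed=7)
state = ps.assemble(slab, chain, ps.PlacementRules(), seed=7)
print(state.box, state.metadata["n_salt_pairs"], ps.counterion_count(chain))
```

prints

```
[11.08  10.256 25.   ] 4 12
```

— the box is 11.08 × 10.256 × 25.00 nm (the printed construction
arithmetic), the 0.006 M salt content of the ≈ 1030 nm³ fluid volume
rounds to 4 NaCl pairs, and the −12 e HPAM 48-mer needs 12 Na⁺
counterions.  Posing the chain with exactly monomers {0, 1} touching and
measuring it:

```python
posed = ps.plant_configuration(state, "end_grafted", {0, 1})
print(ps.count_contacts(posed), ps.classify_mode(posed))
# 12 end_grafted
```

12 polymer atoms (the sites of the two planted monomers) are inside the
0.5 nm contact shell and the pose classifier labels the frame
end-grafted.  The `examples/` directory walks through each capability:
slab construction, chain composition, assembly, a steered adsorption run
with its approach curve, the full metric set on planted poses, and the
run matrix with its report.

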