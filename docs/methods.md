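# Methods

`polysurf` studies how six flocculant polymers adsorb onto the basal
(001) face of brucite, Mg(OH)₂, at coarse-grained resolution.  This note
records the model, its parameters and units, the numerical choices, and
what the synthetic trajectories do and do not show about real systems.

## The mineral slab

Brucite is a CdI₂-type layered hydroxide: sheets of edge-sharing MgO₆
octahedra with hydroxyl groups pointing out of both faces.  The builder
expresses one sheet in an orthorhombic cell — (a, b, c) =
(0.5540, 0.3205, 0.4840) nm, all angles 90°, two Mg(OH)₂ formula units —
with the Mg plane at fractional z = ½ so every replicated cell is a
complete, self-contained layer.  Fractional z-offsets of the hydroxyl O
and H about the Mg plane are 0.21 and 0.406 (O–H = 0.095 nm), chosen to
give Mg–O ≈ 0.21 nm.  Because no coordinate table is authoritative here,
correctness is enforced through coordination chemistry instead: building
a slab verifies that every Mg has exactly six hydroxyl-oxygen neighbours
and every oxygen exactly three Mg within a 0.25 nm bond cutoff (default;
covers Mg–O ≈ 0.21 nm and excludes the next shell) under in-plane
periodic images.  The check is skipped for 1-cell-wide slabs, where the
six neighbours are periodic images of fewer distinct atoms.

The 20 × 32 × 2 supercell gives 12 800 atoms, an 11.08 × 10.256 nm
in-plane box (113.64 nm²), a lattice thickness of 2c = 0.968 nm and an
atomic thickness (max z − min z) of 0.877 nm.  Both thicknesses are
reported; neither is forced to any particular value.  Partial charges are
CLAYFF-like — Mg +1.05, O −0.95, H +0.425 e — summing to zero per formula
unit; the slab is rigid in all dynamics (its internal energy is constant
and excluded from reported energies).

## Polymers

Monomers are small clusters of labelled interaction sites rather than
all-atom topologies: a backbone bead plus functional-group sites
(hydroxyl O/H, amide N/H, carbonyl O, carboxylate O, ring H, and a
carbonyl/carboxyl carbon).  Compositions and pH-11 charge states:

| polymer   | monomer(s)                   | monomers | charge  |
|-----------|------------------------------|----------|---------|
| cellulose | glucose                      | 12       | 0       |
| guar gum  | galactose + pendant mannose  | 12 (+12) | 0       |
| alginate  | mannuronate/guluronate (M-G alternation) | 12 | −12 e |
| PAM       | acrylamide                   | 48       | 0       |
| HPAM      | 3 acrylamide : 1 acrylate, strictly periodic | 48 | −12 e |
| PAA       | acrylate                     | 48       | −48 e   |

Guar gum follows the description of a galactose backbone with pendant
mannose units — the inverse of the textbook mannan-backbone/galactose-
branch structure; the ratio is configurable and the discrepancy is noted
here deliberately.

Charge choices: ring hydrogens +0.08 e (midpoint of the +0.06…+0.10 e
range typical of pyranose rings), amide/carbonyl N and O −0.7 e
(midpoint of −0.6…−0.8 e), carboxylate oxygens −0.75 e each with +0.5 e
on the carboxyl carbon so a charged monomer sums to −1 e.  Backbone
beads are neutral in the vinyl and uronate monomers: the positive
counterweight of each polar group sits on a carbon site *inside* the side
group, as in atomistic charge sets.  This matters dynamically — an early
variant with +0.7 e on the backbone row produced a spurious electrostatic
wall against the positively terminated hydroxyl surface.

Per-monomer extents are 1.0 nm (pyranose) and 0.25 nm (vinyl), so the
default 12-mers and 48-mers both start ≈ 11–12 nm long.  Hydrogens bond
to their parent heavy atom (hydroxyl O, amide N), heavy sites to the
backbone bead; every bond's rest length is its built geometry.

## Assembly

The slab rests on z = 0 of an orthorhombic box periodic in x/y and open
in z.  The fluid box is 10 nm tall, extended by 15 nm after placement so
the chain only interacts with the one surface below it (final
Lz = 25 nm).  The polymer starts linear, centre of mass 3.0 nm above the
slab top, with a uniformly random in-plane orientation rejection-sampled
until the chain clears its own periodic image by ≥ 1.2 nm.  NaCl pairs =
round(0.006 M × fluid volume) with a minimum of one pair (the printed
geometry gives ≈ 3.7 → 4), plus one Na⁺ per polymer charge; ions are
inserted uniformly at random subject to a 0.5 nm exclusion against
everything (the stricter reading of the ion-placement rule).  Solvent is
optional and inert: a point lattice standing in for a pre-equilibrated
water configuration, used to exercise the 0.2 nm overlap-removal filter;
the dynamics are implicit-solvent.

## Dynamics

Units are kJ/mol, nm, ps, e, g/mol.  The engine integrates only mobile
groups with the BAOAB Langevin splitting (temperature 300 K, friction
1 ps⁻¹, dt = 0.005 ps default); with friction 0 it reduces exactly to
velocity Verlet, which is how energy-conservation tests run.  Masses are
dynamical: hydrogen sites carry 6 g/mol (hydrogen-mass repartitioning) so
the default step sits far from the bond-vibration stability limit;
equilibrium structure is mass-independent.

Nonbonded interactions: Lennard-Jones with Lorentz–Berthelot mixing and
an explicit per-pair override hook (provided for the carboxylate-O/Na
pair, whose mixed parameters are commonly corrected; the default override
is the identity since no corrected values are authoritative here), and
**force-shifted Coulomb**, both truncated at 1.2 nm.  The force shift is
load-bearing: a plainly truncated 1/r over a layered charged slab leaves
a large artificial net field above the surface (atoms crossing the cutoff
carry discontinuous force), strong enough to stall every approach; with
the shift both potential and force go smoothly to zero at the cutoff.
The *analysis-layer* energy decomposition deliberately uses plain
truncated sums instead — it mirrors how short-range interaction energies
are conventionally reported, and its LJ/Coulomb proportions are
comparative quantities.

Exclusions: 1-2, 1-3, and all pairs within one monomer (the monomer is a
single coarse-grained cluster; bare partial charges at intra-cluster
range would otherwise form unphysically deep wells).  Bonds are harmonic
(k = 2000 kJ/mol/nm²); bending is worm-like-chain, U = k(1 + cos θ) with
k = 25 kJ/mol on consecutive backbone beads, i.e. a persistence length of
roughly k·b/kT ≈ 2.5 nm for vinyl chains and ≈ 10 nm for pyranose
chains.  Neighbour lists are Verlet lists over a KD-tree of the 3 × 3
in-plane periodic images (cutoff + 0.3 nm skin, rebuilt when any mobile
atom moves half the skin); list forces are tested against exhaustive
O(N²) evaluation.  Minimization is steepest descent with an adaptive
step, monotone in energy.

### Staged steering protocol

Mirroring how steered simulations are set up in practice: (1) energy
minimization; (2) NVT with only the environment mobile (ions here — the
implicit-solvent stand-in for the water-only and water+ion stages);
(3) NVT with a *fictitious* flat-bottom restraint pulling the anchor
monomer toward the surface — terminal monomer for the end-grafted pose,
central monomer for the u-shaped pose; (4) NVT release with all
restraints off, which is the stage all adsorption statistics are
aggregated over.  The restraint acts on the anchor monomer's centre of
mass height above the slab top: zero inside the 0.4 nm target, harmonic
with k = 1000 kJ/mol/nm² beyond it, capped at 300 kJ/mol/nm and
distributed mass-proportionally over the anchor sites (a rigid COM pull).
The cap turns the restraint into the linear-to-constant form common in MD
codes; an uncapped pull from a 2.6 nm initial excursion would exceed the
engine's per-step displacement guard.  "Contact" during steering means
the anchor's lowest atom entering the 0.5 nm contact-shell height.

At desk scale (12 × 20 × 1 slab, PAM 24-mer) the end-grafted anchor
reaches contact in fewer integrator steps than the u-shaped anchor
(medians ≈ 2400 vs ≈ 3400 over 8 seeds in bring-up runs; the acceptance
suite re-measures over 20 seeds).  The mechanism is geometric: a chain
much longer than the 3 nm descent can tilt and dip its end cheaply,
while bringing the centre down drags both arms.  The chain length must
exceed roughly twice the descent for this asymmetry to exist at all,
which is why the steering experiments use 24-mers rather than 12-mers.

`plant_configuration` bypasses dynamics entirely: it poses the chain so
exactly a chosen set of monomers lies inside the contact shell (contact
monomers at ≈ 0.24–0.36 nm above the slab top, others at 1.2 nm, the
whole chain at 3 nm for an empty set) and lifts ions clear of the
surface.  These planted frames are the ground truth the analysis layer is
validated against.

## Analysis

All cutoffs use strict `<` (the quantities are defined as "below" a
threshold).  Defaults: contacts 0.5 nm, hydrogen-bond donor–acceptor
0.35 nm, cationic bridge 0.30 nm, energy 1.2 nm.

* **Contacts** count polymer *atoms* with ≥ 1 surface atom in range (the
  bounded, stable reading of "number of interactions"); raw pair counting
  is available behind `AnalysisParams(pair_counting=True)`.
* **Hydrogen bonds** count donor–acceptor pairs in both directions
  (polymer hydroxyl/amide donors ↔ surface oxygens; surface hydroxyls ↔
  polymer oxygens).  The distance-only definition is the default; an
  H–donor–acceptor angle cutoff (30° conventionally) can be switched on,
  matching the convention of standard H-bond tools.
* **Cationic bridges** count one bridge per sodium that simultaneously
  has a surface O and a polymer O within 0.30 nm; participating triplets
  are recorded for inspection.
* **Pose classification**: desorbed (no contacting monomer), end-grafted
  (all contacting monomers within one terminal quarter of the chain —
  `terminal_fraction` = 0.25, configurable and not authoritative),
  u-shaped (all strictly interior), mixed otherwise.  Pendant guar-gum
  units map onto their host backbone position.  Changing
  `terminal_fraction` moves the end-grafted/u-shaped boundary
  proportionally; planted-pose tests pin the default's behaviour.
* **Energy decomposition**: plain truncated LJ and Coulomb sums over
  polymer × surface pairs within 1.2 nm, Lorentz–Berthelot mixing,
  proportions |E| / (|E_LJ| + |E_Coul|) (absolute-value normalisation; a
  signed alternative would change proportions only when the two terms
  have opposite sign).
* **Aggregation** restricts to release-stage frames and reports means,
  standard errors and pose proportions pooled over frames and replicates
  (both pooling axes are available; a single frame reports SE = 0 with a
  flag).

## Problem sizes and what the tests show

The shipped test and acceptance runs use desk-scale systems: quick
configurations with a 10 × 18 × 1 slab and 12-mer chains; steering
experiments with a 12 × 20 × 1 slab and 24-mers, 20 seeds per pose;
thermostat calibration on a free 12-mer over 10⁵ steps at dt = 0.002 ps
after discarding a 2 × 10⁴-step transient (the minimized start releases
contact energy that inflates early kinetic temperatures).  Full-size
runs (20 × 32 × 2 slab, 48-mers, triplicate) are the library defaults
and run unchanged, only longer.

The synthetic trajectories emulate: guided approach under steering,
contact formation and loss after release, sodium mediation near charged
groups, and the geometry of end-grafted vs u-shaped poses.  They do not
emulate: explicit water (no hydration layers, no competition for
hydrogen-bond partners), long-range electrostatics (no PME; energies are
comparative, not absolute), polymer molecular weights near 10⁶ Da,
tacticity or polydispersity.  Passing tests therefore validate the
*machinery* — construction arithmetic, counting statistics against
exhaustive references, planted-truth recovery, protocol behaviour — and
qualitative orderings, not the stochastic figure-level means of any
full-resolution study.

## Known limitations

* The coarse-grained force field is generic; its LJ table is plausible
  but not fitted, so absolute adsorption energies and bond counts should
  be read comparatively.
* The fictitious-restraint functional form (flat-bottom on the anchor COM
  height, capped) is one reasonable choice among several; pull-velocity
  protocols are not implemented.
* NVT only; no barostat.
* The engine freezes the slab; surface relaxation and protonation-state
  changes with pH are out of scope.
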