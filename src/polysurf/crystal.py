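"""Brucite (001) slab construction.

Brucite, Mg(OH)2, is a layered CdI2-type mineral: sheets of edge-sharing
MgO6 octahedra with hydroxyl groups pointing out of both faces of each
sheet.  The builder expresses one layer in an orthorhombic cell (two
formula units, a ~ sqrt(3)*b) and replicates it into the simulation
supercell.  Correctness is enforced through coordination chemistry — every
Mg must see six hydroxyl oxygens and every oxygen three Mg under the bond
cutoff with in-plane periodic images — rather than through asserted
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighbors import pairs_within

# Default lattice constants of the orthorhombic brucite cell (nm / degrees).
BRUCITE_A = 0.5540
BRUCITE_B = 0.3205
BRUCITE_C = 0.4840

# CLAYFF-style partial charges (e); sum to zero per Mg(OH)2 formula unit.
Q_MG = 1.05
Q_O = -0.95
Q_H = 0.425

# Fractional z offsets of the hydroxyl O and H about the central Mg plane.
_Z_O = 0.21
_Z_H = 0.406


@dataclass(frozen=True)
class Site:
    label: str
    frac: tuple[float, float, float]
    charge: float
    species: str  # Mg | O_hydroxyl | H_hydroxyl


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic unit cell: lengths in nm, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    sites: tuple[Site, ...] = ()

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("lattice lengths must be positive")
        if any(abs(ang - 90.0) > 1e-9 for ang in (self.alpha, self.beta, self.gamma)):
            raise ValueError("only orthorhombic cells (all angles 90) are supported")
        for s in self.sites:
            if not all(0.0 <= f < 1.0 for f in s.frac):
                raise ValueError(f"fractional coordinate out of [0,1): {s}")
        if self.sites and abs(sum(s.charge for s in self.sites)) > 1e-9:
            raise ValueError("unit cell is not charge neutral")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@dataclass
class Slab:
    """Replicated mineral slab resting on the z=0 plane."""

    box_xy: tuple[float, float]
    replication: tuple[int, int, int]
    species: np.ndarray  # (N,) str
    positions: np.ndarray  # (N, 3) nm, cartesian
    charges: np.ndarray  # (N,) e
    labels: np.ndarray  # (N,) str atom names
    lattice_thickness: float  # nz * c
    atomic_thickness: float = field(init=False)

    def __post_init__(self) -> None:
        z = self.positions[:, 2]
        self.atomic_thickness = float(z.max() - z.min())

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def top_z(self) -> float:
        """z of the highest slab atom (the hydroxyl hydrogens of the top face)."""
        return float(self.positions[:, 2].max())

    @property
    def surface_area(self) -> float:
        return self.box_xy[0] * self.box_xy[1]


def _brucite_sites() -> tuple[Site, ...]:
    """One self-contained octahedral layer, Mg plane at fractional z = 1/2.

    The hexagonal lattice points map to (0,0) and (1/2,1/2) of the
    orthorhombic cell; the two hydroxyls per formula unit sit above and
    below the Mg plane.
    """
    sites: list[Site] = []
    for dx, dy in ((0.0, 0.0), (0.5, 0.5)):
        sites.append(Site("MG", (dx, dy, 0.5), Q_MG, "Mg"))
    # hydroxyls above (+) and below (-) the Mg plane; in-plane positions are
    # the two distinct (1/3, 2/3)-type hexagonal sites mapped to ortho
    # fractions, plus the centering translation.
    for dx, dy in ((0.0, 0.0), (0.5, 0.5)):
        up_xy = ((1.0 / 3.0 + dx) % 1.0, (0.0 + dy) % 1.0)
        dn_xy = ((1.0 / 6.0 + dx) % 1.0, (0.5 + dy) % 1.0)
        sites.append(Site("OH", (up_xy[0], up_xy[1], 0.5 + _Z_O), Q_O, "O_hydroxyl"))
        sites.append(Site("HO", (up_xy[0], up_xy[1], 0.5 + _Z_H), Q_H, "H_hydroxyl"))
        sites.append(Site("OH", (dn_xy[0], dn_xy[1], 0.5 - _Z_O), Q_O, "O_hydroxyl"))
        sites.append(Site("HO", (dn_xy[0], dn_xy[1], 0.5 - _Z_H), Q_H, "H_hydroxyl"))
    return tuple(sites)


def make_brucite_cell(
    a: float = BRUCITE_A, b: float = BRUCITE_B, c: float = BRUCITE_C
) -> UnitCell:
    """The orthorhombic brucite unit cell (two Mg(OH)2 formula units)."""
    return UnitCell(a=a, b=b, c=c, sites=_brucite_sites())


def build_slab(
    cell: UnitCell,
    replication: tuple[int, int, int] = (20, 32, 2),
    bond_cutoff: float = 0.25,
    validate: bool = True,
) -> Slab:
    """Replicate ``cell`` into an (nx, ny, nz) supercell slab.

    The slab is shifted so its lowest atom sits at z = 0.  In-plane box
    lengths are (nx*a, ny*b); z is open (the slab is finite in z).

    Raises ``ValueError`` if the octahedral coordination invariants (Mg: 6
    oxygens, O: 3 magnesiums within ``bond_cutoff``) fail — that signals
    wrong fractional sites or an inappropriate cutoff.
    """
    nx, ny, nz = replication
    if min(nx, ny, nz) < 1:
        raise ValueError("replication components must be >= 1")
    if bond_cutoff <= 0:
        raise ValueError("bond_cutoff must be positive")
    if not cell.sites:
        raise ValueError("unit cell has no sites")

    frac = np.array([s.frac for s in cell.sites])
    site_charges = np.array([s.charge for s in cell.sites])
    site_species = np.array([s.species for s in cell.sites])
    site_labels = np.array([s.label for s in cell.sites])

    shifts = np.array(
        [(ix, iy, iz) for iz in range(nz) for iy in range(ny) for ix in range(nx)],
        dtype=float,
    )
    # (ncells, nsites, 3) fractional in supercell units, then cartesian
    allfrac = frac[None, :, :] + shifts[:, None, :]
    cart = allfrac.reshape(-1, 3) * cell.lengths[None, :]
    cart[:, 2] -= cart[:, 2].min()

    ncells = len(shifts)
    slab = Slab(
        box_xy=(nx * cell.a, ny * cell.b),
        replication=(nx, ny, nz),
        species=np.tile(site_species, ncells),
        positions=cart,
        charges=np.tile(site_charges, ncells),
        labels=np.tile(site_labels, ncells),
        lattice_thickness=nz * cell.c,
    )
    # in a 1-cell-wide slab the six octahedral neighbours are not distinct
    # atoms (they include periodic images of the same oxygen), so the
    # coordination check is only meaningful for nx, ny >= 2
    if validate and nx >= 2 and ny >= 2:
        check_coordination(slab, bond_cutoff)
    return slab


def check_coordination(slab: Slab, bond_cutoff: float = 0.25) -> dict[str, int]:
    """Verify Mg–O octahedral coordination; returns the counts found.

    Every Mg must have exactly 6 O_hydroxyl neighbours and every O_hydroxyl
    exactly 3 Mg neighbours within ``bond_cutoff`` under in-plane periodic
    images.  Raises ``ValueError`` on any violation.
    """
    box = np.array([slab.box_xy[0], slab.box_xy[1], 0.0])
    mg = slab.positions[slab.species == "Mg"]
    ox = slab.positions[slab.species == "O_hydroxyl"]
    i_mg, i_ox, _ = pairs_within(mg, ox, bond_cutoff, box)
    mg_coord = np.bincount(i_mg, minlength=len(mg))
    ox_coord = np.bincount(i_ox, minlength=len(ox))
    if not np.all(mg_coord == 6):
        bad = int(np.sum(mg_coord != 6))
        raise ValueError(f"coordination violation: {bad} Mg atoms without 6 O neighbours")
    if not np.all(ox_coord == 3):
        bad = int(np.sum(ox_coord != 3))
        raise ValueError(f"coordination violation: {bad} O atoms without 3 Mg neighbours")
    return {"Mg": 6, "O_hydroxyl": 3}
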