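"""The assembled simulation system: one flat container of per-atom arrays.

Groups partition the atoms: ``surface`` (the rigid slab), ``polymer``,
``cation``/``anion`` (Na+/Cl-), and optional ``solvent`` point sites.
Positions are in nm, charges in e; the box is orthorhombic with periodic
x/y and open z (the slab rests on z=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neighbors import wrap_positions

GROUPS = ("surface", "polymer", "cation", "anion", "solvent")


@dataclass
class SystemState:
    box: np.ndarray  # (3,) nm
    positions: np.ndarray  # (N, 3) nm
    species: np.ndarray  # (N,) str — LJ/mass lookup tag
    charges: np.ndarray  # (N,) e
    groups: np.ndarray  # (N,) str in GROUPS
    labels: np.ndarray  # (N,) str atom names
    roles: np.ndarray  # (N,) str functional role (polymer) or "" elsewhere
    monomer_index: np.ndarray  # (N,) int, -1 outside the polymer
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.empty(0))
    slab_top: float = 0.0  # z of the highest surface atom
    polymer_name: str = ""
    n_monomers: int = 0
    backbone_sites: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name in ("species", "charges", "groups", "labels", "roles", "monomer_index"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_atoms {n}")
        unknown = set(np.unique(self.groups)) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {unknown}")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(np.round(self.charges.sum(), 9))

    def mask(self, *groups: str) -> np.ndarray:
        return np.isin(self.groups, groups)

    def indices(self, *groups: str) -> np.ndarray:
        return np.nonzero(self.mask(*groups))[0]

    def wrapped(self) -> "SystemState":
        return replace(self, positions=wrap_positions(self.positions, self.box))

    def copy(self) -> "SystemState":
        return replace(
            self,
            positions=self.positions.copy(),
            species=self.species.copy(),
            charges=self.charges.copy(),
            groups=self.groups.copy(),
            labels=self.labels.copy(),
            roles=self.roles.copy(),
            monomer_index=self.monomer_index.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            bond_r0=self.bond_r0.copy(),
            backbone_sites=self.backbone_sites.copy(),
            metadata=dict(self.metadata),
        )

    # -- convenience selectors used throughout the analysis layer ----------

    def polymer_oxygens(self) -> np.ndarray:
        """Indices of polymer oxygen sites (any role)."""
        return np.nonzero(self.mask("polymer") & (self.species == "O"))[0]

    def surface_oxygens(self) -> np.ndarray:
        return np.nonzero(self.groups == "surface")[0][
            self.species[self.groups == "surface"] == "O_hydroxyl"
        ]

    def monomer_site_lists(self) -> dict[int, np.ndarray]:
        """Map monomer index -> site indices, polymer atoms only."""
        out: dict[int, np.ndarray] = {}
        pol = self.indices("polymer")
        for m in np.unique(self.monomer_index[pol]):
            out[int(m)] = pol[self.monomer_index[pol] == m]
        return out
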