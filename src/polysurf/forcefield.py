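"""Nonbonded and bonded interaction parameters for the coarse-grained model.

Units follow the GROMACS convention: kJ/mol, nm, ps, e, g/mol.  Cross LJ
parameters come from Lorentz–Berthelot mixing (arithmetic sigma, geometric
epsilon) with an explicit per-pair override hook; the override exists
chiefly for the carboxylate-oxygen/sodium pair, whose mixed parameters are
known to over-bind in standard force fields and are commonly corrected.
Electrostatics are plain cutoff Coulomb with the potential shifted to zero
at the cutoff (forces are unaffected by the shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458
# Boltzmann constant in kJ mol^-1 K^-1
KB = 0.00831446262

# (epsilon kJ/mol, sigma nm) per species tag.  Generic coarse-grained
# values in the range of common biomolecular force fields.
DEFAULT_LJ: dict[str, tuple[float, float]] = {
    "Mg": (0.10, 0.210),
    "O_hydroxyl": (0.65, 0.316),
    "H_hydroxyl": (0.15, 0.158),
    "C": (0.35, 0.350),
    "O": (0.65, 0.300),
    "N": (0.70, 0.325),
    "H": (0.15, 0.158),
    "Na": (0.45, 0.233),
    "Cl": (0.42, 0.440),
    "W": (0.65, 0.315),  # inert solvent site
}

# Dynamical masses (g/mol).  Hydrogen-site masses are repartitioned upward
# (as in hydrogen-mass-repartitioned MD) so the 0.01 ps coarse-grained step
# stays far from the bond-vibration stability limit; equilibrium structure
# and sampled distributions are mass-independent.
DEFAULT_MASS: dict[str, float] = {
    "Mg": 24.3,
    "O_hydroxyl": 16.0,
    "H_hydroxyl": 6.0,
    "C": 40.0,  # backbone bead carries the unresolved ring/chain mass
    "O": 16.0,
    "N": 14.0,
    "H": 6.0,
    "Na": 23.0,
    "Cl": 35.5,
    "W": 18.0,
}


@dataclass
class ForceFieldParams:
    """Interaction table for the coarse-grained engine.

    ``pair_overrides`` maps a frozenset-like sorted species pair, e.g.
    ``("Na", "O")``, to an explicit (epsilon, sigma).  The default table
    contains an identity entry for the carboxylate-O/Na pair as the
    documented correction hook.
    """

    lj: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_LJ))
    masses: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MASS))
    pair_overrides: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    cutoff: float = 1.2  # nm, shared by LJ and Coulomb
    coulomb_constant: float = COULOMB_CONSTANT
    bond_k: float = 2000.0  # kJ/mol/nm^2
    angle_k: float = 25.0  # kJ/mol (worm-like-chain bending stiffness)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for pair in self.pair_overrides:
            for sp in pair:
                if sp not in self.lj:
                    raise ValueError(f"pair override for undeclared species {sp!r}")

    def mixed(self, s1: str, s2: str) -> tuple[float, float]:
        """(epsilon, sigma) for a species pair: LB mixing unless overridden."""
        key = tuple(sorted((s1, s2)))
        if key in self.pair_overrides:
            return self.pair_overrides[key]
        e1, g1 = self.lj[s1]
        e2, g2 = self.lj[s2]
        return float(np.sqrt(e1 * e2)), 0.5 * (g1 + g2)

    def tables_for(self, species: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-atom type index plus (ntypes, ntypes) epsilon/sigma tables."""
        uniq, type_index = np.unique(np.asarray(species), return_inverse=True)
        n = len(uniq)
        eps = np.zeros((n, n))
        sig = np.zeros((n, n))
        for i, si in enumerate(uniq):
            for j, sj in enumerate(uniq):
                eps[i, j], sig[i, j] = self.mixed(si, sj)
        return type_index.astype(int), eps, sig

    def mass_array(self, species: np.ndarray) -> np.ndarray:
        return np.array([self.masses[s] for s in species])


def coo_na_override(epsilon: float, sigma: float) -> dict[tuple[str, str], tuple[float, float]]:
    """Convenience builder for the carboxylate-oxygen/sodium pair correction."""
    return {tuple(sorted(("Na", "O"))): (epsilon, sigma)}
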