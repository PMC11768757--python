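import numpy as np
import pytest

import polysurf as ps
from polysurf.pipeline import RunConfig, build_system


@pytest.fixture(scope="session")
def brucite_cell():
    return ps.make_brucite_cell()


@pytest.fixture(scope="session")
def small_slab(brucite_cell):
    """2x2x1 slab: smallest size on which coordination invariants hold."""
    return ps.build_slab(brucite_cell, (2, 2, 1))


@pytest.fixture(scope="session")
def quick_config():
    return RunConfig.quick()


@pytest.fixture(scope="session")
def quick_system(quick_config):
    """Assembled desk-scale system: 6x10x1 slab + PAM 12-mer + ions."""
    return build_system(quick_config, "PAM", seed=11)


@pytest.fixture(scope="session")
def charged_system(quick_config):
    """Same but with a charged polymer (HPAM), so counterions exist."""
    return build_system(quick_config, "HPAM", seed=12)


def random_chemical_frame(rng: np.random.Generator, n_atoms: int = 200):
    """Random periodic frame with real donor/acceptor structure.

    Surface hydroxyls are O-H pairs in builder order (H immediately after
    its O); polymer monomers are clusters carrying a hydroxyl (O-H bond),
    an amide (N-H bond) and a carbonyl O.  Returns ``(state, known)`` where
    ``known`` records the donor pairs and acceptor sets laid down at
    construction, for independent brute-force hydrogen-bond counting.
    """
    box = np.array([5.0, 4.0, 12.0])
    positions, species, groups, roles, labels, mono, charges = [], [], [], [], [], [], []
    bonds = []
    known = {"donor_pairs_surface": [], "donor_pairs_polymer": []}

    n_oh = max(4, (n_atoms // 2) // 2)
    n_mg = max(2, n_atoms // 10)
    for _ in range(n_oh):
        o = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]), rng.uniform(0, 0.5)])
        direction = rng.normal(size=3)
        h = o + 0.098 * direction / np.linalg.norm(direction)
        known["donor_pairs_surface"].append((len(positions), len(positions) + 1))
        positions += [o, h]
        species += ["O_hydroxyl", "H_hydroxyl"]
        groups += ["surface", "surface"]
        roles += ["", ""]
        labels += ["OH", "HO"]
        mono += [-1, -1]
        charges += [-0.95, 0.425]
    for _ in range(n_mg):
        positions.append(
            np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]), rng.uniform(0, 0.4)])
        )
        species.append("Mg")
        groups.append("surface")
        roles.append("")
        labels.append("MG")
        mono.append(-1)
        charges.append(1.05)

    n_mono = max(2, (n_atoms - len(positions) - 6) // 7)
    for m in range(n_mono):
        c = np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]), rng.uniform(0.1, 2.2)])
        bead = len(positions)
        site_specs = [
            ("C", "backbone", 0.0, np.zeros(3)),
            ("O", "hydroxyl_O", -0.48, rng.normal(0, 0.12, 3)),
            ("H", "hydroxyl_H", 0.40, None),  # bonded to the hydroxyl O
            ("N", "amide_N", -0.70, rng.normal(0, 0.12, 3)),
            ("H", "amide_H", 0.35, None),  # bonded to the amide N
            ("O", "carbonyl_O", -0.70, rng.normal(0, 0.12, 3)),
        ]
        parent = bead
        for elem, role, q, off in site_specs:
            idx = len(positions)
            if off is None:
                direction = rng.normal(size=3)
                positions.append(positions[parent] + 0.1 * direction / np.linalg.norm(direction))
                bonds.append((parent, idx))
                key = "donor_pairs_polymer"
                known[key].append((parent, idx))
            else:
                positions.append(c + off)
                if idx != bead:
                    bonds.append((bead, idx))
                parent = idx
            species.append(elem)
            groups.append("polymer")
            roles.append(role)
            labels.append(elem)
            mono.append(m)
            charges.append(q)

    for sp, q in (("Na", 1.0), ("Na", 1.0), ("Na", 1.0), ("Cl", -1.0), ("Cl", -1.0)):
        positions.append(
            np.array([rng.uniform(0, box[0]), rng.uniform(0, box[1]), rng.uniform(0.1, 2.5)])
        )
        species.append(sp)
        groups.append("cation" if sp == "Na" else "anion")
        roles.append("")
        labels.append(sp.upper())
        mono.append(-1)
        charges.append(q)

    positions = np.array(positions)
    bonds_arr = np.array(bonds, dtype=int).reshape(-1, 2)
    state = ps.SystemState(
        box=box,
        positions=positions,
        species=np.array(species),
        charges=np.array(charges),
        groups=np.array(groups),
        labels=np.array(labels),
        roles=np.array(roles),
        monomer_index=np.array(mono),
        bonds=bonds_arr,
        bond_r0=np.linalg.norm(
            positions[bonds_arr[:, 1]] - positions[bonds_arr[:, 0]], axis=1
        ) if len(bonds_arr) else np.empty(0),
        slab_top=0.6,
        polymer_name="random",
        n_monomers=n_mono,
    )
    return state, known


def random_frame(rng: np.random.Generator, n_atoms: int = 80):
    """A random periodic frame with surface/polymer/ion groups, for oracle
    comparisons.  Positions are scattered through the box so every metric
    sees contacts at a range of distances."""
    box = np.array([4.0, 3.5, 10.0])
    n_surf = n_atoms // 2
    n_pol = n_atoms - n_surf - 6
    n_na, n_cl = 4, 2
    groups = np.array(
        ["surface"] * n_surf + ["polymer"] * n_pol + ["cation"] * n_na + ["anion"] * n_cl
    )
    species = np.empty(len(groups), dtype=object)
    roles = np.array([""] * len(groups), dtype=object)
    mono = np.full(len(groups), -1)
    surf_species = rng.choice(["Mg", "O_hydroxyl", "H_hydroxyl"], size=n_surf)
    species[:n_surf] = surf_species
    pol_species = rng.choice(["C", "O", "N", "H"], size=n_pol)
    species[n_surf : n_surf + n_pol] = pol_species
    roles[n_surf : n_surf + n_pol] = [
        {"C": "backbone", "O": "carbonyl_O", "N": "amide_N", "H": "ring_H"}[s]
        for s in pol_species
    ]
    mono[n_surf : n_surf + n_pol] = np.arange(n_pol) // 4
    species[n_surf + n_pol :] = ["Na"] * n_na + ["Cl"] * n_cl
    positions = np.empty((len(groups), 3))
    positions[:, 0] = rng.uniform(0, box[0], len(groups))
    positions[:, 1] = rng.uniform(0, box[1], len(groups))
    positions[:n_surf, 2] = rng.uniform(0.0, 0.5, n_surf)
    positions[n_surf:, 2] = rng.uniform(0.2, 2.0, len(groups) - n_surf)
    charges = rng.normal(0, 0.4, len(groups))
    charges[n_surf + n_pol :] = [1.0] * n_na + [-1.0] * n_cl
    n_mono = int(mono[n_surf : n_surf + n_pol].max()) + 1
    return ps.SystemState(
        box=box,
        positions=positions,
        species=species.astype(str),
        charges=charges,
        groups=groups,
        labels=species.astype(str),
        roles=roles.astype(str),
        monomer_index=mono,
        slab_top=0.5,
        polymer_name="random",
        n_monomers=n_mono,
    )
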