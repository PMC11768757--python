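"""Assembly of slab + polymer + ions (+ optional solvent sites) into a box.

Placement follows fixed rules: the slab rests on the bottom xy-plane; the
polymer starts linear, with a uniformly random in-plane orientation chosen
by rejection so the chain stays clear of its own periodic image, and its
centre of mass 3 nm above the slab top; Na+/Cl- ions are placed uniformly
at random in the fluid region subject to a pairwise exclusion distance;
the box is finally extended upward in z so the polymer only ever sees the
one surface below it.  Ion counts come from the nominal NaCl molarity times
the fluid volume, plus one Na+ counterion per polymer charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AVOGADRO_PER_NM3 = 0.602214076  # (mol/L)^-1 nm^-3: ions per nm^3 per molar

from .crystal import Slab
from .neighbors import distance_matrix, min_cross_distance, wrap_positions
from .polymers import PolymerChain, counterion_count
from .system import SystemState


class PlacementError(RuntimeError):
    """Raised when random insertion cannot satisfy the exclusion rules."""


@dataclass(frozen=True)
class PlacementRules:
    polymer_com_height: float = 3.0  # nm above the slab top
    ion_exclusion: float = 0.5  # nm, ion to any other compound
    solvent_removal: float = 0.2  # nm
    z_extension: float = 15.0  # nm added above the fluid box
    nacl_molar: float = 0.006  # mol/L
    base_height: float = 10.0  # nm, fluid box height before extension
    self_image_clearance: float = 1.2  # nm, chain to its periodic image
    salt_rounding: str = "nearest"  # nearest | floor | ceil

    def __post_init__(self) -> None:
        for f in (
            "polymer_com_height",
            "ion_exclusion",
            "solvent_removal",
            "z_extension",
            "base_height",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def salt_pairs(rules: PlacementRules, fluid_volume: float) -> int:
    """NaCl pair count from molarity and fluid volume (nm^3); at least 1."""
    x = rules.nacl_molar * fluid_volume * AVOGADRO_PER_NM3
    if rules.salt_rounding == "floor":
        n = int(np.floor(x))
    elif rules.salt_rounding == "ceil":
        n = int(np.ceil(x))
    else:
        n = int(round(x))
    return max(n, 1)


def _orient_chain(
    chain_pos: np.ndarray,
    com_target: np.ndarray,
    box: np.ndarray,
    clearance: float,
    rng: np.random.Generator,
    max_attempts: int = 500,
) -> np.ndarray:
    """Rotate the chain about z and centre it; reject orientations whose
    minimum-image distance to their own periodic copy is below ``clearance``."""
    com = chain_pos.mean(axis=0)
    centred = chain_pos - com
    for _ in range(max_attempts):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pos = centred @ rot.T + com_target
        ok = True
        for gx in (-1, 0, 1):
            for gy in (-1, 0, 1):
                if gx == 0 and gy == 0:
                    continue
                shift = np.array([gx * box[0], gy * box[1], 0.0])
                # plain (unwrapped) distance to the explicitly shifted copy
                d = pos[:, None, :] - (pos + shift)[None, :, :]
                if float(np.sqrt((d**2).sum(axis=2)).min()) < clearance:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return pos
    raise PlacementError(
        f"no chain orientation clears {clearance} nm from its periodic image"
    )


def assemble(
    slab: Slab,
    chain: PolymerChain,
    rules: PlacementRules | None = None,
    seed: int = 0,
) -> SystemState:
    """Build the full periodic system from its parts.

    Returns a charge-neutral :class:`SystemState` with box
    (nx*a, ny*b, base_height + z_extension).
    """
    rules = rules or PlacementRules()
    rng = np.random.default_rng(seed)
    box = np.array(
        [slab.box_xy[0], slab.box_xy[1], rules.base_height + rules.z_extension]
    )
    fluid_volume = slab.surface_area * (rules.base_height - slab.atomic_thickness)

    # --- polymer -----------------------------------------------------------
    com_target = np.array(
        [box[0] / 2.0, box[1] / 2.0, slab.top_z + rules.polymer_com_height]
    )
    pol_pos = _orient_chain(
        chain.positions, com_target, box, rules.self_image_clearance, rng
    )

    # --- ions --------------------------------------------------------------
    n_salt = salt_pairs(rules, fluid_volume)
    n_counter = counterion_count(chain)
    n_na, n_cl = n_salt + n_counter, n_salt

    placed: list[np.ndarray] = []
    z_lo = slab.top_z + max(rules.ion_exclusion, 0.3)
    z_hi = rules.base_height - 0.3
    obstacles = pol_pos
    for _ in range(n_na + n_cl):
        for attempt in range(2000):
            cand = np.array(
                [
                    rng.uniform(0.0, box[0]),
                    rng.uniform(0.0, box[1]),
                    rng.uniform(z_lo, z_hi),
                ]
            )
            others = obstacles if not placed else np.vstack([obstacles, *placed])
            if min_cross_distance(cand, others, box) >= rules.ion_exclusion:
                placed.append(cand)
                break
        else:
            raise PlacementError("ion placement failed: box too crowded")
    ion_pos = np.array(placed).reshape(-1, 3)

    # --- concatenate per-atom arrays --------------------------------------
    n_slab, n_pol = slab.n_atoms, chain.n_sites
    positions = np.vstack([slab.positions, pol_pos, ion_pos])
    species = np.concatenate(
        [slab.species, chain.elements, ["Na"] * n_na, ["Cl"] * n_cl]
    )
    charges = np.concatenate(
        [slab.charges, chain.charges, [1.0] * n_na, [-1.0] * n_cl]
    )
    groups = np.concatenate(
        [
            ["surface"] * n_slab,
            ["polymer"] * n_pol,
            ["cation"] * n_na,
            ["anion"] * n_cl,
        ]
    )
    labels = np.concatenate(
        [slab.labels, chain.labels, ["NA"] * n_na, ["CL"] * n_cl]
    )
    roles = np.concatenate(
        [[""] * n_slab, chain.roles, [""] * (n_na + n_cl)]
    )
    monomer_index = np.concatenate(
        [
            np.full(n_slab, -1, dtype=int),
            chain.monomer_index,
            np.full(n_na + n_cl, -1, dtype=int),
        ]
    )

    bonds = chain.bonds + n_slab
    backbone = chain.backbone_sites + n_slab
    bond_vec = positions[bonds[:, 1]] - positions[bonds[:, 0]]
    bond_r0 = np.sqrt((bond_vec**2).sum(axis=1))
    angles = np.array(
        [
            (backbone[i - 1], backbone[i], backbone[i + 1])
            for i in range(1, len(backbone) - 1)
        ],
        dtype=int,
    ).reshape(-1, 3)

    state = SystemState(
        box=box,
        positions=wrap_positions(positions, box),
        species=species,
        charges=charges,
        groups=groups,
        labels=labels,
        roles=roles,
        monomer_index=monomer_index,
        bonds=bonds,
        angles=angles,
        bond_r0=bond_r0,
        slab_top=slab.top_z,
        polymer_name=chain.name,
        n_monomers=chain.n_monomers,
        backbone_sites=backbone,
        metadata={
            "seed": seed,
            "n_salt_pairs": n_salt,
            "n_counterions": n_counter,
            "fluid_volume": fluid_volume,
        },
    )
    if abs(state.total_charge) > 1e-6:
        raise PlacementError(
            f"charge-balance failure: total charge {state.total_charge} e"
        )
    return state


def lattice_template(
    box: np.ndarray, z_range: tuple[float, float], spacing: float = 0.31
) -> np.ndarray:
    """Cubic point lattice filling the in-plane box between two z planes.

    Stands in for a pre-equilibrated solvent configuration; the sites are
    inert markers used to exercise the overlap-removal filter.
    """
    xs = np.arange(spacing / 2, box[0], spacing)
    ys = np.arange(spacing / 2, box[1], spacing)
    zs = np.arange(z_range[0], z_range[1], spacing)
    grid = np.array(np.meshgrid(xs, ys, zs, indexing="ij")).reshape(3, -1).T
    return grid


def solvent_fill(
    state: SystemState,
    template: np.ndarray,
    removal_cutoff: float = 0.2,
) -> tuple[SystemState, int, int]:
    """Insert solvent sites from ``template``, deleting overlapping ones.

    A template site is removed when it lies strictly within
    ``removal_cutoff`` of any existing (non-solvent) atom.  Returns
    ``(new_state, n_removed, n_retained)``.
    """
    if removal_cutoff < 0:
        raise ValueError("removal_cutoff must be >= 0")
    template = np.asarray(template, dtype=float).reshape(-1, 3)
    solute = state.positions[state.groups != "solvent"]
    if len(solute) == 0 or len(template) == 0 or removal_cutoff == 0.0:
        keep = np.ones(len(template), dtype=bool)
    else:
        keep = np.ones(len(template), dtype=bool)
        # chunked brute-force scan keeps memory bounded on large templates
        for start in range(0, len(template), 2000):
            blk = template[start : start + 2000]
            dm = distance_matrix(blk, solute, state.box)
            keep[start : start + 2000] = dm.min(axis=1) >= removal_cutoff
    kept = template[keep]
    n = len(kept)
    new = state.copy()
    new.positions = np.vstack([state.positions, wrap_positions(kept, state.box)])
    new.species = np.concatenate([state.species, ["W"] * n])
    new.charges = np.concatenate([state.charges, np.zeros(n)])
    new.groups = np.concatenate([state.groups, ["solvent"] * n])
    new.labels = np.concatenate([state.labels, ["W"] * n])
    new.roles = np.concatenate([state.roles, [""] * n])
    new.monomer_index = np.concatenate(
        [state.monomer_index, np.full(n, -1, dtype=int)]
    )
    return new, int(np.sum(~keep)), n
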