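"""Coarse-grained, atom-labelled polymer chains.

Six flocculant polymers are supported, three polysaccharides (cellulose,
guar gum, alginate) and three polyacrylamides (PAM, HPAM, PAA).  Each
monomer is a small cluster of labelled interaction sites — a backbone bead
plus functional-group sites (hydroxyl O/H, amide N/H, carbonyl O,
carboxylate O, ring H) — carrying partial charges chosen so each monomer
sums to its formal charge at pH 11: 0 for glucose/galactose/mannose/
acrylamide units, -1 e for mannuronate/guluronate/acrylate units.

Default chain lengths are 12 monomers for polysaccharides and 48 for
polyacrylamides; with per-monomer extents of 1.0 nm (pyranose) and 0.25 nm
(vinyl) both families start at a comparable ~12 nm linear length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

POLYMER_NAMES = ("cellulose", "guar_gum", "alginate", "PAM", "HPAM", "PAA")
POLYSACCHARIDES = ("cellulose", "guar_gum", "alginate")
POLYACRYLAMIDES = ("PAM", "HPAM", "PAA")

# per-monomer backbone spacing (nm)
PYRANOSE_EXTENT = 1.0
VINYL_EXTENT = 0.25

# lateral offset of functional-group sites from the backbone bead (nm)
_SIDE = 0.15

DEFAULT_N_MONOMERS = {name: 12 for name in POLYSACCHARIDES}
DEFAULT_N_MONOMERS.update({name: 48 for name in POLYACRYLAMIDES})


@dataclass(frozen=True)
class SiteSpec:
    label: str
    element: str
    charge: float
    role: str  # backbone | hydroxyl_O | hydroxyl_H | amide_N | amide_H |
    #            carbonyl_O | carboxylate_O | ring_H | other
    offset: tuple[float, float, float]  # nm, relative to the backbone bead


@dataclass(frozen=True)
class MonomerSpec:
    name: str
    formal_charge: int
    extent: float  # nm along the backbone
    sites: tuple[SiteSpec, ...]
    branch: bool = False  # pendant unit hanging off a backbone monomer

    def __post_init__(self) -> None:
        total = sum(s.charge for s in self.sites)
        if abs(total - self.formal_charge) > 1e-9:
            raise ValueError(
                f"{self.name}: site charges sum to {total}, "
                f"expected formal charge {self.formal_charge}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _pyranose(name: str) -> MonomerSpec:
    """Neutral sugar unit: ring bead, one representative hydroxyl, two ring H."""
    return MonomerSpec(
        name=name,
        formal_charge=0,
        extent=PYRANOSE_EXTENT,
        sites=(
            SiteSpec("C1", "C", -0.08, "backbone", (0.0, 0.0, 0.0)),
            SiteSpec("O2", "O", -0.48, "hydroxyl_O", (0.0, _SIDE, 0.0)),
            SiteSpec("H2", "H", 0.40, "hydroxyl_H", (0.0, _SIDE + 0.095, 0.0)),
            SiteSpec("H3", "H", 0.08, "ring_H", (0.0, -_SIDE, 0.05)),
            SiteSpec("H4", "H", 0.08, "ring_H", (0.0, -_SIDE, -0.05)),
        ),
    )


def _uronate(name: str) -> MonomerSpec:
    """Charged sugar unit (mannuronate/guluronate): COO- plus hydroxyl.

    The backbone ring bead is neutral; the positive counterweight of the
    carboxylate sits on the carboxyl carbon inside the side group, keeping
    the charged moiety a compact local multipole.
    """
    return MonomerSpec(
        name=name,
        formal_charge=-1,
        extent=PYRANOSE_EXTENT,
        sites=(
            SiteSpec("C1", "C", 0.0, "backbone", (0.0, 0.0, 0.0)),
            SiteSpec("CC", "C", 0.50, "other", (0.0, 0.10, 0.0)),
            SiteSpec("OC1", "O", -0.75, "carboxylate_O", (0.06, _SIDE + 0.05, 0.0)),
            SiteSpec("OC2", "O", -0.75, "carboxylate_O", (-0.06, _SIDE + 0.05, 0.0)),
            SiteSpec("O2", "O", -0.48, "hydroxyl_O", (0.0, -_SIDE, 0.0)),
            SiteSpec("H2", "H", 0.40, "hydroxyl_H", (0.0, -_SIDE - 0.095, 0.0)),
            SiteSpec("H3", "H", 0.08, "ring_H", (0.05, 0.0, 0.08)),
        ),
    )


def _acrylamide() -> MonomerSpec:
    """Amide dipole lives entirely in the side group; the vinyl backbone
    bead is neutral, as in atomistic acrylamide charge sets."""
    return MonomerSpec(
        name="acrylamide",
        formal_charge=0,
        extent=VINYL_EXTENT,
        sites=(
            SiteSpec("C1", "C", 0.0, "backbone", (0.0, 0.0, 0.0)),
            SiteSpec("CC", "C", 0.70, "other", (0.0, 0.10, 0.0)),
            SiteSpec("OC", "O", -0.70, "carbonyl_O", (0.08, _SIDE + 0.05, 0.0)),
            SiteSpec("N1", "N", -0.70, "amide_N", (-0.08, _SIDE + 0.05, 0.0)),
            SiteSpec("HN1", "H", 0.35, "amide_H", (-0.13, _SIDE + 0.13, 0.05)),
            SiteSpec("HN2", "H", 0.35, "amide_H", (-0.13, _SIDE + 0.13, -0.05)),
        ),
    )


def _acrylate() -> MonomerSpec:
    return MonomerSpec(
        name="acrylate",
        formal_charge=-1,
        extent=VINYL_EXTENT,
        sites=(
            SiteSpec("C1", "C", 0.0, "backbone", (0.0, 0.0, 0.0)),
            SiteSpec("CC", "C", 0.50, "other", (0.0, 0.10, 0.0)),
            SiteSpec("OC1", "O", -0.75, "carboxylate_O", (0.06, _SIDE + 0.05, 0.0)),
            SiteSpec("OC2", "O", -0.75, "carboxylate_O", (-0.06, _SIDE + 0.05, 0.0)),
        ),
    )


def _mannose_branch() -> MonomerSpec:
    spec = _pyranose("mannose")
    return MonomerSpec(
        name="mannose",
        formal_charge=0,
        extent=spec.extent,
        sites=spec.sites,
        branch=True,
    )


def monomer_sequence(name: str, n_monomers: int) -> list[MonomerSpec]:
    """The ordered monomer sequence for a chain of ``n_monomers`` units.

    ``n_monomers`` counts backbone units; guar gum additionally hangs one
    pendant mannose off every backbone galactose (the pendant units are
    appended with ``branch=True`` and do not count toward ``n_monomers``).
    """
    if name == "cellulose":
        return [_pyranose("glucose") for _ in range(n_monomers)]
    if name == "guar_gum":
        seq = [_pyranose("galactose") for _ in range(n_monomers)]
        seq += [_mannose_branch() for _ in range(n_monomers)]
        return seq
    if name == "alginate":
        # strict M-G alternation
        units = ["mannuronate", "guluronate"]
        return [_uronate(units[i % 2]) for i in range(n_monomers)]
    if name == "PAM":
        return [_acrylamide() for _ in range(n_monomers)]
    if name == "HPAM":
        if n_monomers % 4 != 0:
            raise ValueError("HPAM length must be divisible by 4 (3:1 amide:acrylate)")
        seq: list[MonomerSpec] = []
        for i in range(n_monomers):
            # strictly periodic: three acrylamide then one acrylate
            seq.append(_acrylate() if i % 4 == 3 else _acrylamide())
        return seq
    if name == "PAA":
        return [_acrylate() for _ in range(n_monomers)]
    raise ValueError(f"unknown polymer name: {name!r} (choose from {POLYMER_NAMES})")


@dataclass
class PolymerChain:
    """A built chain: site arrays plus bond topology.

    ``monomer_index`` maps every site to its monomer; backbone monomers are
    numbered 0..n_monomers-1 in chain order, pendant (branch) monomers
    continue the numbering after the backbone.
    """

    name: str
    n_monomers: int
    monomers: list[MonomerSpec]
    positions: np.ndarray  # (N, 3) nm
    labels: np.ndarray  # (N,) str
    elements: np.ndarray  # (N,) str
    charges: np.ndarray  # (N,) e
    roles: np.ndarray  # (N,) str
    monomer_index: np.ndarray  # (N,) int
    bonds: np.ndarray  # (nb, 2) int site-index pairs
    backbone_sites: np.ndarray  # (n_backbone_monomers,) site index of each backbone bead
    branch_bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def net_charge(self) -> float:
        return float(np.round(self.charges.sum(), 9))

    @property
    def linear_extent(self) -> float:
        bb = self.positions[self.backbone_sites]
        return float(np.linalg.norm(bb[-1] - bb[0]))


def build_chain(name: str, n_monomers: int | None = None, seed: int = 0) -> PolymerChain:
    """Build an initially linear chain lying along +x starting at the origin.

    Deterministic given ``seed`` (the seed currently only fixes tiny site
    jitter used to break exact collinearity degeneracies in the dynamics
    engine; geometry is otherwise analytic).
    """
    if name not in POLYMER_NAMES:
        raise ValueError(f"unknown polymer name: {name!r} (choose from {POLYMER_NAMES})")
    if n_monomers is None:
        n_monomers = DEFAULT_N_MONOMERS[name]
    if n_monomers < 2:
        raise ValueError("a chain needs at least 2 monomers")
    seq = monomer_sequence(name, n_monomers)
    rng = np.random.default_rng(seed)

    positions: list[np.ndarray] = []
    labels: list[str] = []
    elements: list[str] = []
    charges: list[float] = []
    roles: list[str] = []
    monomer_index: list[int] = []
    bonds: list[tuple[int, int]] = []
    branch_bonds: list[tuple[int, int]] = []
    backbone_sites: list[int] = []

    backbone = [m for m in seq if not m.branch]
    branches = [m for m in seq if m.branch]

    # hydrogens bond to their parent heavy atom (the nearest preceding site
    # with the matching role), everything else to the backbone bead; keeping
    # charged hydrogens tethered to a heavy atom with a real LJ core is what
    # prevents bare-charge collapse onto oxygens of other monomers
    parent_role = {"hydroxyl_H": "hydroxyl_O", "amide_H": "amide_N"}

    def add_monomer(mono: MonomerSpec, m_idx: int, origin: np.ndarray, flip: float) -> int:
        """Append one monomer's sites; returns the backbone-bead site index."""
        first = len(positions)
        for k, s in enumerate(mono.sites):
            off = np.array(s.offset)
            off[1] *= flip
            pos = origin + off + rng.normal(0.0, 1e-4, 3)
            positions.append(pos)
            labels.append(s.label)
            elements.append(s.element)
            charges.append(s.charge)
            roles.append(s.role)
            monomer_index.append(m_idx)
            if k == 0:
                continue
            want = parent_role.get(s.role)
            partner = first
            if want is not None:
                for back in range(k - 1, -1, -1):
                    if mono.sites[back].role == want:
                        partner = first + back
                        break
            bonds.append((partner, first + k))
        return first

    x = 0.0
    for i, mono in enumerate(backbone):
        # alternate side-group orientation along the chain
        bead = add_monomer(mono, i, np.array([x, 0.0, 0.0]), 1.0 if i % 2 == 0 else -1.0)
        backbone_sites.append(bead)
        if i > 0:
            bonds.append((backbone_sites[i - 1], bead))
        x += mono.extent

    nb = len(backbone)
    for j, mono in enumerate(branches):
        host_bead = backbone_sites[j % nb]
        origin = positions[host_bead] + np.array([0.0, 0.0, 0.45])
        bead = add_monomer(mono, nb + j, origin, 1.0)
        bonds.append((host_bead, bead))
        branch_bonds.append((host_bead, bead))

    chain = PolymerChain(
        name=name,
        n_monomers=n_monomers,
        monomers=seq,
        positions=np.asarray(positions),
        labels=np.asarray(labels),
        elements=np.asarray(elements),
        charges=np.asarray(charges),
        roles=np.asarray(roles),
        monomer_index=np.asarray(monomer_index, dtype=int),
        bonds=np.asarray(bonds, dtype=int),
        backbone_sites=np.asarray(backbone_sites, dtype=int),
        branch_bonds=np.asarray(branch_bonds, dtype=int).reshape(-1, 2),
    )
    return chain


def counterion_count(chain: PolymerChain) -> int:
    """Sodium counterions required to neutralise the chain."""
    return int(round(abs(chain.net_charge)))
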