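"""Per-frame adsorption statistics and their per-run aggregation.

Five families of measurements characterise how a polymer binds the
hydroxylated mineral surface:

* minimum polymer–surface distance over time (the approach curve),
* contact counts — polymer atoms with at least one surface atom inside
  the 0.5 nm contact shell,
* geometric hydrogen bonds — polymer/surface donor–acceptor pairs closer
  than 0.35 nm, optionally filtered by an H–donor–acceptor angle,
* cationic bridges — a sodium ion simultaneously within 0.30 nm of a
  surface oxygen and a polymer oxygen,
* the short-range interaction energy split into Lennard-Jones and
  Coulomb parts within the 1.2 nm cutoff.

Every cutoff uses a strict ``<`` at the boundary.  Adsorption poses are
classified per frame from which monomers hold contacts: ``end_grafted``
when all contacting monomers fall in one terminal quarter of the chain,
``u_shaped`` when they are all strictly interior, ``mixed`` otherwise,
``desorbed`` when nothing touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield import ForceFieldParams
from .neighbors import min_cross_distance, pairs_within
from .system import SystemState
from .dynamics import Trajectory

MODES = ("end_grafted", "u_shaped", "mixed", "desorbed")

# donor heavy-atom roles paired with the hydrogens they carry
_DONOR_ROLES = {
    "hydroxyl_O": "hydroxyl_H",
    "amide_N": "amide_H",
}
_ACCEPTOR_ROLES = ("hydroxyl_O", "carbonyl_O", "carboxylate_O")


@dataclass(frozen=True)
class AnalysisParams:
    contact_cutoff: float = 0.5  # nm
    hbond_da_cutoff: float = 0.35  # nm
    bridge_cutoff: float = 0.30  # nm
    energy_cutoff: float = 1.2  # nm
    hbond_angle_cutoff: float | None = None  # degrees; None = distance-only
    terminal_fraction: float = 0.25
    pair_counting: bool = False  # count atom pairs instead of polymer atoms

    def __post_init__(self) -> None:
        for f in ("contact_cutoff", "hbond_da_cutoff", "bridge_cutoff", "energy_cutoff"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 < self.terminal_fraction < 0.5:
            raise ValueError("terminal_fraction must lie in (0, 0.5)")


@dataclass
class FrameReport:
    time: float
    min_distance: float
    n_contacts: int
    n_hbonds: int
    n_bridges: int
    n_cation_surface: int
    mode: str
    e_lj: float
    e_coul: float

    def __post_init__(self) -> None:
        if min(self.n_contacts, self.n_hbonds, self.n_bridges, self.n_cation_surface) < 0:
            raise ValueError("counts must be non-negative")
        if (self.mode == "desorbed") != (self.n_contacts == 0):
            raise ValueError("mode 'desorbed' must coincide with zero contacts")


# ---------------------------------------------------------------------------
# per-frame measurements
# ---------------------------------------------------------------------------


def min_distance(state: SystemState) -> float:
    """Minimum polymer-atom to surface-atom distance, in-plane images."""
    pol = state.positions[state.mask("polymer")]
    surf = state.positions[state.mask("surface")]
    if len(pol) == 0 or len(surf) == 0:
        raise ValueError("empty polymer or surface group")
    return min_cross_distance(pol, surf, state.box)


def min_distance_series(
    traj: Trajectory,
    polymer_group: str = "polymer",
    surface_group: str = "surface",
) -> pd.DataFrame:
    """Per-frame minimum distance between the two groups (Fig-4-style curve)."""
    st = traj.state
    pol = st.indices(polymer_group)
    surf = st.indices(surface_group)
    if len(pol) == 0 or len(surf) == 0:
        raise ValueError("empty polymer or surface group")
    rows = [
        (t, min_cross_distance(traj.positions[k][pol], traj.positions[k][surf], traj.box))
        for k, t in enumerate(traj.times)
    ]
    return pd.DataFrame(rows, columns=["time", "min_distance"])


def contacting_atoms(state: SystemState, params: AnalysisParams) -> np.ndarray:
    """Indices of polymer atoms with >= 1 surface atom within the cutoff."""
    pol = state.indices("polymer")
    surf = state.indices("surface")
    ia, _, _ = pairs_within(
        state.positions[pol], state.positions[surf], params.contact_cutoff, state.box
    )
    return pol[np.unique(ia)]


def count_contacts(state: SystemState, params: AnalysisParams | None = None) -> int:
    """Number of polymer atoms in contact with the surface.

    With ``params.pair_counting`` the raw atom-pair count is returned
    instead of the per-atom count.
    """
    params = params or AnalysisParams()
    if params.pair_counting:
        pol = state.indices("polymer")
        surf = state.indices("surface")
        ia, _, _ = pairs_within(
            state.positions[pol], state.positions[surf], params.contact_cutoff, state.box
        )
        return int(len(ia))
    return int(len(contacting_atoms(state, params)))


def count_cation_surface(state: SystemState, params: AnalysisParams | None = None) -> int:
    """Cations with at least one surface atom inside the contact shell."""
    params = params or AnalysisParams()
    cat = state.indices("cation")
    surf = state.indices("surface")
    if len(cat) == 0:
        return 0
    ia, _, _ = pairs_within(
        state.positions[cat], state.positions[surf], params.contact_cutoff, state.box
    )
    return int(len(np.unique(ia)))


def _donor_pairs(state: SystemState, group_mask: np.ndarray) -> list[tuple[int, int]]:
    """(donor-heavy-atom, attached-H) site pairs inside one group.

    Polymer donors are read from role tags via the bond list; the surface
    contributes its hydroxyls, whose O and H sites alternate in build
    order.
    """
    out: list[tuple[int, int]] = []
    bonded: dict[int, list[int]] = {}
    for i, j in state.bonds:
        bonded.setdefault(int(i), []).append(int(j))
        bonded.setdefault(int(j), []).append(int(i))
    idx = np.nonzero(group_mask)[0]
    roles = state.roles
    for i in idx:
        h_role = _DONOR_ROLES.get(roles[i])
        if h_role:
            for j in bonded.get(int(i), ()):
                if roles[j] == h_role:
                    out.append((int(i), int(j)))
    # surface hydroxyls: species tags identify O-H; pair each O with the
    # nearest H site index (they are emitted consecutively by the builder)
    if group_mask[state.groups == "surface"].any():
        surf = np.nonzero(group_mask & (state.groups == "surface"))[0]
        o_sites = surf[state.species[surf] == "O_hydroxyl"]
        h_sites = surf[state.species[surf] == "H_hydroxyl"]
        # builder emits each O immediately followed by its H
        h_by_index = {int(h) - 1: int(h) for h in h_sites}
        for o in o_sites:
            h = h_by_index.get(int(o))
            if h is not None:
                out.append((int(o), h))
    return out


def _acceptors(state: SystemState, group_mask: np.ndarray) -> np.ndarray:
    idx = np.nonzero(group_mask)[0]
    is_surface_o = state.species[idx] == "O_hydroxyl"
    is_polymer_o = np.isin(state.roles[idx], _ACCEPTOR_ROLES)
    return idx[is_surface_o | is_polymer_o]


def count_hbonds(
    state: SystemState, params: AnalysisParams | None = None
) -> tuple[int, list[tuple[int, int, int]]]:
    """Polymer<->surface hydrogen bonds, both donation directions.

    A bond is a (donor, H, acceptor) triple with donor–acceptor distance
    strictly below the cutoff; when ``params.hbond_angle_cutoff`` is set
    the H–donor–acceptor angle must additionally stay below it.  Returns
    the count and the participating triples.
    """
    params = params or AnalysisParams()
    records: list[tuple[int, int, int]] = []
    pol_mask = state.mask("polymer")
    surf_mask = state.mask("surface")
    if not pol_mask.any() or not surf_mask.any():
        raise ValueError("hydrogen-bond search needs polymer and surface groups")
    directions = (
        (_donor_pairs(state, pol_mask), _acceptors(state, surf_mask)),
        (_donor_pairs(state, surf_mask), _acceptors(state, pol_mask)),
    )
    if not any(d for d, _ in directions):
        raise ValueError("no donors tagged in either group")
    for donors, acceptors in directions:
        if not donors or len(acceptors) == 0:
            continue
        d_idx = np.array([d for d, _ in donors], dtype=int)
        h_idx = np.array([h for _, h in donors], dtype=int)
        ia, ja, dist = pairs_within(
            state.positions[d_idx],
            state.positions[acceptors],
            params.hbond_da_cutoff,
            state.box,
        )
        for k in range(len(ia)):
            d, h, a = int(d_idx[ia[k]]), int(h_idx[ia[k]]), int(acceptors[ja[k]])
            if params.hbond_angle_cutoff is not None:
                v_h = state.positions[h] - state.positions[d]
                v_a = state.positions[a] - state.positions[d]
                # in-plane minimum image for the acceptor leg
                for ax in (0, 1):
                    v_a[ax] -= state.box[ax] * np.round(v_a[ax] / state.box[ax])
                    v_h[ax] -= state.box[ax] * np.round(v_h[ax] / state.box[ax])
                cosang = np.dot(v_h, v_a) / (
                    np.linalg.norm(v_h) * np.linalg.norm(v_a)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang >= params.hbond_angle_cutoff:
                    continue
            records.append((d, h, a))
    return len(records), records


def count_cationic_bridges(
    state: SystemState, params: AnalysisParams | None = None
) -> tuple[int, list[tuple[int, int, int]]]:
    """Cations simultaneously coordinating a surface O and a polymer O.

    Counted once per cation regardless of how many oxygens are in range;
    the records list one (cation, surface-O, polymer-O) triple per
    bridging cation, using the closest oxygen on each side.
    """
    params = params or AnalysisParams()
    cations = state.indices("cation")
    if len(cations) == 0:
        return 0, []
    surf_o = state.surface_oxygens()
    pol_o = state.polymer_oxygens()
    if len(surf_o) == 0 or len(pol_o) == 0:
        return 0, []
    ic_s, js, ds = pairs_within(
        state.positions[cations], state.positions[surf_o], params.bridge_cutoff, state.box
    )
    ic_p, jp, dp = pairs_within(
        state.positions[cations], state.positions[pol_o], params.bridge_cutoff, state.box
    )
    records: list[tuple[int, int, int]] = []
    for c in np.intersect1d(np.unique(ic_s), np.unique(ic_p)):
        s_hits = np.nonzero(ic_s == c)[0]
        p_hits = np.nonzero(ic_p == c)[0]
        best_s = int(surf_o[js[s_hits[np.argmin(ds[s_hits])]]])
        best_p = int(pol_o[jp[p_hits[np.argmin(dp[p_hits])]]])
        records.append((int(cations[c]), best_s, best_p))
    return len(records), records


def monomer_contacts(state: SystemState, params: AnalysisParams | None = None) -> set[int]:
    """Backbone monomer indices holding >= 1 atomic contact.

    Pendant (branch) monomers are attributed to their host backbone unit so
    pose classification sees one linear coordinate along the chain.
    """
    params = params or AnalysisParams()
    atoms = contacting_atoms(state, params)
    n = state.n_monomers
    out: set[int] = set()
    for m in np.unique(state.monomer_index[atoms]):
        m = int(m)
        out.add(m if m < n else (m - n) % n)
    return out


def classify_mode(state: SystemState, params: AnalysisParams | None = None) -> str:
    """Adsorption-pose label from the set of contacting monomers."""
    params = params or AnalysisParams()
    contacts = monomer_contacts(state, params)
    if not contacts:
        return "desorbed"
    n = state.n_monomers
    w = max(1, int(round(params.terminal_fraction * n)))
    lo = all(m < w for m in contacts)
    hi = all(m >= n - w for m in contacts)
    if lo or hi:
        return "end_grafted"
    if all(w <= m < n - w for m in contacts):
        return "u_shaped"
    return "mixed"


def energy_decomposition(
    state: SystemState,
    ff: ForceFieldParams | None = None,
    params: AnalysisParams | None = None,
) -> tuple[float, float, dict[str, float]]:
    """Short-range polymer–surface interaction energy, split LJ vs Coulomb.

    Plain truncated sums over polymer x surface pairs within the energy
    cutoff (minimum image in-plane), Lorentz–Berthelot mixing; proportions
    are |E| / (|E_lj| + |E_coul|).
    """
    ff = ff or ForceFieldParams()
    params = params or AnalysisParams()
    pol = state.indices("polymer")
    surf = state.indices("surface")
    if len(pol) == 0 or len(surf) == 0:
        raise ValueError("empty polymer or surface group")
    type_index, eps_tab, sig_tab = ff.tables_for(state.species)
    ia, ja, r = pairs_within(
        state.positions[pol], state.positions[surf], params.energy_cutoff, state.box
    )
    if len(ia) == 0:
        return 0.0, 0.0, {"lj": 0.0, "coul": 0.0}
    i, j = pol[ia], surf[ja]
    ti, tj = type_index[i], type_index[j]
    sr6 = (sig_tab[ti, tj] / r) ** 6
    e_lj = float(np.sum(4.0 * eps_tab[ti, tj] * (sr6 * sr6 - sr6)))
    e_coul = float(
        np.sum(ff.coulomb_constant * state.charges[i] * state.charges[j] / r)
    )
    denom = abs(e_lj) + abs(e_coul)
    props = {
        "lj": abs(e_lj) / denom if denom > 0 else 0.0,
        "coul": abs(e_coul) / denom if denom > 0 else 0.0,
    }
    return e_lj, e_coul, props


def analyze_frame(
    state: SystemState,
    time: float = 0.0,
    ff: ForceFieldParams | None = None,
    params: AnalysisParams | None = None,
) -> FrameReport:
    """All per-frame statistics bundled into one report."""
    params = params or AnalysisParams()
    n_contacts = count_contacts(state, params)
    n_hb, _ = count_hbonds(state, params)
    n_br, _ = count_cationic_bridges(state, params)
    e_lj, e_coul, _ = energy_decomposition(state, ff, params)
    return FrameReport(
        time=time,
        min_distance=min_distance(state),
        n_contacts=n_contacts,
        n_hbonds=n_hb,
        n_bridges=n_br,
        n_cation_surface=count_cation_surface(state, params),
        mode=classify_mode(state, params) if n_contacts else "desorbed",
        e_lj=e_lj,
        e_coul=e_coul,
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Release-stage statistics of one replicate (or a pooled set)."""

    replicate_id: int
    frames: pd.DataFrame  # FrameReport columns, one row per frame
    means: dict[str, float] = field(default_factory=dict)
    sems: dict[str, float] = field(default_factory=dict)
    mode_proportions: dict[str, float] = field(default_factory=dict)
    n_frames: int = 0
    single_frame: bool = False

    def __post_init__(self) -> None:
        if self.mode_proportions:
            total = sum(self.mode_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("mode proportions must sum to 1")


_NUMERIC = ["min_distance", "n_contacts", "n_hbonds", "n_bridges",
            "n_cation_surface", "e_lj", "e_coul"]


def frame_table(reports: list[FrameReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def analyze_trajectory(
    traj: Trajectory,
    ff: ForceFieldParams | None = None,
    params: AnalysisParams | None = None,
    stage: str | None = None,
) -> pd.DataFrame:
    """FrameReport rows for every (optionally stage-filtered) frame."""
    t = traj.select_stage(stage) if stage else traj
    reports = [
        analyze_frame(t.frame_state(k), time=float(t.times[k]), ff=ff, params=params)
        for k in range(t.n_frames)
    ]
    return frame_table(reports)


def aggregate(
    trajs: list[Trajectory] | Trajectory,
    ff: ForceFieldParams | None = None,
    params: AnalysisParams | None = None,
    stage: str = "release",
) -> RunReport:
    """Pool release-stage frames over one or more replicates.

    Means and standard errors of every numeric FrameReport field plus the
    pose-mode proportions.  A single-frame input reports SE = 0 with the
    ``single_frame`` flag set.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories to aggregate")
    tables = []
    for traj in trajs:
        if stage is not None and stage not in set(traj.stage_labels):
            raise ValueError(f"trajectory has no stage tagged {stage!r}")
        df = analyze_trajectory(traj, ff=ff, params=params, stage=stage)
        df["replicate_id"] = traj.replicate_id
        tables.append(df)
    frames = pd.concat(tables, ignore_index=True)
    n = len(frames)
    means = {c: float(frames[c].mean()) for c in _NUMERIC}
    sems = {
        c: float(frames[c].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        for c in _NUMERIC
    }
    counts = frames["mode"].value_counts()
    props = {m: float(counts.get(m, 0)) / n for m in MODES}
    return RunReport(
        replicate_id=int(trajs[0].replicate_id) if len(trajs) == 1 else -1,
        frames=frames,
        means=means,
        sems=sems,
        mode_proportions=props,
        n_frames=n,
        single_frame=(n == 1),
    )
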