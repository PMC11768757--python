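"""Reading and writing standard coordinate formats plus the topology table.

Coordinates go through MDAnalysis (GRO/PDB in their native conventions —
nm-based GRO fields, Angstrom PDB fields — and XYZ for raw frames).  The
chemistry the coordinate formats cannot carry (species tags, charges,
groups, monomer indices, roles, bonds) travels in a plain CSV topology
table with one row per atom and an optional bond list.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from .dynamics import Trajectory
from .system import SystemState

NM_TO_ANGSTROM = 10.0

_ATOM_COLUMNS = [
    "index",
    "label",
    "species",
    "charge",
    "group",
    "monomer_index",
    "role",
]


def _universe_from_state(state: SystemState) -> mda.Universe:
    n = state.n_atoms
    # one residue per polymer monomer; one shared residue per other group
    resindex = np.zeros(n, dtype=int)
    resnames = []
    next_res = 0
    group_res: dict[str, int] = {}
    group_resname = {
        "surface": "SLB",
        "cation": "NA",
        "anion": "CL",
        "solvent": "SOL",
    }
    mono_res: dict[int, int] = {}
    for i in range(n):
        g = state.groups[i]
        if g == "polymer":
            m = int(state.monomer_index[i])
            if m not in mono_res:
                mono_res[m] = next_res
                resnames.append("POL")
                next_res += 1
            resindex[i] = mono_res[m]
        else:
            if g not in group_res:
                group_res[g] = next_res
                resnames.append(group_resname.get(g, "UNK"))
                next_res += 1
            resindex[i] = group_res[g]
    u = mda.Universe.empty(
        n, n_residues=next_res, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", list(state.labels))
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(range(1, next_res + 1)))
    u.dimensions = [
        state.box[0] * NM_TO_ANGSTROM,
        state.box[1] * NM_TO_ANGSTROM,
        state.box[2] * NM_TO_ANGSTROM,
        90.0,
        90.0,
        90.0,
    ]
    u.atoms.positions = state.positions * NM_TO_ANGSTROM
    return u


def write_coordinates(state: SystemState, path: str | Path) -> None:
    """Write a single frame as GRO, PDB or XYZ (chosen by extension)."""
    u = _universe_from_state(state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_topology(state: SystemState, path: str | Path) -> None:
    """One-row-per-atom CSV; bonds appended as a second CSV next to it."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "index": np.arange(state.n_atoms),
            "label": state.labels,
            "species": state.species,
            "charge": state.charges,
            "group": state.groups,
            "monomer_index": state.monomer_index,
            "role": state.roles,
        }
    )
    df.to_csv(path, index=False)
    if len(state.bonds):
        bonds = pd.DataFrame(state.bonds, columns=["i", "j"])
        bonds["r0"] = state.bond_r0
        bonds.to_csv(path.with_suffix(".bonds.csv"), index=False)


def read_system(
    coordinates: str | Path,
    topology: str | Path,
    box: tuple[float, float, float] | None = None,
    polymer_name: str = "",
) -> SystemState:
    """Rebuild a :class:`SystemState` from a coordinate file + topology CSV."""
    topology = Path(topology)
    df = pd.read_csv(topology, keep_default_na=False)
    missing = set(_ATOM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"topology table misses columns: {sorted(missing)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coordinates))
    if len(u.atoms) != len(df):
        raise ValueError(
            f"coordinate file has {len(u.atoms)} atoms, topology {len(df)}"
        )
    if box is None:
        if u.dimensions is None or not u.dimensions[:3].any():
            raise ValueError("no box in coordinate file; pass box= explicitly")
        box = tuple(np.asarray(u.dimensions[:3], dtype=float) / NM_TO_ANGSTROM)
    bonds = np.empty((0, 2), dtype=int)
    bond_r0 = np.empty(0)
    bonds_path = topology.with_suffix(".bonds.csv")
    if bonds_path.exists():
        bdf = pd.read_csv(bonds_path)
        bonds = bdf[["i", "j"]].to_numpy(dtype=int)
        bond_r0 = bdf["r0"].to_numpy(dtype=float)
    groups = df["group"].to_numpy(dtype=str)
    surface_z = (u.atoms.positions[:, 2] / NM_TO_ANGSTROM)[groups == "surface"]
    monomer_index = df["monomer_index"].to_numpy(dtype=int)
    n_monomers = 0
    pol_monomers = monomer_index[groups == "polymer"]
    if len(pol_monomers):
        n_monomers = int(pol_monomers.max()) + 1
    return SystemState(
        box=np.asarray(box, dtype=float),
        positions=u.atoms.positions / NM_TO_ANGSTROM,
        species=df["species"].to_numpy(dtype=str),
        charges=df["charge"].to_numpy(dtype=float),
        groups=groups,
        labels=df["label"].to_numpy(dtype=str),
        roles=df["role"].to_numpy(dtype=str),
        monomer_index=monomer_index,
        bonds=bonds,
        bond_r0=bond_r0,
        slab_top=float(surface_z.max()) if len(surface_z) else 0.0,
        polymer_name=polymer_name,
        n_monomers=n_monomers,
    )


def write_trajectory(traj: Trajectory, prefix: str | Path, fmt: str = "xyz") -> Path:
    """Write all frames to one multi-frame file plus a frame-index CSV.

    Returns the coordinate file path; the frame table (time, stage) goes to
    ``<prefix>.frames.csv`` and the topology to ``<prefix>.top.csv``.
    """
    prefix = Path(prefix)
    coord_path = prefix.with_suffix(f".{fmt}")
    u = _universe_from_state(traj.frame_state(0))
    u.load_new(
        traj.positions * NM_TO_ANGSTROM,
        format=MemoryReader,
        dimensions=np.array(
            [[*(traj.box * NM_TO_ANGSTROM), 90.0, 90.0, 90.0]] * traj.n_frames
        ),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(coord_path), n_atoms=len(u.atoms)) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    pd.DataFrame(
        {
            "time": traj.times,
            "stage": traj.stage_labels,
            "box_x": traj.box[0],
            "box_y": traj.box[1],
            "box_z": traj.box[2],
        }
    ).to_csv(prefix.with_suffix(".frames.csv"), index=False)
    write_topology(traj.state, prefix.with_suffix(".top.csv"))
    return coord_path


def read_trajectory(
    coordinates: str | Path,
    topology: str | Path,
    frame_table: str | Path,
    box: tuple[float, float, float] | None = None,
) -> Trajectory:
    """Load a multi-frame coordinate file back into a :class:`Trajectory`.

    The box comes from the coordinate file when it has one, else from the
    explicit ``box=`` argument, else from the frame table written by
    :func:`write_trajectory`.
    """
    if box is None:
        ft_probe = pd.read_csv(frame_table, nrows=1)
        if {"box_x", "box_y", "box_z"} <= set(ft_probe.columns):
            box = (
                float(ft_probe["box_x"].iloc[0]),
                float(ft_probe["box_y"].iloc[0]),
                float(ft_probe["box_z"].iloc[0]),
            )
    state = read_system_first_frame(coordinates, topology, box)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coordinates))
        frames = np.array([u.atoms.positions / NM_TO_ANGSTROM for _ in u.trajectory])
    ft = pd.read_csv(frame_table)
    if len(ft) != len(frames):
        raise ValueError("frame table and trajectory disagree on frame count")
    state.positions = frames[-1]
    return Trajectory(
        times=ft["time"].to_numpy(dtype=float),
        positions=frames,
        box=state.box,
        stage_labels=ft["stage"].to_numpy(dtype=str),
        state=state,
    )


def read_system_first_frame(
    coordinates: str | Path,
    topology: str | Path,
    box: tuple[float, float, float] | None = None,
) -> SystemState:
    state = read_system(coordinates, topology, box=box)
    return state
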