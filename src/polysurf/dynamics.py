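"""Coarse-grained Langevin engine with a staged steering protocol.

The engine integrates only the mobile groups of a :class:`SystemState`
(the mineral slab stays rigid throughout) with the BAOAB Langevin splitting;
with the friction set to zero the O-step becomes the identity and the
scheme reduces exactly to velocity Verlet, which is how the conservative
integrator is obtained for energy-drift checks.

Adsorption poses are generated by a staged protocol modelled on how
steered simulations are normally set up: equilibrate the environment,
switch on a temporary flat-bottom restraint that pulls an anchor monomer
(terminal monomer for the end-grafted pose, central monomer for the
u-shaped pose) down to the surface, then release every restraint and watch
which contacts survive.  ``plant_configuration`` bypasses dynamics and
poses the chain geometrically with an exactly known contact set — the
ground truth used to validate the analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import KB, ForceFieldParams
from .neighbors import minimum_image_displacement, wrap_positions
from .system import SystemState

END_GRAFTED = "end_grafted"
U_SHAPED = "u_shaped"


class SimulationUnstable(RuntimeError):
    """Raised when a step moves an atom farther than half the cutoff."""


# ---------------------------------------------------------------------------
# steering protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stage:
    """One protocol stage: who moves, for how long, under which restraint."""

    name: str
    duration: int  # steps
    mobile_groups: tuple[str, ...]
    restraint_k: float = 0.0  # kJ/mol/nm^2; 0 disables the restraint
    restraint_target: float = 0.4  # nm, flat-bottom z-separation
    restraint_fmax: float = 300.0  # kJ/mol/nm force cap (0 = uncapped)
    mode: str = END_GRAFTED  # which monomer is anchored

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stage duration must be positive")
        if self.mode not in (END_GRAFTED, U_SHAPED):
            raise ValueError(f"unknown steering mode {self.mode!r}")


@dataclass(frozen=True)
class SteeringProtocol:
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol needs at least one stage")


def default_protocol(
    mode: str = END_GRAFTED,
    equilibration_steps: int = 500,
    steering_steps: int = 4000,
    release_steps: int = 2000,
    restraint_k: float = 1000.0,
    restraint_target: float = 0.4,
) -> SteeringProtocol:
    """The standard four-stage protocol: environment equilibration (ions
    only, the stand-in for the water-only and water+ions stages), steering
    with the fictitious restraint, then unrestrained release."""
    return SteeringProtocol(
        stages=(
            Stage("equil_ions", equilibration_steps, ("cation", "anion", "solvent")),
            Stage(
                "steering",
                steering_steps,
                ("polymer", "cation", "anion", "solvent"),
                restraint_k=restraint_k,
                restraint_target=restraint_target,
                mode=mode,
            ),
            Stage("release", release_steps, ("polymer", "cation", "anion", "solvent")),
        )
    )


def anchor_monomer(state: SystemState, mode: str) -> int:
    """Backbone monomer index anchored by the steering restraint."""
    n = state.n_monomers
    if n < 1:
        raise ValueError("state has no polymer")
    return 0 if mode == END_GRAFTED else n // 2


def anchor_sites(state: SystemState, mode: str) -> np.ndarray:
    """Site indices of the anchored monomer."""
    m = anchor_monomer(state, mode)
    idx = np.nonzero(state.mask("polymer") & (state.monomer_index == m))[0]
    if len(idx) == 0:
        raise ValueError(f"anchor monomer {m} has no sites")
    return idx


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def _exclusion_pairs(state: SystemState) -> set[int]:
    """Nonbonded exclusions, encoded as i * n_atoms + j with i < j.

    Excluded are pairs within two bonds (1-2, 1-3) and all pairs inside the
    same monomer: each monomer is one coarse-grained cluster whose internal
    geometry is maintained by its bond network, and bare partial charges at
    intra-cluster distances would otherwise create unphysically deep wells.
    """
    n = state.n_atoms
    adj: dict[int, set[int]] = {}
    for i, j in state.bonds:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    excl: set[int] = set()

    def add(i: int, j: int) -> None:
        if i != j:
            a, b = (i, j) if i < j else (j, i)
            excl.add(a * n + b)

    for i, nbrs in adj.items():
        for j in nbrs:
            add(i, j)
            for k in adj.get(j, ()):
                add(i, k)
    mono = state.monomer_index
    pol = np.nonzero(state.groups == "polymer")[0]
    for m in np.unique(mono[pol]):
        members = pol[mono[pol] == m]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                add(int(members[a]), int(members[b]))
    return excl


class ForceCalculator:
    """Bonded + nonbonded forces on the mobile atoms of one system.

    Nonbonded pairs come from a Verlet list over mobile x all atoms
    (frozen-frozen pairs never contribute force to a mobile atom and the
    rigid-slab internal energy is constant, so both are skipped).  The
    list is built from a KD-tree over the 3x3 in-plane images and refreshed
    whenever an atom has moved more than half the skin.
    """

    def __init__(
        self,
        state: SystemState,
        ff: ForceFieldParams,
        mobile: np.ndarray,
        skin: float = 0.3,
    ) -> None:
        self.ff = ff
        self.box = state.box
        self.n = state.n_atoms
        self.mobile = np.asarray(mobile, dtype=int)
        self.skin = skin
        self.type_index, self.eps_tab, self.sig_tab = ff.tables_for(state.species)
        self.charges = state.charges
        self.bonds = state.bonds
        self.bond_r0 = state.bond_r0
        self.angles = state.angles
        self.excl = _exclusion_pairs(state)
        self._excl_arr = np.fromiter(self.excl, dtype=np.int64) if self.excl else np.empty(0, dtype=np.int64)
        self._ref_positions: np.ndarray | None = None
        self._pairs: tuple[np.ndarray, np.ndarray] | None = None
        self._pair_eps = np.empty(0)
        self._pair_sig2 = np.empty(0)
        self._pair_qq = np.empty(0)

    # -- neighbour list -----------------------------------------------------

    def _build_pairs(self, positions: np.ndarray) -> None:
        rc = self.ff.cutoff + self.skin
        pos = wrap_positions(positions, self.box)
        shifts = [
            np.array([ix * self.box[0], iy * self.box[1], 0.0])
            for ix in (-1, 0, 1)
            for iy in (-1, 0, 1)
        ]
        tiled = np.concatenate([pos + s for s in shifts])
        index = np.tile(np.arange(self.n), len(shifts))
        tree = cKDTree(tiled)
        mobile_set = np.zeros(self.n, dtype=bool)
        mobile_set[self.mobile] = True
        hits = tree.query_ball_point(pos[self.mobile], rc)
        counts = [len(h) for h in hits]
        if sum(counts):
            pi = np.repeat(self.mobile, counts)
            pj = index[np.concatenate(hits).astype(int)]
            # rc + skin is far below half the box, so a pair can appear
            # through at most one periodic image — no dedup needed
            keep = pj != pi
            keep &= ~(mobile_set[pj] & (pj < pi))  # mobile-mobile counted once
            a = np.minimum(pi, pj).astype(np.int64)
            b = np.maximum(pi, pj).astype(np.int64)
            if len(self._excl_arr):
                keep &= ~np.isin(a * self.n + b, self._excl_arr)
            pi, pj = pi[keep], pj[keep]
        else:
            pi = pj = np.empty(0, dtype=int)
        self._pairs = (pi, pj)
        # per-pair parameters are fixed between rebuilds
        ti, tj = self.type_index[pi], self.type_index[pj]
        self._pair_eps = self.eps_tab[ti, tj]
        self._pair_sig2 = self.sig_tab[ti, tj] ** 2
        self._pair_qq = self.ff.coulomb_constant * self.charges[pi] * self.charges[pj]
        self._ref_positions = positions.copy()

    def _pairs_current(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._pairs is None or self._ref_positions is None:
            self._build_pairs(positions)
        else:
            disp = positions[self.mobile] - self._ref_positions[self.mobile]
            if len(disp) and float(np.abs(disp).max()) > 0.5 * self.skin:
                self._build_pairs(positions)
        assert self._pairs is not None
        return self._pairs

    # -- energies and forces ------------------------------------------------

    def compute(self, positions: np.ndarray) -> tuple[float, float, float, np.ndarray]:
        """Returns (e_lj, e_coul, e_bonded, forces)."""
        forces = np.zeros_like(positions)
        rc = self.ff.cutoff
        ii, jj = self._pairs_current(positions)
        e_lj = e_coul = 0.0
        if len(ii):
            d = positions[jj] - positions[ii]
            for ax in (0, 1):
                d[:, ax] -= self.box[ax] * np.round(d[:, ax] / self.box[ax])
            r2 = np.einsum("ij,ij->i", d, d)
            within = r2 < rc * rc
            i, j, d, r2 = ii[within], jj[within], d[within], r2[within]
            r = np.sqrt(r2)
            eps = self._pair_eps[within]
            sig2 = self._pair_sig2[within]
            sr6 = (sig2 / r2) ** 3
            # potential shifted to zero at the cutoff; force unchanged
            sr6_c = (sig2 / (rc * rc)) ** 3
            e_lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6 - sr6_c * sr6_c + sr6_c)))
            f_lj = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
            # force-shifted Coulomb: both potential and force go smoothly to
            # zero at the cutoff.  A plainly truncated 1/r over a layered
            # charged slab leaves a large spurious net field above the
            # surface (atoms crossing the cutoff carry discontinuous force);
            # the force shift removes that artifact.
            qq = self._pair_qq[within]
            e_coul = float(np.sum(qq * (1.0 / r + r / (rc * rc) - 2.0 / rc)))
            f_coul = qq * (1.0 / (r2 * r) - 1.0 / (r * rc * rc))
            fvec = (f_lj + f_coul)[:, None] * d
            for ax in range(3):
                forces[:, ax] += np.bincount(j, weights=fvec[:, ax], minlength=self.n)
                forces[:, ax] -= np.bincount(i, weights=fvec[:, ax], minlength=self.n)
        e_bonded = self._bonded(positions, forces)
        return e_lj, e_coul, e_bonded, forces

    def _bonded(self, positions: np.ndarray, forces: np.ndarray) -> float:
        e = 0.0
        if len(self.bonds):
            b0, b1 = self.bonds[:, 0], self.bonds[:, 1]
            d = minimum_image_displacement(positions[b0], positions[b1], self.box)
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            dr = r - self.bond_r0
            e += float(np.sum(0.5 * self.ff.bond_k * dr * dr))
            with np.errstate(invalid="ignore"):
                fvec = (-self.ff.bond_k * dr / np.where(r > 0, r, 1.0))[:, None] * d
            np.add.at(forces, b1, fvec)
            np.add.at(forces, b0, -fvec)
        if len(self.angles):
            e += self._angle_forces(positions, forces)
        return e

    def _angle_forces(self, positions: np.ndarray, forces: np.ndarray) -> float:
        """Worm-like-chain bending U = k (1 + cos(theta)), minimum at 180
        degrees: harmonic about the straight state with forces regular
        everywhere; k maps onto a persistence length of roughly
        k * b / kT for bond length b."""
        k = self.ff.angle_k
        a0, a1, a2 = self.angles[:, 0], self.angles[:, 1], self.angles[:, 2]
        u = minimum_image_displacement(positions[a1], positions[a0], self.box)
        v = minimum_image_displacement(positions[a1], positions[a2], self.box)
        ru = np.sqrt(np.einsum("ij,ij->i", u, u))
        rv = np.sqrt(np.einsum("ij,ij->i", v, v))
        cos = np.einsum("ij,ij->i", u, v) / (ru * rv)
        cos = np.clip(cos, -1.0, 1.0)
        e = float(np.sum(k * (cos + 1.0)))
        dud = np.full(len(cos), k)  # dU/dcos
        # gradients of cos(theta) w.r.t. the end atoms
        gu = (v / (ru * rv)[:, None]) - (cos / (ru * ru))[:, None] * u
        gv = (u / (ru * rv)[:, None]) - (cos / (rv * rv))[:, None] * v
        f0 = -dud[:, None] * gu
        f2 = -dud[:, None] * gv
        np.add.at(forces, a0, f0)
        np.add.at(forces, a2, f2)
        np.add.at(forces, a1, -(f0 + f2))
        return e

    def invalidate(self) -> None:
        self._pairs = None
        self._ref_positions = None


def potential_energy(
    state: SystemState, ff: ForceFieldParams, mobile: np.ndarray | None = None
) -> float:
    """Total potential energy of the mobile-vs-all interactions plus bonded
    terms (the rigid slab's internal energy is a constant and excluded)."""
    if mobile is None:
        mobile = np.nonzero(state.groups != "surface")[0]
    calc = ForceCalculator(state, ff, mobile)
    e_lj, e_coul, e_bonded, _ = calc.compute(state.positions)
    return e_lj + e_coul + e_bonded


# ---------------------------------------------------------------------------
# restraint
# ---------------------------------------------------------------------------


def _restraint_force(
    positions: np.ndarray,
    anchor: np.ndarray,
    masses: np.ndarray,
    slab_top: float,
    stage: Stage,
) -> tuple[float, np.ndarray]:
    """Flat-bottom harmonic on the anchor monomer's COM height above the
    slab top.

    Active only beyond the target separation; the pull force is capped so
    steering stays gentle at large initial separations, and distributed
    mass-proportionally over the anchor sites (a rigid COM pull that does
    not distort the monomer internally).
    """
    m = masses[anchor]
    z = float(np.average(positions[anchor, 2], weights=m))
    d = z - slab_top
    if d <= stage.restraint_target or stage.restraint_k == 0.0:
        return 0.0, np.zeros((len(anchor),))
    excess = d - stage.restraint_target
    f = stage.restraint_k * excess
    if stage.restraint_fmax > 0:
        f = min(f, stage.restraint_fmax)
    energy = 0.5 * stage.restraint_k * excess**2
    return energy, -f * m / m.sum()


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def minimize(
    state: SystemState,
    ff: ForceFieldParams,
    max_steps: int = 200,
    f_tol: float = 10.0,
    initial_step: float = 0.01,
) -> SystemState:
    """Steepest descent with adaptive step, on the non-surface atoms.

    Accepted moves never increase the potential energy; terminates when the
    largest force component drops below ``f_tol`` (kJ/mol/nm) or after
    ``max_steps`` trial steps.  Raises on NaN energies.
    """
    out = state.copy()
    mobile = np.nonzero(out.groups != "surface")[0]
    if len(mobile) == 0:
        return out
    calc = ForceCalculator(out, ff, mobile)
    pos = out.positions.copy()
    e_lj, e_coul, e_b, forces = calc.compute(pos)
    energy = e_lj + e_coul + e_b
    if not np.isfinite(energy):
        raise FloatingPointError("minimization diverged: non-finite initial energy")
    step = initial_step
    for _ in range(max_steps):
        fmax = float(np.abs(forces[mobile]).max())
        if fmax < f_tol:
            break
        trial = pos.copy()
        trial[mobile] += step * forces[mobile] / fmax
        calc.invalidate()
        e_lj, e_coul, e_b, trial_forces = calc.compute(trial)
        e_trial = e_lj + e_coul + e_b
        if not np.isfinite(e_trial):
            raise FloatingPointError("minimization diverged: non-finite energy")
        if e_trial <= energy:
            pos, forces, energy = trial, trial_forces, e_trial
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    out.positions = pos
    out.metadata = dict(out.metadata, minimized_energy=float(energy))
    return out


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Sampled frames of one run; positions are (n_frames, n_atoms, 3) nm."""

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    stage_labels: np.ndarray  # (n_frames,) str
    state: SystemState  # topology/metadata reference (positions = final frame)
    seed: int = 0
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must increase monotonically")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def polymer_name(self) -> str:
        return self.state.polymer_name

    def frame_state(self, i: int) -> SystemState:
        return replace(self.state, positions=self.positions[i])

    def select_stage(self, name: str) -> "Trajectory":
        m = self.stage_labels == name
        if not m.any():
            raise ValueError(f"no frames tagged with stage {name!r}")
        return replace(
            self,
            times=self.times[m],
            positions=self.positions[m],
            stage_labels=self.stage_labels[m],
        )

    @classmethod
    def concatenate(cls, parts: list["Trajectory"]) -> "Trajectory":
        if not parts:
            raise ValueError("nothing to concatenate")
        last = parts[-1]
        return cls(
            times=np.concatenate([p.times for p in parts]),
            positions=np.concatenate([p.positions for p in parts]),
            box=last.box,
            stage_labels=np.concatenate([p.stage_labels for p in parts]),
            state=last.state,
            seed=last.seed,
            replicate_id=last.replicate_id,
            metadata=dict(last.metadata),
        )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def run_stage(
    state: SystemState,
    ff: ForceFieldParams,
    stage: Stage,
    thermostat: tuple[float, float] = (300.0, 1.0),
    dt: float = 0.005,
    seed: int = 0,
    sample_every: int = 10,
    t0: float = 0.0,
    stop_on_contact: float = 0.0,
) -> Trajectory:
    """Integrate one protocol stage with BAOAB Langevin dynamics.

    Only atoms in ``stage.mobile_groups`` move; everything else is frozen
    bit-identically.  ``thermostat`` is (temperature K, friction 1/ps);
    friction 0 turns the scheme into plain velocity Verlet.  If
    ``stop_on_contact`` > 0 the stage ends early once the anchor monomer's
    minimum distance to the slab top plane drops below that value (used to
    measure steering approach times).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    temperature, friction = thermostat
    rng = np.random.default_rng(seed)
    out = state.copy()
    pos = out.positions.copy()
    n = out.n_atoms
    mobile = out.indices(*stage.mobile_groups)
    frozen = np.setdiff1d(np.arange(n), mobile)

    masses = ff.mass_array(out.species)
    inv_m = np.zeros(n)
    inv_m[mobile] = 1.0 / masses[mobile]

    vel = np.zeros((n, 3))
    if temperature > 0 and len(mobile):
        vel[mobile] = rng.normal(0.0, 1.0, (len(mobile), 3)) * np.sqrt(
            KB * temperature / masses[mobile]
        )[:, None]

    calc = ForceCalculator(out, ff, mobile)
    restrained = stage.restraint_k > 0
    anchor = anchor_sites(out, stage.mode) if (restrained or stop_on_contact > 0) else None

    def total_force(p: np.ndarray) -> np.ndarray:
        _, _, _, f = calc.compute(p)
        if restrained and anchor is not None:
            _, fz = _restraint_force(p, anchor, masses, out.slab_top, stage)
            f[anchor, 2] += fz
        return f

    forces = total_force(pos)
    c1 = np.exp(-friction * dt) if friction > 0 else 1.0
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.zeros(n)
    if temperature > 0:
        sigma_v[mobile] = np.sqrt(KB * temperature / masses[mobile])

    max_disp = 0.5 * ff.cutoff
    times, frames, kinetic = [], [], []
    steps_done = stage.duration
    for step in range(stage.duration):
        # B
        vel[mobile] += 0.5 * dt * forces[mobile] * inv_m[mobile][:, None]
        # A
        half = 0.5 * dt * vel[mobile]
        if len(half) and float(np.abs(half).max()) > max_disp:
            raise SimulationUnstable(
                f"stage {stage.name!r}: displacement exceeds {max_disp:.2f} nm/step"
            )
        pos[mobile] += half
        # O — friction damps even at zero temperature; noise vanishes there
        if friction > 0:
            vel[mobile] = c1 * vel[mobile] + c2 * sigma_v[mobile][:, None] * rng.normal(
                0.0, 1.0, (len(mobile), 3)
            )
        # A
        pos[mobile] += 0.5 * dt * vel[mobile]
        # B
        forces = total_force(pos)
        vel[mobile] += 0.5 * dt * forces[mobile] * inv_m[mobile][:, None]

        if (step + 1) % sample_every == 0 or step == stage.duration - 1:
            times.append(t0 + (step + 1) * dt)
            frames.append(wrap_positions(pos, out.box))
            ke = 0.5 * float(
                np.sum(masses[mobile][:, None] * vel[mobile] ** 2)
            )
            kinetic.append(ke)
        if stop_on_contact > 0 and anchor is not None:
            # contact = lowest anchor atom entering the threshold height
            if pos[anchor, 2].min() - out.slab_top < stop_on_contact:
                steps_done = step + 1
                if not times or times[-1] < t0 + (step + 1) * dt:
                    times.append(t0 + (step + 1) * dt)
                    frames.append(wrap_positions(pos, out.box))
                    kinetic.append(
                        0.5 * float(np.sum(masses[mobile][:, None] * vel[mobile] ** 2))
                    )
                break

    if frozen.size and frames:
        # frozen atoms must be bit-identical across frames
        assert np.array_equal(frames[-1][frozen], wrap_positions(state.positions, state.box)[frozen])

    out.positions = pos
    n_dof = 3 * len(mobile)
    mean_t = (
        float(2.0 * np.mean(kinetic) / (n_dof * KB)) if (kinetic and n_dof) else 0.0
    )
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames).reshape(len(frames), n, 3),
        box=out.box,
        stage_labels=np.full(len(times), stage.name),
        state=out,
        seed=seed,
        metadata={
            "stage": stage.name,
            "mean_temperature": mean_t,
            "steps_done": steps_done,
            "dt": dt,
        },
    )


def run_protocol(
    state: SystemState,
    ff: ForceFieldParams,
    protocol: SteeringProtocol,
    seed: int = 0,
    thermostat: tuple[float, float] = (300.0, 1.0),
    dt: float = 0.005,
    sample_every: int = 10,
    replicate_id: int = 0,
    do_minimize: bool = True,
) -> Trajectory:
    """Minimize, then run the stages in order; frames carry stage tags."""
    current = minimize(state, ff) if do_minimize else state.copy()
    parts: list[Trajectory] = []
    t0 = 0.0
    for k, stage in enumerate(protocol.stages):
        traj = run_stage(
            current,
            ff,
            stage,
            thermostat=thermostat,
            dt=dt,
            seed=seed + 7919 * k,
            sample_every=sample_every,
            t0=t0,
        )
        current = traj.state
        t0 = float(traj.times[-1])
        parts.append(traj)
    full = Trajectory.concatenate(parts)
    full.seed = seed
    full.replicate_id = replicate_id
    full.metadata["stage_names"] = [s.name for s in protocol.stages]
    return full


# ---------------------------------------------------------------------------
# ground-truth pose planting
# ---------------------------------------------------------------------------


def plant_configuration(
    state: SystemState,
    mode: str,
    contact_monomers: set[int] | frozenset[int],
    contact_height: float = 0.30,
    clear_height: float = 1.2,
) -> SystemState:
    """Geometrically pose the chain so exactly ``contact_monomers`` touch.

    Every site of a contact monomer is placed within the 0.5 nm contact
    shell of the slab; every other polymer site sits at ``clear_height``
    (or 3 nm when the contact set is empty, a fully desorbed pose).  Ions
    are lifted well away from the surface so they cannot contribute
    accidental contacts or bridges.  Deterministic; no dynamics involved.
    """
    contact_monomers = set(int(m) for m in contact_monomers)
    out = state.copy()
    site_lists = out.monomer_site_lists()
    if not site_lists:
        raise ValueError("state has no polymer")
    bad = contact_monomers - set(site_lists)
    if bad:
        raise ValueError(f"infeasible geometry: unknown monomer indices {sorted(bad)}")
    n_backbone = out.n_monomers
    desorbed_height = 3.0
    base_z = out.slab_top

    pos = out.positions.copy()
    x0, y0 = 0.6, out.box[1] / 2.0
    spacing = 0.8
    for m, sites in site_lists.items():
        if m < n_backbone:
            cx = (x0 + m * spacing) % out.box[0]
            cy = y0
        else:  # pendant unit rides beside its host backbone unit
            host = (m - n_backbone) % n_backbone
            cx = (x0 + host * spacing) % out.box[0]
            cy = (y0 + 0.6) % out.box[1]
        if not contact_monomers:
            zlow = base_z + desorbed_height
        elif m in contact_monomers:
            zlow = base_z + contact_height - 0.06
        else:
            zlow = base_z + clear_height
        block = pos[sites]
        block[:, 0] = block[:, 0] - block[:, 0].mean() + cx
        block[:, 1] = block[:, 1] - block[:, 1].mean() + cy
        block[:, 2] = block[:, 2] - block[:, 2].min() + zlow
        # clamp the vertical span so no site strays out of its shell
        span = block[:, 2].max() - block[:, 2].min()
        if span > 0.12:
            block[:, 2] = zlow + (block[:, 2] - zlow) * (0.12 / span)
        pos[sites] = block

    ions = out.mask("cation", "anion")
    pos[ions, 2] = np.maximum(pos[ions, 2], base_z + 2.5)
    out.positions = wrap_positions(pos, out.box)
    return out
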