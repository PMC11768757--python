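"""Langevin engine: minimization, integrator physics, steering, planting."""

import numpy as np
import pytest

import polysurf as ps
from polysurf.dynamics import (
    ForceCalculator,
    SimulationUnstable,
    Stage,
    anchor_sites,
    run_stage,
)

from polysurf.neighbors import distance_matrix

from conftest import random_frame


def _two_bead_state(separation, species=("C", "C"), charges=(0.0, 0.0), bond=False):
    box = np.array([6.0, 6.0, 12.0])
    state = ps.SystemState(
        box=box,
        positions=np.array([[3.0, 3.0, 5.0], [3.0 + separation, 3.0, 5.0]]),
        species=np.array(species),
        charges=np.array(charges, dtype=float),
        groups=np.array(["polymer", "polymer"]),
        labels=np.array(["A", "B"]),
        roles=np.array(["backbone", "backbone"]),
        monomer_index=np.array([0, 1]),
        n_monomers=2,
    )
    if bond:
        state.bonds = np.array([[0, 1]])
        state.bond_r0 = np.array([0.4])
    return state


def test_minimize_moves_lj_dimer_toward_well_bottom():
    ff = ps.ForceFieldParams()
    sigma = ff.lj["C"][1]
    state = _two_bead_state(0.9 * sigma)
    out = ps.minimize(state, ff, max_steps=500, f_tol=0.5)
    r = np.linalg.norm(out.positions[1] - out.positions[0])
    assert r == pytest.approx(2 ** (1 / 6) * sigma, abs=0.01)


def test_minimize_never_increases_energy(quick_system):
    ff = ps.ForceFieldParams()
    e0 = ps.potential_energy(quick_system, ff)
    out = ps.minimize(quick_system, ff, max_steps=100)
    assert out.metadata["minimized_energy"] <= e0 + 1e-9


def test_minimize_relaxes_stretched_bond_to_rest_length():
    ff = ps.ForceFieldParams()
    state = _two_bead_state(0.8, bond=True)  # stretched to 2 x r0
    out = ps.minimize(state, ff, max_steps=2000, f_tol=0.05)
    r = np.linalg.norm(out.positions[1] - out.positions[0])
    # LJ shifts the harmonic minimum slightly outward from r0
    assert r == pytest.approx(0.4, abs=0.05)


def test_velocity_verlet_energy_drift_small():
    """With friction 0 the integrator is conservative: relative drift of
    the total energy stays below 1e-3 over 10^4 steps."""
    rng = np.random.default_rng(0)
    box = np.array([6.0, 6.0, 12.0])
    n = 8
    pos = np.array([[1.0 + 1.2 * (i % 4), 2.0 + 1.2 * (i // 4), 5.0] for i in range(n)])
    state = ps.SystemState(
        box=box,
        positions=pos,
        species=np.array(["C"] * n),
        charges=np.zeros(n),
        groups=np.array(["polymer"] * n),
        labels=np.array(["C"] * n),
        roles=np.array(["backbone"] * n),
        monomer_index=np.arange(n),
        n_monomers=n,
    )
    ff = ps.ForceFieldParams()
    state = ps.minimize(state, ff, max_steps=300, f_tol=1.0)
    # give a small thermal kick, then integrate conservatively
    kick = run_stage(state, ff, Stage("kick", 10, ("polymer",)),
                     thermostat=(50.0, 5.0), dt=0.002, seed=1)
    masses = ff.mass_array(state.species)

    calc = ForceCalculator(kick.state, ff, np.arange(n))
    pos = kick.state.positions.copy()
    vel = np.zeros((n, 3))
    dt = 0.002
    _, _, _, f = calc.compute(pos)

    def total_energy():
        e_lj, e_c, e_b, _ = calc.compute(pos)
        ke = 0.5 * np.sum(masses[:, None] * vel**2)
        return e_lj + e_c + e_b + ke

    e0 = total_energy()
    for _ in range(10_000):
        vel += 0.5 * dt * f / masses[:, None]
        pos += dt * vel
        _, _, _, f = calc.compute(pos)
        vel += 0.5 * dt * f / masses[:, None]
    scale = max(abs(e0), 1.0)
    assert abs(total_energy() - e0) / scale < 1e-3


def test_frozen_groups_bit_identical(quick_system):
    ff = ps.ForceFieldParams()
    stage = Stage("s", 200, ("cation", "anion"))
    traj = run_stage(quick_system, ff, stage, seed=3, dt=0.005)
    frozen = quick_system.indices("surface", "polymer")
    for k in range(traj.n_frames):
        assert np.array_equal(
            traj.positions[k][frozen],
            traj.positions[0][frozen],
        )


def test_same_seed_identical_trajectory(quick_system):
    ff = ps.ForceFieldParams()
    stage = Stage("s", 100, ("polymer", "cation", "anion"))
    a = run_stage(quick_system, ff, stage, seed=7, dt=0.005)
    b = run_stage(quick_system, ff, stage, seed=7, dt=0.005)
    assert np.array_equal(a.positions, b.positions)
    c = run_stage(quick_system, ff, stage, seed=8, dt=0.005)
    assert not np.allclose(a.positions[-1], c.positions[-1])


def test_zero_restraint_stage_matches_plain_stage(quick_system):
    ff = ps.ForceFieldParams()
    plain = Stage("s", 150, ("polymer",))
    zero_k = Stage("s", 150, ("polymer",), restraint_k=0.0)
    a = run_stage(quick_system, ff, plain, seed=5, dt=0.005)
    b = run_stage(quick_system, ff, zero_k, seed=5, dt=0.005)
    assert np.array_equal(a.positions, b.positions)


def test_cell_list_forces_match_brute_force():
    """Verlet-list forces equal an exhaustive O(N^2) evaluation."""
    rng = np.random.default_rng(42)
    state = random_frame(rng, n_atoms=90)
    ff = ps.ForceFieldParams()
    mobile = np.nonzero(state.groups != "surface")[0]
    calc = ForceCalculator(state, ff, mobile)
    _, _, _, forces = calc.compute(state.positions)

    # brute force, same force-shifted formulas
    n = state.n_atoms
    ref = np.zeros((n, 3))
    rc = ff.cutoff
    dm = distance_matrix(state.positions, state.positions, state.box)
    frozen = set(np.nonzero(state.groups == "surface")[0])
    for i in range(n):
        for j in range(i + 1, n):
            if i in frozen and j in frozen:
                continue
            # same-monomer pairs are excluded from nonbonded interactions
            if (
                state.groups[i] == state.groups[j] == "polymer"
                and state.monomer_index[i] == state.monomer_index[j]
            ):
                continue
            r = dm[i, j]
            if r >= rc or r == 0:
                continue
            eps, sig = ff.mixed(state.species[i], state.species[j])
            d = state.positions[j] - state.positions[i]
            for ax in (0, 1):
                d[ax] -= state.box[ax] * np.round(d[ax] / state.box[ax])
            sr6 = (sig / r) ** 6
            f_lj = 24 * eps * (2 * sr6 * sr6 - sr6) / r**2
            qq = ff.coulomb_constant * state.charges[i] * state.charges[j]
            f_c = qq * (1 / r**3 - 1 / (r * rc * rc))
            ref[j] += (f_lj + f_c) * d
            ref[i] -= (f_lj + f_c) * d
    assert np.allclose(forces[mobile], ref[mobile], atol=1e-9)


def test_equipartition_temperature():
    """Mean kinetic temperature of a free chain within 5% of the 300 K
    set point (shortened companion of the acceptance-scale check)."""
    chain = ps.build_chain("PAM", 6, seed=0)
    box = np.array([8.0, 8.0, 16.0])
    state = ps.SystemState(
        box=box,
        positions=chain.positions + np.array([2.0, 4.0, 8.0]),
        species=chain.elements,
        charges=chain.charges,
        groups=np.array(["polymer"] * chain.n_sites),
        labels=chain.labels,
        roles=chain.roles,
        monomer_index=chain.monomer_index,
        bonds=chain.bonds,
        bond_r0=np.linalg.norm(
            chain.positions[chain.bonds[:, 1]] - chain.positions[chain.bonds[:, 0]],
            axis=1,
        ),
        n_monomers=6,
        backbone_sites=chain.backbone_sites,
    )
    ff = ps.ForceFieldParams()
    state = ps.minimize(state, ff, max_steps=200)
    # discard the thermalisation transient (the minimized start releases
    # contact energy), then measure
    warm = run_stage(
        state, ff, Stage("warmup", 10_000, ("polymer",)),
        thermostat=(300.0, 1.0), dt=0.002, seed=8,
    )
    traj = run_stage(
        warm.state, ff, Stage("nvt", 25_000, ("polymer",)),
        thermostat=(300.0, 1.0), dt=0.002, seed=9, sample_every=10,
    )
    assert traj.metadata["mean_temperature"] == pytest.approx(300.0, rel=0.05)


def test_instability_guard_raises():
    ff = ps.ForceFieldParams()
    # two beads placed deep inside the LJ core with a huge timestep
    state = _two_bead_state(0.05)
    with pytest.raises(SimulationUnstable):
        run_stage(state, ff, Stage("s", 50, ("polymer",)), dt=0.05, seed=0)


# ---------------------------------------------------------------------------
# protocol and planting
# ---------------------------------------------------------------------------


def test_protocol_stages_tagged_and_ordered(quick_system):
    ff = ps.ForceFieldParams()
    proto = ps.default_protocol(
        "end_grafted", equilibration_steps=40, steering_steps=60, release_steps=40
    )
    traj = ps.run_protocol(quick_system, ff, proto, seed=2, sample_every=20)
    labels = list(traj.stage_labels)
    assert set(labels) == {"equil_ions", "steering", "release"}
    # stage order preserved in time
    first = {s: labels.index(s) for s in set(labels)}
    assert first["equil_ions"] < first["steering"] < first["release"]
    assert np.all(np.diff(traj.times) > 0)


def test_steering_reduces_anchor_height(quick_system):
    ff = ps.ForceFieldParams()
    anchor = anchor_sites(quick_system, "end_grafted")
    z0 = quick_system.positions[anchor, 2].mean() - quick_system.slab_top
    stage = Stage(
        "steer", 1500, ("polymer", "cation", "anion"),
        restraint_k=1000.0, mode="end_grafted",
    )
    state = ps.minimize(quick_system, ff)
    traj = run_stage(state, ff, stage, seed=4, dt=0.005)
    z1 = traj.state.positions[anchor, 2].mean() - quick_system.slab_top
    assert z1 < z0 - 0.5


@pytest.mark.parametrize(
    "mode,contacts",
    [("end_grafted", {0}), ("end_grafted", {0, 1, 2}), ("u_shaped", {5, 6})],
)
def test_plant_configuration_exact_contact_sets(quick_system, mode, contacts):
    posed = ps.plant_configuration(quick_system, mode, contacts)
    assert ps.monomer_contacts(posed) == contacts
    assert ps.classify_mode(posed) == mode


def test_plant_empty_set_fully_desorbed(quick_system):
    posed = ps.plant_configuration(quick_system, "u_shaped", set())
    assert ps.min_distance(posed) > 1.0
    assert ps.classify_mode(posed) == "desorbed"


def test_plant_rejects_bad_monomer_indices(quick_system):
    with pytest.raises(ValueError, match="infeasible"):
        ps.plant_configuration(quick_system, "end_grafted", {999})
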