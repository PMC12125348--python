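"""Langevin engine: forces, integrator, thermostat, determinism."""

import numpy as np
import pytest

from supracg import engine
from supracg.model import (InteractionTable, PairPotential, System,
                           SystemSpec, build_system)
from supracg.synthetic import ideal_fibre
from supracg.units import KB


def _two_bead_system(r, box=8.0, eps=45.0):
    """Two isolated attractive cores at separation r along x."""
    table = InteractionTable(
        pairs={("core_m", "core_m"): PairPotential(eps, 0.47,
                                                   "lj_cut_shift")},
        coulomb=False)
    empty2 = np.empty((0, 2), np.int64)
    return System(
        positions=np.array([[2.0, 2.0, 2.0], [2.0 + r, 2.0, 2.0]]),
        velocities=np.zeros((2, 3)), box_edge=box,
        masses=np.full(2, 72.0), charges=np.zeros(2),
        cls_idx=np.zeros(2, np.int64), class_names=["core_m"],
        mol=np.arange(2, dtype=np.int64), species=["free", "free"],
        bonds=empty2, bond_k=np.empty(0), bond_r0=np.empty(0),
        angles=np.empty((0, 3), np.int64), angle_k=np.empty(0),
        angle_theta0=np.empty(0), constraints=empty2,
        constraint_d=np.empty(0), table=table,
        meta={"core_idx": [0, 1], "temperature": 300.0})


def test_lj_minimum_gives_zero_force():
    s = _two_bead_system(2.0 ** (1 / 6) * 0.47)
    f, _ = engine.compute_forces(s)
    assert np.abs(f).max() < 1e-9


def test_pair_energy_zero_beyond_cutoff():
    s = _two_bead_system(1.2)
    _, rep = engine.compute_forces(s)
    assert rep.vdw == 0.0
    # inside the cutoff, the potential is shifted to vanish at rc
    s2 = _two_bead_system(1.0999)
    _, rep2 = engine.compute_forces(s2)
    assert abs(rep2.vdw) < 1e-3


@pytest.mark.parametrize("counts,seed", [({"M": 3}, 2), ({"Mcoop": 2}, 5)])
def test_forces_are_exact_gradient(counts, seed):
    """Central finite differences agree with analytic forces to 1e-6."""
    spec = SystemSpec(counts=counts, box_edge=4.0, seed=seed,
                      placement_min_distance=0.7)
    s = engine.minimise(build_system(spec), max_steps=300)
    rng = np.random.default_rng(0)
    s.positions += rng.normal(scale=0.005, size=s.positions.shape)
    f, _ = engine.compute_forces(s)
    scale = max(np.abs(f).max(), 1.0)
    h = 1e-6
    rng2 = np.random.default_rng(1)
    picks = rng2.integers(0, s.n_beads, size=12)
    for i in picks:
        for d in range(3):
            sp = s.copy()
            sp.positions = s.positions.copy()
            sp.positions[i, d] += h
            sm = s.copy()
            sm.positions = s.positions.copy()
            sm.positions[i, d] -= h
            _, rp = engine.compute_forces(sp)
            _, rm = engine.compute_forces(sm)
            fd = -(rp.potential - rm.potential) / (2 * h)
            assert abs(fd - f[i, d]) / scale < 1e-6


def test_zero_forces_zero_temperature_static():
    s = _two_bead_system(2.0 ** (1 / 6) * 0.47)
    params = engine.IntegratorParams(temperature=0.0, seed=1)
    out = engine.langevin_step(s, params, n_steps=100)
    assert np.allclose(out.positions, s.positions, atol=1e-12)


def test_free_particle_temperature(free_gas_traj):
    """Equipartition: mean kinetic temperature within 2% of 300 K."""
    mean_t = free_gas_traj.energies["temperature"][1:].mean()
    assert abs(mean_t - 300.0) / 300.0 < 0.02


def test_free_particle_diffusion(free_gas_traj):
    """Einstein relation: D = kT tau / m within 5%."""
    from supracg.transport import diffusion_coefficient, msd

    curve = msd(free_gas_traj)
    d_est = diffusion_coefficient(curve, (0.1, 0.9))
    d_theory = KB * 300.0 * 0.1 / 72.0 * 1000.0  # nm^2/ns
    assert abs(d_est - d_theory) / d_theory < 0.05


def test_com_drift_is_diffusive(free_gas_traj):
    """No systematic centre-of-mass drift beyond diffusive expectation."""
    com = free_gas_traj.com_positions().mean(axis=1)
    disp = np.linalg.norm(com[-1] - com[0])
    d_theory = KB * 300.0 * 0.1 / 72.0 * 1000.0  # nm^2/ns per bead
    t = free_gas_traj.times[-1] - free_gas_traj.times[0]
    sigma = np.sqrt(6 * d_theory * t / 500)
    assert disp < 4.0 * sigma


def test_thermostat_on_interacting_system(m10_short_traj):
    """Kinetic temperature within 2% of target on a >= 1 ns run."""
    mean_t = m10_short_traj.energies["temperature"][1:].mean()
    assert abs(mean_t - 300.0) / 300.0 < 0.02


def test_nve_energy_conservation():
    """With friction/noise off, total-energy drift < 1e-3 |U0|.

    Run at 5 fs, where the stiff hexagon bonds are well inside the
    stability region of the velocity-Verlet limit of the integrator.
    """
    fib = ideal_fibre(10)
    rng = np.random.default_rng(3)
    fib.velocities = rng.normal(size=fib.velocities.shape) * \
        np.sqrt(KB * 300.0 / fib.masses)[:, None]
    params = engine.IntegratorParams(dt_fs=5.0, seed=1, friction=False)
    traj = engine.run(fib, params, n_steps=100_000, sample_every_ps=5.0)
    e = (traj.energies["potential"] + traj.energies["kinetic"]).to_numpy()
    t = traj.energies["time_ns"].to_numpy()
    drift = abs(np.polyfit(t, e, 1)[0]) * (t[-1] - t[0])
    u0 = abs(traj.energies["potential"][0])
    assert drift < 1e-3 * u0


def test_restart_is_bit_exact(m10_system):
    params = engine.IntegratorParams(seed=7)
    full = engine.run(m10_system, params, n_steps=30_000,
                      sample_every_ps=20.0)
    half = engine.run(m10_system, params, n_steps=15_000,
                      sample_every_ps=20.0)
    cont = engine.run(half.final_state, params, n_steps=15_000,
                      sample_every_ps=20.0)
    assert np.array_equal(full.positions[-1], cont.positions[-1])
    assert np.array_equal(full.final_state.velocities,
                          cont.final_state.velocities)


def test_frame_count_arithmetic(m10_system):
    params = engine.IntegratorParams(seed=2)
    traj = engine.run(m10_system, params, n_steps=30_000,
                      sample_every_ps=60.0)  # 0.6 ns sampled every 60 ps
    assert traj.n_frames == 11  # 10 chunks + t=0
    assert traj.times[0] == m10_system.time
    with pytest.raises(ValueError, match="multiple"):
        engine.run(m10_system, params, n_steps=14_999,
                   sample_every_ps=20.0)


def test_overlap_detection():
    s = _two_bead_system(0.05)
    with pytest.raises(engine.OverlapError, match="beads 0 and 1"):
        engine.compute_forces(s)


def test_blowup_detection():
    s = _two_bead_system(1.5)
    s.velocities[0] = [50.0, 0.0, 0.0]  # 1 nm per step
    params = engine.IntegratorParams(seed=1)
    with pytest.raises(engine.SimulationBlowupError):
        engine.langevin_step(s, params, n_steps=10)


def test_dipole_separation_invariant():
    """Charge-charge distance stays 0.28 nm within 1% during Mcoop runs."""
    spec = SystemSpec(counts={"Mcoop": 4}, box_edge=4.5, seed=2)
    s = engine.minimise(build_system(spec))
    params = engine.IntegratorParams(
        dt_fs=engine.default_dt_fs(["Mcoop"]), seed=6)
    traj = engine.run(s, params, n_steps=50_000, sample_every_ps=10.0)
    qp = traj.positions[:, traj.core_idx + 7, :]
    qm = traj.positions[:, traj.core_idx + 8, :]
    d = np.linalg.norm(qp - qm, axis=-1)
    assert d.min() > 0.28 * 0.99 and d.max() < 0.28 * 1.01


def test_assembly_onset():
    """A 10-monomer M system at stock concentration binds within 25 ns."""
    from supracg.aggregation import aggregation_series
    from supracg.trajectory import from_system_frames

    spec = SystemSpec(counts={"M": 10}, box_edge=5.99, seed=8)
    s = engine.minimise(build_system(spec))
    params = engine.IntegratorParams(seed=21)
    traj = engine.run(s, params, n_steps=1_245_000, sample_every_ps=300.0)
    series = aggregation_series(traj)
    assert series.sizes[:, -1].max() >= 2  # at least one bound pair
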