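"""MSD, diffusion coefficients and rotational autocorrelation."""

import numpy as np
import pytest

from supracg.synthetic import ideal_fibre
from supracg.trajectory import Trajectory, from_system_frames
from supracg.transport import MSDCurve, diffusion_coefficient, msd, orientation_acf


def _walk_trajectory(pos_frames, dt_ns=0.1):
    """Single-bead molecules from scripted centre positions."""
    n_frames, n_mol = pos_frames.shape[:2]
    return Trajectory(
        positions=pos_frames, times=np.arange(n_frames) * dt_ns,
        box_edge=100.0, mol=np.arange(n_mol),
        species=["free"] * n_mol, core_idx=np.arange(n_mol),
        roles=np.zeros(n_mol, np.int8), masses=np.full(n_mol, 72.0))


def test_msd_static_zero():
    pos = np.zeros((20, 3, 3))
    curve = msd(_walk_trajectory(pos))
    assert np.allclose(curve.msd, 0.0)
    assert curve.msd[0] == 0.0


def test_msd_ballistic():
    v = 2.0  # nm/ns
    t = np.arange(50) * 0.1
    pos = np.zeros((50, 1, 3))
    pos[:, 0, 0] = v * t
    curve = msd(_walk_trajectory(pos))
    assert np.allclose(curve.msd, (v * curve.tau_ns) ** 2, atol=1e-9)


def test_diffusion_coefficient_exact_line():
    tau = np.linspace(0, 10, 101)
    assert diffusion_coefficient(MSDCurve(tau, 6 * 0.1 * tau)) == \
        pytest.approx(0.1)
    assert diffusion_coefficient(MSDCurve(tau, np.zeros_like(tau))) == \
        pytest.approx(0.0)
    with pytest.raises(ValueError):
        diffusion_coefficient(MSDCurve(tau[:1], tau[:1] * 0))


def test_planted_brownian_recovery():
    """Planted D recovered within 3% from 1e4-step synthetic walks."""
    rng = np.random.default_rng(8)
    d_true = 0.25  # nm^2/ns
    dt = 0.05
    steps = rng.normal(scale=np.sqrt(2 * d_true * dt),
                       size=(10_000, 200, 3))
    pos = np.cumsum(steps, axis=0)
    curve = msd(_walk_trajectory(pos, dt_ns=dt))
    # short-lag window: many independent time origins per walker
    d_est = diffusion_coefficient(curve, (0.002, 0.05))
    assert abs(d_est - d_true) / d_true < 0.03


def test_wrapped_trajectory_rejected():
    pos = np.zeros((5, 2, 3))
    traj = _walk_trajectory(pos)
    traj.unwrapped = False
    with pytest.raises(ValueError, match="unwrapped"):
        msd(traj)


def test_acf_frozen_orientations():
    fib = ideal_fibre(5)
    traj = from_system_frames(fib, [fib.positions] * 10,
                              np.arange(10) * 0.05)
    acf = orientation_acf(traj)
    assert np.allclose(acf.acf, 1.0, atol=1e-12)
    assert acf.acf[0] == pytest.approx(1.0)


def test_acf_randomised_orientations_decorrelate():
    """Isotropically re-drawn orientations average to ~0 at any lag."""
    from supracg.model import _assemble, build_interaction_table, build_monomer
    from supracg.model import _random_rotation

    rng = np.random.default_rng(3)
    topo = build_monomer("M")
    table = build_interaction_table({"M"})
    frames = []
    n_mol, n_frames = 40, 30
    for f in range(n_frames):
        mols = [("M", topo, np.array([5.0 + 2 * m, 5.0, 5.0]),
                 _random_rotation(rng)) for m in range(n_mol)]
        frames.append(_assemble(mols, 100.0, table, 300.0,
                                np.random.default_rng(0)).positions)
    traj = Trajectory(
        positions=np.asarray(frames), times=np.arange(n_frames) * 0.05,
        box_edge=100.0, mol=np.repeat(np.arange(n_mol), 7),
        species=["M"] * n_mol, core_idx=np.arange(n_mol) * 7,
        roles=np.tile([0, 1, 1, 1, 1, 1, 1], n_mol).astype(np.int8),
        masses=np.full(7 * n_mol, 72.0))
    acf = orientation_acf(traj, max_lag_frames=10)
    assert acf.acf[0] == pytest.approx(1.0)
    # ~1200 independent samples per lag -> sampling error ~ 1/sqrt(n)
    assert np.abs(acf.acf[1:]).max() < 0.12


def test_acf_rotational_diffusion_rate_recovery():
    """Small-step random rotations give exp(-2 D_r t); rate within 10%."""
    rng = np.random.default_rng(9)
    n_mol, n_frames = 200, 300
    dt = 0.05  # ns
    d_r = 2.0  # rad^2/ns
    sigma = np.sqrt(2 * d_r * dt)
    u = rng.normal(size=(n_mol, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    us = np.empty((n_frames, n_mol, 3))
    for f in range(n_frames):
        us[f] = u
        axis = rng.normal(size=(n_mol, 3))
        axis -= (axis * u).sum(1, keepdims=True) * u
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        ang = rng.normal(scale=sigma, size=(n_mol, 1))
        u = np.cos(ang) * u + np.sin(ang) * axis
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    # realise the orientations as hexagon plane normals of M molecules
    from supracg.model import build_monomer

    topo = build_monomer("M")
    z = np.array([0.0, 0.0, 1.0])
    pos = np.empty((n_frames, n_mol * 7, 3))
    for f in range(n_frames):
        for m in range(n_mol):
            n_vec = us[f, m]
            v = np.cross(z, n_vec)
            c = float(z @ n_vec)
            if np.linalg.norm(v) < 1e-12:
                R = np.eye(3) if c > 0 else -np.eye(3)
            else:
                vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                               [-v[1], v[0], 0]])
                R = np.eye(3) + vx + vx @ vx / (1 + c)
            pos[f, m * 7:(m + 1) * 7] = topo.coords @ R.T + [3.0 * m, 0, 0]
    traj = Trajectory(
        positions=pos, times=np.arange(n_frames) * dt, box_edge=10000.0,
        mol=np.repeat(np.arange(n_mol), 7), species=["M"] * n_mol,
        core_idx=np.arange(n_mol) * 7,
        roles=np.tile([0, 1, 1, 1, 1, 1, 1], n_mol).astype(np.int8),
        masses=np.full(7 * n_mol, 72.0))
    acf = orientation_acf(traj, max_lag_frames=40)
    good = acf.acf > 0.05
    rate = -np.polyfit(acf.lag_ns[good], np.log(acf.acf[good]), 1)[0]
    # one random transverse axis per step: <dtheta^2> = sigma^2 = 2 D_r dt,
    # i.e. an effective sphere diffusivity D_r/2 and decay rate D_r
    assert abs(rate - d_r) / d_r < 0.10


def test_dipole_vector_requires_dipolar_species():
    fib = ideal_fibre(3, species="M")
    traj = from_system_frames(fib, [fib.positions] * 2, [0.0, 0.3])
    with pytest.raises(ValueError, match="dipolar"):
        orientation_acf(traj, vector="dipole")
    with pytest.raises(ValueError):
        orientation_acf(traj, vector="nope")


def test_dipole_acf_for_mcoop_fibre():
    fib = ideal_fibre(4, species="Mcoop")
    traj = from_system_frames(fib, [fib.positions] * 3, np.arange(3) * 0.3)
    acf = orientation_acf(traj, vector="dipole")
    assert np.allclose(acf.acf, 1.0)


def test_acf_bounded():
    fib = ideal_fibre(3)
    traj = from_system_frames(fib, [fib.positions] * 6, np.arange(6) * 0.1)
    acf = orientation_acf(traj)
    assert np.all(np.abs(acf.acf) <= 1.0 + 1e-12)
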