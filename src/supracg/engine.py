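"""Implicit-solvent Langevin dynamics for the coarse-grained models.

The integrator is a Langevin scheme in the spirit of the GROMACS ``sd``
integrator, with per-bead friction gamma_i = m_i / tau_t and exactly
matched Ornstein-Uhlenbeck thermal noise, so a free bead samples the
Maxwell-Boltzmann distribution at the target temperature by
construction.  The splitting is BAOAB (half-kick, half-drift, OU noise,
half-drift, half-kick), chosen for its near-exact configurational
sampling at finite time step; with friction and noise disabled it
reduces to velocity-Verlet NVE dynamics.  Distance constraints (the
Mcoop core-charge links) are enforced with an iterative SHAKE pass after
the position update, and velocities are made consistent with the
constrained displacement.

Non-bonded interactions use the minimum-image convention in a cubic
periodic box, truncated at ``table.cutoff`` (default 1.1 nm) and
potential-shifted to zero there; WCA-style pairs are truncated and
shifted at the potential minimum 2^(1/6) sigma.  Coulomb forces act only
between dipole charge beads, likewise truncated and shifted.

Units: nm, ps, kJ/mol, amu (velocities nm/ps, forces kJ mol^-1 nm^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import InteractionTable, System
from .trajectory import Trajectory, roles_for_species
from .units import F_COULOMB, KB

_SHAKE_TOL = 1.0e-6  # nm
_SHAKE_MAXITER = 200
_HARD_FLOOR = 0.08  # nm, bead-overlap error threshold (vdW-active pairs)
_MAX_STEP_DISP = 0.25  # nm per step, blow-up detector
_SKIN = 0.2  # nm, neighbour-list skin


class SimulationBlowupError(RuntimeError):
    pass


class OverlapError(RuntimeError):
    pass


def default_dt_fs(species) -> float:
    """Default time step: 20 fs, or 10 fs when dipolar species are present.

    The dipole bending mode (angle k = 1500 kJ/mol on charge beads of a
    third of the regular mass) sits at omega*dt ~ 2 for dt = 20 fs --
    the Verlet stability boundary -- so dipolar systems integrate at
    10 fs by default.
    """
    return 10.0 if set(species) & {"Mcoop", "McoopR"} else 20.0


@dataclass
class IntegratorParams:
    """Langevin ("sd"-like) integrator settings."""

    dt_fs: float = 20.0
    tau_t_ps: float = 0.1
    temperature: float = 300.0
    seed: int = 0
    friction: bool = True  # False -> NVE velocity-Verlet (validation only)

    def __post_init__(self):
        if self.dt_fs <= 0 or self.tau_t_ps <= 0:
            raise ValueError("dt and tau_t must be positive")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1.0e-3


@dataclass
class EnergyReport:
    bond: float
    angle: float
    vdw: float
    coulomb: float
    kinetic: float
    temperature: float

    @property
    def potential(self) -> float:
        return self.bond + self.angle + self.vdw + self.coulomb


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _build_pairs(pos, box, mol, cls, active, rlist):
    n = pos.shape[0]
    r2max = rlist * rlist
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            if active[cls[i], cls[j]] == 0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            if dx * dx + dy * dy + dz * dz <= r2max:
                cnt += 1
    pi = np.empty(cnt, np.int64)
    pj = np.empty(cnt, np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            if active[cls[i], cls[j]] == 0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            if dx * dx + dy * dy + dz * dz <= r2max:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True)
def _nonbonded(pos, box, pi, pj, cls, q, eps, sig, style, ushift, rc, fq,
               floor2, forces):
    """vdW + Coulomb forces over the pair list.

    Returns (E_vdw, E_coulomb, bad_pair): bad_pair >= 0 flags a pair below
    the hard overlap floor.
    """
    evdw = 0.0
    ecoul = 0.0
    bad = np.int64(-1)
    rc2 = rc * rc
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        a = cls[i]
        b = cls[j]
        s = style[a, b]
        fmag = 0.0
        if s > 0:
            if r2 < floor2:
                bad = k
            ep = eps[a, b]
            sg = sig[a, b]
            if s == 1:
                rcut2 = rc2
                shift = ushift[a, b]
            else:
                rw = 1.1224620483093730 * sg  # 2^(1/6) sigma
                rcut2 = rw * rw
                shift = -ep
            if r2 < rcut2:
                sr2 = sg * sg / r2
                sr6 = sr2 * sr2 * sr2
                sr12 = sr6 * sr6
                evdw += 4.0 * ep * (sr12 - sr6) - shift
                fmag += 24.0 * ep * (2.0 * sr12 - sr6) / r2
        qq = q[i] * q[j]
        if qq != 0.0 and r2 < rc2:
            if r2 < floor2:
                bad = k
            r = math.sqrt(r2)
            ecoul += fq * qq * (1.0 / r - 1.0 / rc)
            fmag += fq * qq / (r2 * r)
        if fmag != 0.0:
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[i, 2] += fmag * dz
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
            forces[j, 2] -= fmag * dz
    return evdw, ecoul, bad


@njit(cache=True)
def _bonded(pos, bi, bj, bk, br0, forces):
    e = 0.0
    for n in range(bi.shape[0]):
        i = bi[n]
        j = bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - br0[n]
        e += 0.5 * bk[n] * dr * dr
        fmag = -bk[n] * dr / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=True)
def _angles(pos, ai, aj, ak, akf, at0, forces):
    e = 0.0
    for n in range(ai.shape[0]):
        i = ai[n]
        j = aj[n]
        k = ak[n]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = math.sqrt(ux * ux + uy * uy + uz * uz)
        lv = math.sqrt(vx * vx + vy * vy + vz * vz)
        ux /= lu; uy /= lu; uz /= lu
        vx /= lv; vy /= lv; vz /= lv
        ct = ux * vx + uy * vy + uz * vz
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        dth = theta - at0[n]
        e += 0.5 * akf[n] * dth * dth
        st = math.sqrt(1.0 - ct * ct)
        if st < 1.0e-8:
            st = 1.0e-8
        coef = akf[n] * dth / st
        # F_i = coef/lu * (v - ct*u); F_k = coef/lv * (u - ct*v)
        fix = coef / lu * (vx - ct * ux)
        fiy = coef / lu * (vy - ct * uy)
        fiz = coef / lu * (vz - ct * uz)
        fkx = coef / lv * (ux - ct * vx)
        fky = coef / lv * (uy - ct * vy)
        fkz = coef / lv * (uz - ct * vz)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return e


@njit(cache=True)
def _shake(pos, ci, cj, cd, invm, tol, maxiter):
    for _ in range(maxiter):
        worst = 0.0
        for n in range(ci.shape[0]):
            i = ci[n]
            j = cj[n]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            d0 = cd[n]
            diff = r2 - d0 * d0
            err = abs(math.sqrt(r2) - d0)
            if err > worst:
                worst = err
            lam = diff / (2.0 * (invm[i] + invm[j]) * r2)
            pos[i, 0] -= invm[i] * lam * dx
            pos[i, 1] -= invm[i] * lam * dy
            pos[i, 2] -= invm[i] * lam * dz
            pos[j, 0] += invm[j] * lam * dx
            pos[j, 1] += invm[j] * lam * dy
            pos[j, 2] += invm[j] * lam * dz
        if worst < tol:
            return 0
    return 1


@njit(cache=True)
def _rattle(vel, pos, ci, cj, cd, invm, tol, maxiter):
    """Project velocities onto the constraint tangent (dG . v = 0)."""
    for _ in range(maxiter):
        worst = 0.0
        for n in range(ci.shape[0]):
            i = ci[n]
            j = cj[n]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dvx = vel[i, 0] - vel[j, 0]
            dvy = vel[i, 1] - vel[j, 1]
            dvz = vel[i, 2] - vel[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            dot = dvx * dx + dvy * dy + dvz * dz
            err = abs(dot) / math.sqrt(r2)
            if err > worst:
                worst = err
            lam = dot / ((invm[i] + invm[j]) * r2)
            vel[i, 0] -= invm[i] * lam * dx
            vel[i, 1] -= invm[i] * lam * dy
            vel[i, 2] -= invm[i] * lam * dz
            vel[j, 0] += invm[j] * lam * dx
            vel[j, 1] += invm[j] * lam * dy
            vel[j, 2] += invm[j] * lam * dz
        if worst < tol:
            return 0
    return 1


@njit(cache=True)
def _compute_all(pos, box, pi, pj, cls, q, eps, sig, style, ushift, rc, fq,
                 floor2, bi, bj, bkk, br0, ai, aj, ak, akf, at0, forces):
    forces[:] = 0.0
    evdw, ecoul, bad = _nonbonded(pos, box, pi, pj, cls, q, eps, sig, style,
                                  ushift, rc, fq, floor2, forces)
    ebond = _bonded(pos, bi, bj, bkk, br0, forces)
    eang = _angles(pos, ai, aj, ak, akf, at0, forces)
    return ebond, eang, evdw, ecoul, bad


@njit(cache=True)
def _apply_bias(pos, box, forces, bias_centres, bias_r0, bias_dr,
                bias_dvdr):
    """Add the tabulated distance-bias force between two centre beads."""
    if bias_centres.shape[0] != 2 or bias_dvdr.shape[0] < 2:
        return
    i0 = bias_centres[0]
    i1 = bias_centres[1]
    dx = pos[i0, 0] - pos[i1, 0]
    dy = pos[i0, 1] - pos[i1, 1]
    dz = pos[i0, 2] - pos[i1, 2]
    dx -= box * round(dx / box)
    dy -= box * round(dy / box)
    dz -= box * round(dz / box)
    r = math.sqrt(dx * dx + dy * dy + dz * dz)
    x = (r - bias_r0) / bias_dr
    if x < 0.0:
        x = 0.0
    nmax = bias_dvdr.shape[0] - 1
    if x > nmax:
        x = float(nmax)
    k0 = int(x)
    if k0 >= nmax:
        k0 = nmax - 1
    frac = x - k0
    dvdr = bias_dvdr[k0] * (1.0 - frac) + bias_dvdr[k0 + 1] * frac
    fb = -dvdr
    forces[i0, 0] += fb * dx / r
    forces[i0, 1] += fb * dy / r
    forces[i0, 2] += fb * dz / r
    forces[i1, 0] -= fb * dx / r
    forces[i1, 1] -= fb * dy / r
    forces[i1, 2] -= fb * dz / r


@njit(cache=True)
def _run_chunk(pos, vel, box, invm, cls, q, mol, active, eps, sig, style,
               ushift, rc, fq, bi, bj, bkk, br0, ai, aj, ak, akf, at0,
               ci, cj, cd, nsteps, dt, afr, bno, seed, rlist, max_disp,
               bias_centres, bias_r0, bias_dr, bias_dvdr):
    """Integrate nsteps of BAOAB Langevin; returns (status, mean KE).

    Status: 0 = ok, 1 = overlap, 2 = blow-up, 3 = SHAKE failure.
    The mean kinetic energy is accumulated right after the O
    (friction/noise) sub-step, where the BAOAB velocity marginal is
    unbiased; full-step velocities read systematically cold on stiff
    bonds at finite dt.
    ``bias_centres`` (two bead indices) plus a tabulated bias gradient
    dV/dr on a uniform distance grid (``bias_r0``, ``bias_dr``,
    ``bias_dvdr``) implement the optional metadynamics bias on the
    centre-centre distance; empty arrays disable it.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    ref = pos.copy()
    pi, pj = _build_pairs(pos, box, mol, cls, active, rlist)
    skin_half = 0.5 * (rlist - rc)
    floor2 = 0.08 * 0.08
    oldpos = np.empty_like(pos)
    free = np.empty_like(pos)
    # force at chunk entry
    _, _, _, _, bad = _compute_all(
        pos, box, pi, pj, cls, q, eps, sig, style, ushift, rc, fq,
        floor2, bi, bj, bkk, br0, ai, aj, ak, akf, at0, forces)
    if bad >= 0:
        return 1, 0.0
    _apply_bias(pos, box, forces, bias_centres, bias_r0, bias_dr, bias_dvdr)
    ke_sum = 0.0
    for step in range(nsteps):
        # BAOAB splitting: B half-kick, A half-drift, O, A half-drift,
        # (SHAKE), B half-kick with the fresh force
        constrained = ci.shape[0] > 0
        for i in range(n):
            for d in range(3):
                oldpos[i, d] = pos[i, d]
                vel[i, d] += 0.5 * dt * forces[i, d] * invm[i]
                pos[i, d] += 0.5 * dt * vel[i, d]
                vel[i, d] = afr[i] * vel[i, d] \
                    + bno[i] * np.random.standard_normal()
        if constrained:
            _rattle(vel, pos, ci, cj, cd, invm, 1.0e-8, 100)
        for i in range(n):
            for d in range(3):
                ke_sum += 0.5 * vel[i, d] * vel[i, d] / invm[i]
                pos[i, d] += 0.5 * dt * vel[i, d]
        if constrained:
            if _shake(pos, ci, cj, cd, invm, 1.0e-6, 200) != 0:
                return 3, 0.0
            _rattle(vel, pos, ci, cj, cd, invm, 1.0e-8, 100)
        maxstep2 = 0.0
        for i in range(n):
            ddx = pos[i, 0] - oldpos[i, 0]
            ddy = pos[i, 1] - oldpos[i, 1]
            ddz = pos[i, 2] - oldpos[i, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > maxstep2:
                maxstep2 = d2
        if maxstep2 > max_disp * max_disp:
            return 2, 0.0
        # fresh force for the closing half-kick
        maxd2 = 0.0
        for i in range(n):
            ddx = pos[i, 0] - ref[i, 0]
            ddy = pos[i, 1] - ref[i, 1]
            ddz = pos[i, 2] - ref[i, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > skin_half * skin_half:
            pi, pj = _build_pairs(pos, box, mol, cls, active, rlist)
            ref[:] = pos
        _, _, _, _, bad = _compute_all(
            pos, box, pi, pj, cls, q, eps, sig, style, ushift, rc, fq,
            floor2, bi, bj, bkk, br0, ai, aj, ak, akf, at0, forces)
        if bad >= 0:
            return 1, 0.0
        _apply_bias(pos, box, forces, bias_centres, bias_r0, bias_dr,
                    bias_dvdr)
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * forces[i, d] * invm[i]
        if constrained:
            _rattle(vel, pos, ci, cj, cd, invm, 1.0e-8, 100)
    return 0, ke_sum / nsteps


# ---------------------------------------------------------------------------
# python-level driver


def _table_arrays(system: System):
    table: InteractionTable = system.table
    eps, sig, style = table.to_arrays(system.class_names)
    rc = table.cutoff
    src = (sig / rc) ** 6
    ushift = 4.0 * eps * (src * src - src)  # LJ energy at the cutoff
    charge_cls = (np.array([c == "charge" for c in system.class_names]))
    active = (style > 0).astype(np.int64)
    if table.coulomb:
        active |= np.outer(charge_cls, charge_cls).astype(np.int64)
    fq = F_COULOMB / table.epsilon_r if table.coulomb else 0.0
    return eps, sig, style, ushift, active, rc, fq


def n_dof(system: System) -> int:
    """Degrees of freedom: 3N minus one per distance constraint."""
    return 3 * system.n_beads - len(system.constraint_d)


def kinetic_energy(system: System) -> float:
    return float(0.5 * (system.masses * (system.velocities ** 2).sum(axis=1)).sum())


def instantaneous_temperature(system: System) -> float:
    return 2.0 * kinetic_energy(system) / (n_dof(system) * KB)


def compute_forces(system: System) -> tuple[np.ndarray, EnergyReport]:
    """Forces (kJ mol^-1 nm^-1) and an energy report for one configuration.

    Raises :class:`OverlapError` naming the closest pair if any interacting
    beads sit below the hard overlap floor.
    """
    eps, sig, style, ushift, active, rc, fq = _table_arrays(system)
    pi, pj = _build_pairs(system.positions, system.box_edge, system.mol,
                          system.cls_idx, active, rc)
    forces = np.zeros_like(system.positions)
    ebond, eang, evdw, ecoul, bad = _compute_all(
        system.positions, system.box_edge, pi, pj, system.cls_idx,
        system.charges, eps, sig, style, ushift, rc, fq,
        _HARD_FLOOR ** 2, system.bonds[:, 0], system.bonds[:, 1],
        system.bond_k, system.bond_r0,
        system.angles[:, 0] if system.angles.size else np.empty(0, np.int64),
        system.angles[:, 1] if system.angles.size else np.empty(0, np.int64),
        system.angles[:, 2] if system.angles.size else np.empty(0, np.int64),
        system.angle_k, system.angle_theta0, forces)
    if bad >= 0:
        i, j = int(pi[bad]), int(pj[bad])
        raise OverlapError(f"beads {i} and {j} closer than {_HARD_FLOOR} nm")
    ke = kinetic_energy(system)
    temp = 2.0 * ke / (n_dof(system) * KB)
    return forces, EnergyReport(ebond, eang, evdw, ecoul, ke, temp)


def langevin_step(system: System, params: IntegratorParams,
                  n_steps: int = 1, _seed: int | None = None) -> System:
    """Advance the system by ``n_steps`` integrator steps (in place on a copy)."""
    out = system.copy()
    status, _ = _advance(out, params, n_steps,
                         params.seed if _seed is None else _seed)
    _raise_status(status)
    out.time += n_steps * params.dt_ps * 1.0e-3
    return out


def _raise_status(status: int):
    if status == 1:
        raise OverlapError("interacting beads below the hard overlap floor")
    if status == 2:
        raise SimulationBlowupError(
            f"per-step displacement exceeded {_MAX_STEP_DISP} nm")
    if status == 3:
        raise RuntimeError("SHAKE did not converge")


def _advance(system: System, params: IntegratorParams, n_steps: int,
             seed: int, bias_centres=None, bias_r0: float = 0.0,
             bias_dr: float = 1.0, bias_dvdr=None) -> int:
    eps, sig, style, ushift, active, rc, fq = _table_arrays(system)
    invm = 1.0 / system.masses
    dt = params.dt_ps
    if params.friction:
        a = math.exp(-dt / params.tau_t_ps)
        afr = np.full(system.n_beads, a)
        bno = np.sqrt((1.0 - a * a) * KB * params.temperature * invm)
    else:
        afr = np.ones(system.n_beads)
        bno = np.zeros(system.n_beads)
    ang = system.angles if system.angles.size else np.empty((0, 3), np.int64)
    cons = system.constraints if system.constraints.size else np.empty((0, 2), np.int64)
    if bias_centres is None:
        bias_centres = np.empty(0, np.int64)
    if bias_dvdr is None:
        bias_dvdr = np.empty(0)
    return _run_chunk(
        system.positions, system.velocities, system.box_edge, invm,
        system.cls_idx, system.charges, system.mol, active, eps, sig, style,
        ushift, rc, fq, system.bonds[:, 0], system.bonds[:, 1],
        system.bond_k, system.bond_r0, ang[:, 0], ang[:, 1], ang[:, 2],
        system.angle_k, system.angle_theta0, cons[:, 0], cons[:, 1],
        system.constraint_d, n_steps, dt, afr, bno, seed, rc + _SKIN,
        _MAX_STEP_DISP, bias_centres, bias_r0, bias_dr, bias_dvdr)


def _chunk_seed(seed: int, chunk_index: int) -> int:
    """Per-chunk RNG seed; deterministic and restart-stable."""
    return (seed * 1000003 + 7919 * (chunk_index + 1)) % 2147483647


def run(system: System, params: IntegratorParams, n_steps: int,
        sample_every_ps: float = 300.0) -> Trajectory:
    """Run Langevin dynamics, sampling frames every ``sample_every_ps``.

    The first stored frame is the initial state, so ``n_steps`` covering
    30 ns at a 0.3 ns sampling period yields 101 frames.  Runs are
    bit-reproducible for a fixed seed, and a run restarted from the
    final state of a shorter run continues the same trajectory exactly
    (chunk seeds derive from the absolute frame index, kept by
    ``system.time``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    steps_per_frame = int(round(sample_every_ps / params.dt_ps))
    if steps_per_frame < 1 or n_steps % steps_per_frame != 0:
        raise ValueError("n_steps must be a positive multiple of the "
                         "sampling period")
    n_frames = n_steps // steps_per_frame
    state = system.copy()
    frame_offset = int(round(state.time * 1000.0 / sample_every_ps))

    n = state.n_beads
    positions = np.empty((n_frames + 1, n, 3))
    times = np.empty(n_frames + 1)
    energies = []
    positions[0] = state.positions
    times[0] = state.time
    _, rep = compute_forces(state)
    energies.append(rep)
    ndof = n_dof(state)
    for f in range(n_frames):
        seed = _chunk_seed(params.seed, frame_offset + f)
        status, ke_chunk = _advance(state, params, steps_per_frame, seed)
        if status != 0:
            try:
                _raise_status(status)
            except Exception as exc:
                raise type(exc)(f"frame {f + 1}: {exc}") from exc
        state.time += steps_per_frame * params.dt_ps * 1.0e-3
        positions[f + 1] = state.positions
        times[f + 1] = state.time
        _, rep = compute_forces(state)
        if params.friction:
            # chunk-averaged KE from the unbiased (post-O) estimator;
            # NVE runs keep the endpoint full-step estimate, which is the
            # consistent one for energy-conservation checks
            rep.kinetic = ke_chunk
            rep.temperature = 2.0 * ke_chunk / (ndof * KB)
        energies.append(rep)

    roles = np.concatenate([roles_for_species(s) for s in state.species])
    import pandas as pd
    edf = pd.DataFrame([{
        "time_ns": t, "bond": e.bond, "angle": e.angle, "vdw": e.vdw,
        "coulomb": e.coulomb, "potential": e.potential, "kinetic": e.kinetic,
        "temperature": e.temperature} for t, e in zip(times, energies)])
    return Trajectory(
        positions=positions, times=times, box_edge=state.box_edge,
        mol=state.mol.copy(), species=list(state.species),
        core_idx=state.core_indices.copy(), roles=roles,
        masses=state.masses.copy(), unwrapped=True,
        meta={"dt_fs": params.dt_fs, "tau_t_ps": params.tau_t_ps,
              "temperature": params.temperature, "seed": params.seed,
              "sample_every_ps": sample_every_ps},
        final_state=state, energies=edf)


def minimise(system: System, max_steps: int = 2000, f_tol: float = 10.0,
             step0: float = 0.01) -> System:
    """Steepest-descent energy minimisation (adaptive step, capped moves).

    Relaxes the bead overlaps of a freshly packed random configuration
    before dynamics.  Constraints are re-satisfied after every accepted
    move; velocities are left untouched.
    """
    out = system.copy()
    eps, sig, style, ushift, active, rc, fq = _table_arrays(out)
    invm = 1.0 / out.masses
    ang = out.angles if out.angles.size else np.empty((0, 3), np.int64)
    cons = out.constraints if out.constraints.size else np.empty((0, 2), np.int64)
    forces = np.zeros_like(out.positions)

    def energy_forces(pos):
        pi, pj = _build_pairs(pos, out.box_edge, out.mol, out.cls_idx,
                              active, rc)
        eb, ea, ev, ec, _ = _compute_all(
            pos, out.box_edge, pi, pj, out.cls_idx, out.charges, eps, sig,
            style, ushift, rc, fq, 0.0, out.bonds[:, 0], out.bonds[:, 1],
            out.bond_k, out.bond_r0, ang[:, 0], ang[:, 1], ang[:, 2],
            out.angle_k, out.angle_theta0, forces)
        return eb + ea + ev + ec, forces.copy()

    pos = out.positions
    e, f = energy_forces(pos)
    h = step0
    for _ in range(max_steps):
        fmax = np.abs(f).max()
        if fmax < f_tol or h < 1.0e-8:
            break
        trial = pos + f * (h / fmax)
        if cons.shape[0]:
            _shake(trial, cons[:, 0], cons[:, 1], out.constraint_d, invm,
                   _SHAKE_TOL, _SHAKE_MAXITER)
        e_new, f_new = energy_forces(trial)
        if e_new < e:
            pos, e, f = trial, e_new, f_new
            h *= 1.2
        else:
            h *= 0.2
    out.positions = pos.copy()
    return out


def free_particle_system(n: int, box_edge: float, mass: float = 72.0,
                         temperature: float = 300.0, seed: int = 0) -> System:
    """Ideal-gas system of non-interacting beads (integrator validation)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box_edge, size=(n, 3))
    vel = rng.normal(size=(n, 3)) * math.sqrt(KB * temperature / mass)
    from .model import PairPotential
    table = InteractionTable(
        pairs={("ideal", "ideal"): PairPotential(0.0, 0.47, "none")},
        coulomb=False)
    empty2 = np.empty((0, 2), np.int64)
    return System(
        positions=pos, velocities=vel, box_edge=box_edge,
        masses=np.full(n, mass), charges=np.zeros(n),
        cls_idx=np.zeros(n, np.int64), class_names=["ideal"],
        mol=np.arange(n, dtype=np.int64), species=["free"] * n,
        bonds=empty2, bond_k=np.empty(0), bond_r0=np.empty(0),
        angles=np.empty((0, 3), np.int64), angle_k=np.empty(0),
        angle_theta0=np.empty(0), constraints=empty2,
        constraint_d=np.empty(0), table=table,
        meta={"core_idx": list(range(n)), "temperature": temperature})
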