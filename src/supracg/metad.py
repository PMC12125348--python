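"""Well-tempered metadynamics on the dimer core-core distance.

Two monomers in a small cubic box (3.5012 nm edge, the same concentration
as the 2000-monomer systems) are biased on the distance between their
core beads: Gaussian kernels (width 0.1 nm, initial height 0.1 kJ/mol)
are deposited every 10 ps with well-tempered scaling at bias factor 5,
so the kernel height at a revisited distance decays as the accumulated
bias grows.  The free-energy profile follows from the converged bias,

    dF(r) = -(gamma / (gamma - 1)) * V_bias(r),

re-zeroed at a reference separation, but its resolution is limited by
the kernel width; the default estimator instead reweights the sampled
distances with the time-dependent well-tempered weights, which resolves
the narrow binding well (see :func:`free_energy_profile`).  The profile
along the distance includes the geometric -2 kT ln(r) radial-entropy
term; a volume-correction toggle removes it for comparison with
orientation-averaged pair free energies.

The internal-energy profile dU(r) is the conditional mean of the
unbiased potential energy given r (within a distance bin the bias is
essentially constant, so the final-bias reweighting factors cancel);
-T dS = dF - dU pointwise.

A companion numerical oracle evaluates the same pair free energy by
direct Boltzmann integration over orientations and isolated-molecule
internal conformations, without ever touching the dynamics; it is the
independent reference the sampled profiles are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .model import (D_CHARGE, System, build_interaction_table,
                    build_monomer, _assemble, _random_rotation)
from .units import F_COULOMB, KB

METAD_BOX_EDGE = 3.5012  # nm; two monomers at the stock concentration


@dataclass
class BiasState:
    """Deposited kernels plus the tabulated bias potential."""

    kernels: pd.DataFrame  # time_ps, centre, width, height
    bias_factor: float
    pace_ps: float
    width: float
    height0: float
    temperature: float
    grid_r: np.ndarray
    grid_v: np.ndarray

    def potential_at(self, r) -> np.ndarray:
        return np.interp(r, self.grid_r, self.grid_v)

    def rebuild(self, n_kernels: int | None = None) -> np.ndarray:
        """Bias potential on the grid using only the first n kernels."""
        ks = self.kernels if n_kernels is None else self.kernels.iloc[:n_kernels]
        v = np.zeros_like(self.grid_r)
        for c, w, h in zip(ks["centre"], ks["width"], ks["height"]):
            v += h * np.exp(-0.5 * ((self.grid_r - c) / w) ** 2)
        return v

    def to_hills(self) -> pd.DataFrame:
        """Kernel log in HILLS-style columns (time, centre, width, height)."""
        return self.kernels.copy()


@dataclass
class MetadRun:
    species: str
    box_edge: float
    temperature: float
    bias: BiasState
    #: (n, 4): time_ps, r, V_bias(r, t), c(t) - the reweighting record
    cv_samples: np.ndarray
    #: (n_paces, 2): r, unbiased potential energy (kJ/mol)
    pot_samples: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class FreeEnergyProfile:
    r: np.ndarray  # nm
    dF: np.ndarray  # kJ/mol, zero at the reference separation
    dU: np.ndarray | None = None
    minus_TdS: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {"r_nm": self.r, "dF": self.dF}
        if self.dU is not None:
            d["dU"] = self.dU
            d["minus_TdS"] = self.minus_TdS
        return pd.DataFrame(d)


def _dimer_system(species: str, box_edge: float, temperature: float,
                  seed: int, restrain_dipole: bool,
                  restraint_k: float) -> System:
    if restrain_dipole and species not in ("Mcoop", "McoopR"):
        raise ValueError("the dipole restraint applies to Mcoop variants "
                         f"only, not {species}")
    topo = build_monomer(species)
    table = build_interaction_table({species})
    rng = np.random.default_rng(seed)
    c = box_edge / 2.0
    mols = [(species, topo, np.array([c, c, c - 0.5]), _random_rotation(rng)),
            (species, topo, np.array([c, c, c + 0.5]), _random_rotation(rng))]
    system = _assemble(mols, box_edge, table, temperature, rng)
    if restrain_dipole:
        # pin the dipole of molecule 0 along its plane normal: the
        # charge-core-shield angles to two adjacent vertices are held at 90
        extra = np.array([[7, 0, 1], [7, 0, 2]], dtype=np.int64)
        system.angles = np.vstack([system.angles, extra]) \
            if system.angles.size else extra
        system.angle_k = np.concatenate(
            [system.angle_k, [restraint_k, restraint_k]])
        system.angle_theta0 = np.concatenate(
            [system.angle_theta0, [math.pi / 2.0, math.pi / 2.0]])
        system.meta["dipole_restraint_k"] = restraint_k
    return system


def _core_distance(system: System) -> float:
    i0, i1 = system.core_indices
    d = system.positions[i0] - system.positions[i1]
    d -= system.box_edge * np.round(d / system.box_edge)
    return float(np.sqrt((d * d).sum()))


def wtmetad_run(species: str = "M", box_edge: float = METAD_BOX_EDGE,
                duration_ns: float = 100.0, width: float = 0.1,
                height: float = 0.1, pace_ps: float = 10.0,
                bias_factor: float = 5.0, temperature: float = 300.0,
                seed: int = 0, dt_fs: float | None = None,
                tau_t_ps: float = 0.1,
                restrain_dipole: bool = False,
                restraint_k: float = 500.0, wall_at: float = 1.6,
                wall_k: float = 500.0) -> MetadRun:
    """Run WT-metadynamics on a two-monomer system.

    The collective variable is the minimum-image core-core distance; the
    bias is accumulated on a distance grid (kernel deposition every
    ``pace_ps``) and its gradient is interpolated by the integrator at
    every step.  A harmonic upper wall at ``wall_at`` keeps the pair from
    wandering into the box corners; the wall force is applied alongside
    the bias but never enters the free-energy estimate, which is only
    meaningful below the wall.  Exactly two monomers are simulated -
    many-monomer metadynamics is out of scope.
    """
    if bias_factor <= 1.0:
        raise ValueError("bias_factor must exceed 1")
    system = _dimer_system(species, box_edge, temperature, seed,
                           restrain_dipole, restraint_k)
    system = engine.minimise(system, max_steps=500)
    if dt_fs is None:
        dt_fs = engine.default_dt_fs([species])
    params = engine.IntegratorParams(dt_fs=dt_fs, tau_t_ps=tau_t_ps,
                                     temperature=temperature, seed=seed)
    n_grid = 700
    grid_r = np.linspace(0.2, box_edge / 2.0, n_grid)
    grid_v = np.zeros(n_grid)
    wall_dvdr = wall_k * np.maximum(grid_r - wall_at, 0.0)
    grid_dvdr = wall_dvdr.copy()
    dr = grid_r[1] - grid_r[0]
    steps_per_pace = int(round(pace_ps / params.dt_ps))
    sub_sample_ps = min(1.0, pace_ps)
    steps_per_sub = int(round(sub_sample_ps / params.dt_ps))
    subs_per_pace = steps_per_pace // steps_per_sub
    n_paces = int(round(duration_ns * 1000.0 / pace_ps))
    delta_t = (bias_factor - 1.0) * temperature  # well-tempering Delta T
    beta = 1.0 / (KB * temperature)
    gamma = bias_factor
    bias_centres = system.core_indices.astype(np.int64)

    kernels = np.empty((n_paces, 4))
    cv = np.empty((n_paces * subs_per_pace, 4))
    pot = np.empty((n_paces, 2))
    c_t = 0.0
    isub = 0
    for k in range(n_paces):
        for s in range(subs_per_pace):
            status, _ = engine._advance(system, params, steps_per_sub,
                                        engine._chunk_seed(
                                            seed, k * subs_per_pace + s),
                                        bias_centres=bias_centres,
                                        bias_r0=grid_r[0], bias_dr=dr,
                                        bias_dvdr=grid_dvdr)
            engine._raise_status(status)
            r = _core_distance(system)
            t_ps = k * pace_ps + (s + 1) * sub_sample_ps
            cv[isub] = (t_ps, r, np.interp(r, grid_r, grid_v), c_t)
            isub += 1
        t_ps = (k + 1) * pace_ps
        h = height * math.exp(-np.interp(r, grid_r, grid_v) / (KB * delta_t))
        grid_v += h * np.exp(-0.5 * ((grid_r - r) / width) ** 2)
        grid_dvdr = np.gradient(grid_v, dr) + wall_dvdr
        kernels[k] = (t_ps, r, width, h)
        # time-dependent bias offset c(t) for on-the-fly reweighting
        c_t = (1.0 / beta) * (
            math.log(np.trapezoid(np.exp(beta * gamma / (gamma - 1.0)
                                         * grid_v), grid_r))
            - math.log(np.trapezoid(np.exp(beta / (gamma - 1.0) * grid_v),
                                    grid_r)))
        _, rep = engine.compute_forces(system)
        pot[k] = (r, rep.potential)
    bias = BiasState(
        kernels=pd.DataFrame(kernels,
                             columns=["time_ps", "centre", "width", "height"]),
        bias_factor=bias_factor, pace_ps=pace_ps, width=width,
        height0=height, temperature=temperature, grid_r=grid_r,
        grid_v=grid_v)
    return MetadRun(species, box_edge, temperature, bias, cv, pot,
                    meta={"seed": seed, "duration_ns": duration_ns,
                          "restrain_dipole": restrain_dipole})


def free_energy_profile(run_or_bias, grid: np.ndarray | None = None,
                        volume_correction: bool = False,
                        r_ref: float = 1.4, average_from: float = 0.5,
                        method: str = "reweight",
                        bin_width: float = 0.015) -> FreeEnergyProfile:
    """Free-energy profile from a WT-metadynamics run.

    ``method="reweight"`` (default, needs a full :class:`MetadRun`)
    histograms the sampled distances with the time-dependent weights
    exp(beta [V(s_t, t) - c(t)]); it resolves features narrower than the
    kernel width and converges to the unbiased profile.  ``method="bias"``
    uses the deposited bias directly, dF(r) = -(gamma/(gamma-1)) V(r),
    averaged over bias snapshots from the ``average_from`` fraction of
    the run onwards (resolution limited by the kernel width); its
    convergence diagnostic is the RMS drift between the last-quarter
    snapshots and the final profile.  Both are re-zeroed at ``r_ref``;
    ``volume_correction`` adds 2 kT ln(r), removing the radial-entropy
    term of the distance coordinate.
    """
    if method == "reweight":
        if not isinstance(run_or_bias, MetadRun):
            raise ValueError("reweighting needs the full run record")
        return _reweighted_profile(run_or_bias, volume_correction, r_ref,
                                   average_from, bin_width)
    if method != "bias":
        raise ValueError(f"unknown method {method!r}")
    bias = run_or_bias.bias if isinstance(run_or_bias, MetadRun) else run_or_bias
    if len(bias.kernels) == 0:
        raise ValueError("empty bias: no kernels deposited")
    r = bias.grid_r if grid is None else np.asarray(grid)
    gamma = bias.bias_factor
    pref = -gamma / (gamma - 1.0)
    nk = len(bias.kernels)
    n_snap = 24
    first = max(1, int(average_from * nk))
    snaps = np.unique(np.linspace(first, nk, n_snap).astype(int))
    centres = bias.kernels["centre"].to_numpy()
    widths = bias.kernels["width"].to_numpy()
    heights = bias.kernels["height"].to_numpy()
    contrib = heights[:, None] * np.exp(
        -0.5 * ((r[None, :] - centres[:, None]) / widths[:, None]) ** 2)
    cumv = np.cumsum(contrib, axis=0)
    profiles = []
    for s in snaps:
        f = pref * cumv[s - 1]
        f = f - np.interp(r_ref, r, f)
        profiles.append(f)
    profiles = np.asarray(profiles)
    dF = profiles.mean(axis=0)
    last_q = profiles[snaps >= 0.75 * nk]
    drift = float(np.sqrt(np.mean((last_q - profiles[-1]) ** 2))) \
        if len(last_q) > 1 else 0.0
    if volume_correction:
        kt = KB * bias.temperature
        dF = dF + 2.0 * kt * np.log(r / r_ref)
    return FreeEnergyProfile(r, dF, meta={
        "bias_factor": gamma, "r_ref": r_ref,
        "volume_correction": volume_correction,
        "convergence_drift": drift,
        "n_kernels": nk})


def _reweighted_profile(run: MetadRun, volume_correction: bool,
                        r_ref: float, discard: float,
                        bin_width: float) -> FreeEnergyProfile:
    kt = KB * run.temperature
    n0 = int(discard * len(run.cv_samples))
    t, r, vb, c = run.cv_samples[n0:].T
    logw = (vb - c) / kt
    logw -= logw.max()
    w = np.exp(logw)
    lo = run.bias.grid_r[0]
    hi = float(run.bias.grid_r[-1])
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, _ = np.histogram(r, bins=edges, weights=w)
    counts, _ = np.histogram(r, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        dF = -kt * np.log(hist)
    dF[counts < 5] = np.nan
    if volume_correction:
        dF = dF + 2.0 * kt * np.log(centres)
    ok = np.isfinite(dF)
    if not ok.any():
        raise ValueError("no sampled bins; run too short")
    dF = dF - np.interp(r_ref, centres[ok], dF[ok])
    # bootstrap-free precision proxy: effective sample count per bin
    neff = hist ** 2 / np.maximum(
        np.histogram(r, bins=edges, weights=w * w)[0], 1e-300)
    return FreeEnergyProfile(centres, dF, meta={
        "method": "reweight", "r_ref": r_ref,
        "volume_correction": volume_correction,
        "bin_width": bin_width,
        "n_samples": int(len(r)),
        "min_neff_sampled": float(np.nanmin(np.where(ok, neff, np.nan)))})


def energy_decomposition(run: MetadRun, profile: FreeEnergyProfile,
                         bin_width: float = 0.05, r_max: float | None = None,
                         min_samples: int = 25, discard: float = 0.25,
                         ) -> FreeEnergyProfile:
    """Attach dU(r) and -T dS(r) to a free-energy profile.

    dU(r) is the binned conditional mean of the unbiased potential energy
    (final-bias reweighting cancels within a bin), referenced to the bins
    around the profile's reference separation; bins with fewer than
    ``min_samples`` samples are masked (NaN).  -T dS = dF - dU.
    """
    r_ref = profile.meta.get("r_ref", 1.4)
    if r_max is None:
        r_max = float(run.bias.grid_r[-1])
    n0 = int(discard * len(run.pot_samples))
    rs = run.pot_samples[n0:, 0]
    us = run.pot_samples[n0:, 1]
    edges = np.arange(run.bias.grid_r[0], r_max + bin_width, bin_width)
    idx = np.digitize(rs, edges) - 1
    nb = len(edges) - 1
    mean_u = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        if sel.sum() >= min_samples:
            mean_u[b] = us[sel].mean()
    centres = 0.5 * (edges[:-1] + edges[1:])
    u_ref = np.interp(r_ref, centres[~np.isnan(mean_u)],
                      mean_u[~np.isnan(mean_u)])
    dU_bins = mean_u - u_ref
    dU = np.interp(profile.r, centres, dU_bins)
    # keep NaN masking: mark profile points whose nearest bin was masked
    nearest = np.clip(np.digitize(profile.r, edges) - 1, 0, nb - 1)
    dU[np.isnan(mean_u[nearest])] = np.nan
    minus_tds = profile.dF - dU
    return FreeEnergyProfile(profile.r, profile.dF, dU, minus_tds,
                             meta={**profile.meta,
                                   "bin_width": bin_width,
                                   "n_samples": int(len(rs))})


def restrained_dipole_run(duration_ns: float = 100.0, seed: int = 0,
                          restraint_k: float = 500.0,
                          species: str = "Mcoop", **kwargs) -> MetadRun:
    """WT-metadynamics of a dimer with one dipole pinned along its normal.

    Emulates the environment of a fibre-tip monomer, whose dipole is held
    by the stack; the comparison with the unrestrained dimerisation
    profile probes the cooperativity of elongation.
    """
    if species not in ("Mcoop", "McoopR"):
        raise ValueError("the restrained-dipole variant requires a dipolar "
                         "species (Mcoop or McoopR)")
    return wtmetad_run(species=species, duration_ns=duration_ns, seed=seed,
                       restrain_dipole=True, restraint_k=restraint_k,
                       **kwargs)


# ---------------------------------------------------------------------------
# direct numerical oracle


def sample_internal_ensemble(species: str, n_samples: int = 4096,
                             seed: int = 0, temperature: float = 300.0,
                             n_sweeps: int = 1200,
                             step: float = 0.02) -> np.ndarray:
    """Isolated-molecule internal Boltzmann ensemble by Metropolis MC.

    The hexagon is only quartically stiff against out-of-plane bending
    (all bonds lie in the plane), so beads fluctuate by ~0.05-0.08 nm
    along the normal at 300 K; a rigid-geometry reference would misstate
    pair free energies by >1 kJ/mol.  This sampler runs ``n_samples``
    independent replicas in parallel, one single-bead Metropolis move per
    bead per sweep, using only the bonded energy (intramolecular
    non-bonded terms are excluded, as in the dynamics).  Dipole charge
    beads (Mcoop variants) are handled analytically afterwards: the
    dipole direction is a free rotor, and the charge-core-charge angle
    follows sin(theta) exp(-beta k (theta-pi)^2 / 2).

    Returns (n_samples, n_beads, 3) conformations with the core bead at
    the origin.  Results are memoised per parameter set (callers receive
    a copy).
    """
    key = (species, n_samples, seed, temperature, n_sweeps, step)
    if key in _POOL_CACHE:
        return _POOL_CACHE[key].copy()
    out = _sample_internal_ensemble(species, n_samples, seed, temperature,
                                    n_sweeps, step)
    if len(_POOL_CACHE) < 8:
        _POOL_CACHE[key] = out
    return out.copy()


_POOL_CACHE: dict = {}


def _sample_internal_ensemble(species, n_samples, seed, temperature,
                              n_sweeps, step) -> np.ndarray:
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    topo = build_monomer(species)
    dipolar = species in ("Mcoop", "McoopR")
    nb_ring = 7 if species != "C" else 8
    bonds = [(i, j, k, r0) for (i, j, k, r0) in topo.bonds]
    pos = np.repeat(topo.coords[None, :nb_ring, :], n_samples, axis=0).copy()
    neigh = {b: [] for b in range(nb_ring)}
    for (i, j, k, r0) in bonds:
        neigh[i].append((j, k, r0))
        neigh[j].append((i, k, r0))

    def local_energy(p, bead):
        e = np.zeros(n_samples)
        for (j, k, r0) in neigh[bead]:
            r = np.linalg.norm(p[:, bead] - p[:, j], axis=1)
            e += 0.5 * k * (r - r0) ** 2
        return e

    for sweep in range(n_sweeps):
        for bead in range(nb_ring):
            e0 = local_energy(pos, bead)
            trial = pos.copy()
            trial[:, bead] += rng.normal(scale=step, size=(n_samples, 3))
            e1 = local_energy(trial, bead)
            acc = rng.random(n_samples) < np.exp(-(e1 - e0) / kt)
            pos[acc, bead] = trial[acc, bead]
    pos -= pos[:, :1, :]  # core at the origin
    if not dipolar:
        return pos
    # dipole: free-rotor direction, harmonic charge-core-charge angle
    u_plus = rng.normal(size=(n_samples, 3))
    u_plus /= np.linalg.norm(u_plus, axis=1, keepdims=True)
    from .model import K_ANGLE_DIPOLE
    th_grid = np.linspace(math.pi / 2, math.pi, 20001)
    pdf = np.sin(th_grid) * np.exp(
        -0.5 * K_ANGLE_DIPOLE * (th_grid - math.pi) ** 2 / kt)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    theta = np.interp(rng.random(n_samples), cdf, th_grid)
    phi = rng.uniform(0, 2 * math.pi, n_samples)
    # u_minus at angle theta from u_plus, random azimuth
    a = np.where(np.abs(u_plus[:, 2:3]) < 0.9,
                 np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    e1v = np.cross(u_plus, a)
    e1v /= np.linalg.norm(e1v, axis=1, keepdims=True)
    e2v = np.cross(u_plus, e1v)
    u_minus = (np.cos(theta)[:, None] * u_plus
               + np.sin(theta)[:, None] * (np.cos(phi)[:, None] * e1v
                                           + np.sin(phi)[:, None] * e2v))
    qp = D_CHARGE * u_plus
    qm = D_CHARGE * u_minus
    return np.concatenate([pos, qp[:, None, :], qm[:, None, :]], axis=1)


def dimer_free_energy_oracle(species: str = "M",
                             r_values: np.ndarray | None = None,
                             n_samples: int = 200_000, seed: int = 0,
                             box_edge: float = METAD_BOX_EDGE,
                             temperature: float = 300.0,
                             restrain_dipole: bool = False,
                             batch: int = 50_000) -> FreeEnergyProfile:
    """Orientation-averaged Boltzmann integration of the rigid dimer.

    Uses the exact free-energy perturbation identity

        F(r) - F(inf) = -kT ln < exp(-U_inter/kT) >_0

    where the average runs over the *non-interacting* pair ensemble:
    uniformly random molecular orientations and separation directions,
    independent dipole directions, and internal conformations drawn from
    the isolated-molecule Boltzmann ensemble (the floppy out-of-plane
    modes matter at this precision; see
    :func:`sample_internal_ensemble`).  Minimum-image distances are
    taken in the same box as the dynamics.

    This is the volume-corrected pair free energy (no radial 2 kT ln r
    term), zeroed at the largest r requested.  dU(r) is the matching
    conditional Boltzmann average of U_inter.
    """
    if r_values is None:
        r_values = np.linspace(0.42, 1.5, 37)
    r_values = np.asarray(r_values, dtype=float)
    kt = KB * temperature
    topo = build_monomer(species)
    table = build_interaction_table({species})
    classes = sorted({b.vdw_class for b in topo.beads})
    cls_of = np.array([classes.index(b.vdw_class) for b in topo.beads])
    eps, sig, style = table.to_arrays(classes)
    rc = table.cutoff
    src = (sig / rc) ** 6
    ushift = 4.0 * eps * (src * src - src)
    q = np.array([b.charge for b in topo.beads])
    fq = F_COULOMB / table.epsilon_r if table.coulomb else 0.0
    dipolar = species in ("Mcoop", "McoopR")

    rng = np.random.default_rng(seed)
    n_pool = 8192
    # fixed pool seeds: the conformation pools are a reusable quadrature
    # set; the oracle's own seed drives orientations and pool indices
    pool1 = sample_internal_ensemble(species, n_pool, 1234, temperature)
    pool2 = sample_internal_ensemble(species, n_pool, 5678, temperature)
    if dipolar and restrain_dipole:
        # molecule 1: dipole pinned along the (fluctuating) ring normal
        d1n = np.cross(pool1[:, 1] - pool1[:, 4], pool1[:, 2] - pool1[:, 5])
        d1n /= np.linalg.norm(d1n, axis=1, keepdims=True)
        pool1[:, 7] = +D_CHARGE * d1n
        pool1[:, 8] = -D_CHARGE * d1n
    logZ = np.zeros_like(r_values)
    u_cond = np.zeros_like(r_values)

    def rand_rot(n):
        qv = rng.normal(size=(n, 4))
        qv /= np.linalg.norm(qv, axis=1, keepdims=True)
        w, x, y, z = qv.T
        R = np.empty((n, 3, 3))
        R[:, 0, 0] = 1 - 2 * (y * y + z * z)
        R[:, 0, 1] = 2 * (x * y - w * z)
        R[:, 0, 2] = 2 * (x * z + w * y)
        R[:, 1, 0] = 2 * (x * y + w * z)
        R[:, 1, 1] = 1 - 2 * (x * x + z * z)
        R[:, 1, 2] = 2 * (y * z - w * x)
        R[:, 2, 0] = 2 * (x * z - w * y)
        R[:, 2, 1] = 2 * (y * z + w * x)
        R[:, 2, 2] = 1 - 2 * (x * x + y * y)
        return R

    def rand_dir(n):
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    nb = len(topo.beads)
    eps_pair = eps[cls_of[:, None], cls_of[None, :]]
    sig_pair = sig[cls_of[:, None], cls_of[None, :]]
    sty_pair = style[cls_of[:, None], cls_of[None, :]]
    shift_pair = ushift[cls_of[:, None], cls_of[None, :]]
    qq_pair = fq * q[:, None] * q[None, :]

    for ir, rv in enumerate(r_values):
        log_terms = []
        uw_num = 0.0
        uw_den = 0.0
        done = 0
        while done < n_samples:
            nsb = min(batch, n_samples - done)
            done += nsb
            R1 = rand_rot(nsb)
            R2 = rand_rot(nsb)
            sep = rand_dir(nsb) * rv
            c1 = pool1[rng.integers(0, n_pool, nsb)]
            c2 = pool2[rng.integers(0, n_pool, nsb)]
            p1 = np.einsum("sij,sbj->sbi", R1, c1)
            p2 = np.einsum("sij,sbj->sbi", R2, c2) + sep[:, None, :]
            delta = p1[:, :, None, :] - p2[:, None, :, :]
            delta -= box_edge * np.round(delta / box_edge)
            r2 = (delta * delta).sum(axis=-1)
            U = np.zeros(nsb)
            # vdW
            for a in range(nb):
                for b in range(nb):
                    st = sty_pair[a, b]
                    if st == 0:
                        continue
                    ep = eps_pair[a, b]
                    sg = sig_pair[a, b]
                    if st == 1:
                        rcut2 = rc * rc
                        shift = shift_pair[a, b]
                    else:
                        rw = 2.0 ** (1.0 / 6.0) * sg
                        rcut2 = rw * rw
                        shift = -ep
                    rr = r2[:, a, b]
                    in_rng = rr < rcut2
                    sr2 = np.where(in_rng, sg * sg / np.maximum(rr, 1e-12),
                                   0.0)
                    sr6 = sr2 ** 3
                    U += np.where(in_rng,
                                  4.0 * ep * (sr6 * sr6 - sr6) - shift, 0.0)
            if fq != 0.0:
                for a in range(nb):
                    for b in range(nb):
                        qq = qq_pair[a, b]
                        if qq == 0.0:
                            continue
                        rr = np.sqrt(r2[:, a, b])
                        in_rng = rr < rc
                        U += np.where(in_rng, qq * (1.0 / rr - 1.0 / rc),
                                      0.0)
            lw = -U / kt
            m = lw.max()
            log_terms.append((m, np.exp(lw - m).sum(), nsb))
            w = np.exp(lw - m)
            uw_num += (U * w).sum() * math.exp(m)
            uw_den += w.sum() * math.exp(m)
        M = max(t[0] for t in log_terms)
        total = sum(t[1] * math.exp(t[0] - M) for t in log_terms)
        n_tot = sum(t[2] for t in log_terms)
        logZ[ir] = M + math.log(total / n_tot)
        u_cond[ir] = uw_num / uw_den
    dF = -kt * logZ
    dF -= dF[-1]
    dU = u_cond - u_cond[-1]
    return FreeEnergyProfile(r_values, dF, dU, dF - dU,
                             meta={"oracle": True, "n_samples": n_samples,
                                   "species": species,
                                   "restrain_dipole": restrain_dipole})
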