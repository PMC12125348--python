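"""Synthetic fixtures: planted Markov chains, ideal fibres, scripted events.

Three generators make every analysis module testable without running any
dynamics:

* per-monomer Markov aggregation-state series sampled from a planted
  (known) transition matrix, for estimator-recovery and
  Chapman-Kolmogorov tests;
* ideal fibre configurations with monomers stacked at the LJ-minimum
  spacing 2^(1/6) sigma;
* scripted bead-level scenarios, one per supramolecular event class,
  each carrying its ground-truth aggregation sizes, traffic and event
  labels.  Scenarios serialise to the standard trajectory container, so
  downstream analyses cannot distinguish them from simulations.

Planted chains evolve each monomer independently (no global size
conservation) - a deliberate simplification adequate for testing the
transition-matrix estimators, not a model of coupled assembly dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aggregation import AggregationStateSeries
from .model import R_HEX, System, build_interaction_table, build_monomer
from .trajectory import Trajectory, roles_for_species

STACK_SPACING = 2.0 ** (1.0 / 6.0) * R_HEX  # nm, LJ-minimum core spacing


# ---------------------------------------------------------------------------
# planted Markov chains


@dataclass
class PlantedChainSpec:
    """Recipe for a synthetic aggregation-state series with known truth."""

    transition_matrix: np.ndarray  # row-stochastic (S, S)
    state_sizes: list  # assembly size represented by each state
    n_monomers: int
    n_frames: int
    seed: int
    dt_ns: float = 0.3
    init: str = "stationary"  # or "uniform"

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must be non-negative "
                             "and sum to 1")
        if len(self.state_sizes) != P.shape[0]:
            raise ValueError("state_sizes length mismatch")
        self.transition_matrix = P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalised."""
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def planted_markov_series(spec: PlantedChainSpec
                          ) -> tuple[AggregationStateSeries, dict]:
    """Sample independent per-monomer chains from the planted matrix.

    Returns the state series (sizes are ``state_sizes[state]``) and a
    truth record with the planted matrix and the generator settings.
    Bit-reproducible for a fixed seed.
    """
    P = spec.transition_matrix
    S = P.shape[0]
    rng = np.random.default_rng(spec.seed)
    cum = np.cumsum(P, axis=1)
    states = np.empty((spec.n_monomers, spec.n_frames), dtype=np.int64)
    if spec.init == "stationary":
        pi = stationary_distribution(P)
    elif spec.init == "uniform":
        pi = np.full(S, 1.0 / S)
    else:
        raise ValueError(f"unknown init {spec.init!r}")
    states[:, 0] = rng.choice(S, size=spec.n_monomers, p=pi)
    for f in range(1, spec.n_frames):
        u = rng.random(spec.n_monomers)
        rows = cum[states[:, f - 1]]
        states[:, f] = (u[:, None] > rows).sum(axis=1)
    sizes = np.asarray(spec.state_sizes, dtype=np.int64)[states]
    series = AggregationStateSeries(sizes=sizes, dt_ns=spec.dt_ns,
                                    meta={"planted": True,
                                          "seed": spec.seed})
    truth = {"transition_matrix": P, "state_sizes": list(spec.state_sizes),
             "initial_distribution": pi, "seed": spec.seed}
    return series, truth


# ---------------------------------------------------------------------------
# ideal fibres


def ideal_fibre(n: int, species: str = "M", box_edge: float | None = None,
                axis_offset: tuple[float, float] = (0.0, 0.0)) -> System:
    """A fibre of ``n`` monomers stacked at the LJ-minimum spacing.

    Monomers stack along z with their hexagon planes perpendicular to the
    fibre axis; for Mcoop the dipoles are aligned head-to-tail.  The
    returned system has zero velocities (a static fixture).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if box_edge is None:
        box_edge = max(4.0, n * STACK_SPACING + 3.0)
    topo = build_monomer(species)
    table = build_interaction_table({species})
    from .model import _assemble  # shared flattening path
    rng = np.random.default_rng(0)
    x0, y0 = axis_offset
    centre = box_edge / 2.0
    molecules = []
    for k in range(n):
        pos = np.array([centre + x0, centre + y0,
                        centre + (k - (n - 1) / 2.0) * STACK_SPACING])
        molecules.append((species, topo, pos, np.eye(3)))
    system = _assemble(molecules, box_edge, table, 300.0, rng)
    system.velocities[:] = 0.0
    return system


# ---------------------------------------------------------------------------
# scripted scenarios


@dataclass
class ScriptedScenario:
    """A frame-by-frame coordinate script with its ground truth.

    ``expected_sizes`` is (n_monomers, n_frames); ``expected_events`` is
    a sorted list of (frame, event_class, multimeric) tuples as produced
    by the event classifier; ``expected_traffic`` the final cumulative
    count of bond formation/rupture events.
    """

    name: str
    description: str
    trajectory: Trajectory
    expected_sizes: np.ndarray
    expected_events: list
    expected_traffic: int
    meta: dict = field(default_factory=dict)


def _traj_from_cores(core_frames: list[np.ndarray], box_edge: float = 30.0,
                     dt_ns: float = 0.3, species: str = "M") -> Trajectory:
    """Expand scripted core positions into full-molecule frames."""
    topo = build_monomer(species)
    n_mol = core_frames[0].shape[0]
    n_beads = topo.n_beads
    frames = []
    for cores in core_frames:
        pos = np.empty((n_mol * n_beads, 3))
        for m in range(n_mol):
            pos[m * n_beads:(m + 1) * n_beads] = topo.coords + cores[m]
        frames.append(pos)
    roles = np.concatenate([roles_for_species(species)] * n_mol)
    return Trajectory(
        positions=np.asarray(frames),
        times=np.arange(len(frames)) * dt_ns,
        box_edge=box_edge,
        mol=np.repeat(np.arange(n_mol), n_beads),
        species=[species] * n_mol,
        core_idx=np.arange(n_mol) * n_beads,
        roles=roles,
        masses=np.tile([b.mass for b in topo.beads], n_mol),
        unwrapped=True,
        meta={"scripted": True})


def _line(n: int, spacing: float = 0.53, z0: float = 0.0) -> np.ndarray:
    cores = np.zeros((n, 3))
    cores[:, 2] = z0 + np.arange(n) * spacing
    return cores


def _arc(n: int, n_slots: int, spacing: float = 0.53) -> np.ndarray:
    """n points of a regular n_slots-gon with the given side length."""
    r = spacing / (2.0 * math.sin(math.pi / n_slots))
    ang = 2.0 * math.pi * np.arange(n) / n_slots
    cores = np.zeros((n, 3))
    cores[:, 0] = r * np.cos(ang)
    cores[:, 2] = r * np.sin(ang)
    return cores


def scripted_scenarios() -> list[ScriptedScenario]:
    """The scenario suite: one script per event class plus hysteresis."""
    scenarios = []
    s = 0.53  # intra-fibre core spacing, below r_b

    # -- free monomer binds to a fibre tip ---------------------------------
    fib = _line(5)
    tip = fib[-1, 2]
    cores = []
    for dz in (3.0, 1.5, 0.55):
        c = np.vstack([fib, [0.0, 0.0, tip + dz]])
        cores.append(c)
    sizes = np.array([[5, 5, 6]] * 5 + [[1, 1, 6]])
    scenarios.append(ScriptedScenario(
        "monomer_binding",
        "a free monomer approaches and binds the tip of a pentamer",
        _traj_from_cores(cores), sizes,
        [(2, "monomer_exchange", False)], 1))

    # -- tip monomer unbinds -----------------------------------------------
    cores_rev = [cores[2], cores[2], cores[0]]
    sizes = np.array([[6, 6, 5]] * 5 + [[6, 6, 1]])
    scenarios.append(ScriptedScenario(
        "monomer_unbinding",
        "the tip monomer detaches from a hexamer and diffuses away",
        _traj_from_cores(cores_rev), sizes,
        [(2, "monomer_exchange", False)], 1))

    # -- fibre fission ------------------------------------------------------
    whole = _line(10)
    split = whole.copy()
    split[5:, 2] += 1.0  # gap 1.53 nm, beyond r_u
    cores = [whole, whole, split, split]
    sizes = np.array([[10, 10, 5, 5]] * 10)
    scenarios.append(ScriptedScenario(
        "fibre_fission",
        "a 10-mer breaks into two pentamers",
        _traj_from_cores(cores), sizes,
        [(2, "fibre_poly_depoly", True)], 1))

    # -- fibre fusion -------------------------------------------------------
    a = _line(4)
    b = _line(4, z0=3 * s + 2.0)
    b_close = _line(4, z0=3 * s + 0.55)
    cores = [np.vstack([a, b])] * 2 + [np.vstack([a, b_close])]
    sizes = np.array([[4, 4, 8]] * 8)
    scenarios.append(ScriptedScenario(
        "fibre_fusion",
        "two tetramers join end-to-end into an octamer",
        _traj_from_cores(cores), sizes,
        [(2, "fibre_poly_depoly", True)], 1))

    # -- fibre bending / straightening --------------------------------------
    line9 = _line(9)
    arc_open = _arc(9, 10)  # ends ~1.0 nm apart: no contact
    ring = _arc(9, 9)       # ends at bond distance: contact forms
    cores = [line9, arc_open, ring, arc_open, line9]
    sizes = np.full((9, 5), 9)
    scenarios.append(ScriptedScenario(
        "bend_straighten",
        "a 9-mer curls until its ends touch, then straightens again",
        _traj_from_cores(cores), sizes,
        [(2, "bend_straighten", False), (3, "bend_straighten", False)], 2))

    # -- branching -----------------------------------------------------------
    fib6 = _line(6)
    mid_z = (fib6[2, 2] + fib6[3, 2]) / 2.0
    x_off = math.sqrt(0.55 ** 2 - (s / 2.0) ** 2)
    far = np.vstack([fib6, [2.5, 0.0, mid_z]])
    docked = np.vstack([fib6, [x_off, 0.0, mid_z]])
    cores = [far, far, docked, far]
    sizes = np.array([[6, 6, 7, 6]] * 6 + [[1, 1, 7, 1]])
    scenarios.append(ScriptedScenario(
        "branch",
        "a monomer docks sideways onto two mid-fibre monomers, forming "
        "and then losing a three-centre junction",
        _traj_from_cores(cores), sizes,
        [(2, "branch", False), (3, "branch", False)], 4))

    # -- four-centre branching ----------------------------------------------
    d1 = np.array([[0.0, 0.0, 0.0], [s, 0.0, 0.0]])
    d2_far = d1 + [0.0, 3.0, 0.0]
    d2_close = d1 + [0.0, 0.55, 0.0]
    cores = [np.vstack([d1, d2_far])] * 2 + [np.vstack([d1, d2_close])]
    sizes = np.array([[2, 2, 4]] * 4)
    scenarios.append(ScriptedScenario(
        "four_centre_branch",
        "two dimers cross-link side-by-side into a four-centre junction",
        _traj_from_cores(cores), sizes,
        [(2, "four_centre_branch", True)], 2))

    # -- hysteresis oscillation ----------------------------------------------
    def pair(d):
        return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]])

    cores = [pair(0.70), pair(0.55), pair(0.65), pair(0.85),
             pair(0.65), pair(0.85)]
    sizes = np.array([[1, 2, 2, 2, 2, 2]] * 2)
    scenarios.append(ScriptedScenario(
        "hysteresis_oscillation",
        "a dimer binds once, then oscillates between the cutoffs without "
        "ever unbinding",
        _traj_from_cores(cores), sizes,
        [(1, "monomer_exchange", False)], 1))

    # -- dimer break by distance ramp ----------------------------------------
    cores = [pair(d) for d in (0.50, 0.70, 0.85, 0.95, 1.20)]
    sizes = np.array([[2, 2, 2, 1, 1]] * 2)
    scenarios.append(ScriptedScenario(
        "dimer_break_ramp",
        "a bound dimer is pulled apart past the unbinding cutoff at "
        "frame 3",
        _traj_from_cores(cores), sizes,
        [(3, "monomer_exchange", False)], 1))

    return scenarios
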