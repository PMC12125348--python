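"""Minimalistic coarse-grained monomer models and system assembly.

Five species are constructible:

``M``
    Non-cooperative (isodesmic) monomer: a planar hexagon of six shielding
    beads around a central core bead.  Cores of different molecules attract
    via a Lennard-Jones potential (eps = 45 kJ/mol, sigma = 0.47 nm);
    shielding beads are purely repulsive and force stacking along the
    hexagon axis.
``Mcoop``
    Cooperative variant: same hexagon, weaker core-core attraction
    (eps = 20 kJ/mol) plus a freely rotating dipole of two charged beads
    (q = +-1.4 e) held at 0.14 nm on either side of the core.  Dipole beads
    carry no excluded volume and interact only via Coulomb forces with
    other dipoles.
``C``
    Chain stopper: an M monomer with one extra shielding bead on the
    hexagon axis next to the core.  The cap bead interacts weakly
    (eps = 0.2 kJ/mol) with everything and blocks stacking on that face.
``MR`` / ``McoopR``
    Purely repulsive references: identical topologies with all attractions
    removed (LJ truncated and shifted at its minimum, i.e. WCA) and dipole
    charges set to zero.

All lengths are nm, energies kJ/mol, masses amu, charges in e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import KB, N_AVOGADRO, NM3_PER_LITRE

SPECIES = ("M", "Mcoop", "C", "MR", "McoopR")

#: circumradius of the hexagon == nearest-neighbour bond length, nm
R_HEX = 0.47
K_BOND_NN = 20_000.0  # kJ mol^-1 nm^-2
K_BOND_CROSS = 15_000.0
R0_CROSS = 0.94
SIGMA = 0.47
EPS_CORE_M = 45.0
EPS_CORE_COOP = 20.0
EPS_CAP = 0.2
#: shield-bead repulsion strength (WCA); shown only graphically in the
#: source model, kept configurable here
EPS_SHIELD = 45.0
Q_DIPOLE = 1.4
D_CHARGE = 0.14  # core-to-charge-bead distance, nm
K_ANGLE_DIPOLE = 1500.0  # kJ mol^-1 rad^-2
DEFAULT_BEAD_MASS = 72.0  # amu; never stated by the model, configurable
DEFAULT_CUTOFF = 1.1  # nm

_CORE_CLASS = {"M": "core_m", "Mcoop": "core_coop", "C": "core_c",
               "MR": "core_m", "McoopR": "core_coop"}
_REPULSIVE = {"MR", "McoopR"}


class UnknownSpeciesError(ValueError):
    pass


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class BeadSpec:
    """One bead of a monomer topology."""

    name: str
    role: str  # core | shield | cap_shield | charge
    mass: float
    charge: float
    vdw_class: str

    def __post_init__(self):
        if self.charge != 0.0 and self.role != "charge":
            raise ValueError(f"bead {self.name}: only charge beads may carry charge")


@dataclass
class MonomerTopology:
    """Beads, body-frame geometry and bonded terms of one molecule."""

    species: str
    beads: list[BeadSpec]
    coords: np.ndarray  # (n_beads, 3) body frame, nm
    bonds: list[tuple[int, int, float, float]]  # i, j, k (kJ/mol/nm^2), r0 (nm)
    angles: list[tuple[int, int, int, float, float]]  # i, j, k, kf, theta0 (deg)
    constraints: list[tuple[int, int, float]]  # i, j, distance (nm)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def mass(self) -> float:
        return sum(b.mass for b in self.beads)


def _hexagon(mass: float) -> tuple[list[BeadSpec], list[np.ndarray],
                                    list[tuple[int, int, float, float]]]:
    beads = [BeadSpec("CORE", "core", mass, 0.0, "core")]
    coords = [np.zeros(3)]
    for k in range(6):
        a = math.pi / 3.0 * k
        beads.append(BeadSpec(f"SH{k + 1}", "shield", mass, 0.0, "shield"))
        coords.append(np.array([R_HEX * math.cos(a), R_HEX * math.sin(a), 0.0]))
    bonds = [(0, k, K_BOND_NN, R_HEX) for k in range(1, 7)]
    bonds += [(k, k % 6 + 1, K_BOND_NN, R_HEX) for k in range(1, 7)]
    bonds += [(k, k + 3, K_BOND_CROSS, R0_CROSS) for k in range(1, 4)]
    return beads, coords, bonds


def build_monomer(species: str, bead_mass: float = DEFAULT_BEAD_MASS) -> MonomerTopology:
    """Construct the topology of one monomer of the given species.

    The hexagon lies in the body-frame xy plane (core at the origin);
    the chain-stopper cap bead and the Mcoop dipole sit on the +-z axis.
    """
    if species not in SPECIES:
        raise UnknownSpeciesError(
            f"unknown species {species!r}; expected one of {SPECIES}")
    beads, coords, bonds = _hexagon(bead_mass)
    core_cls = _CORE_CLASS[species]
    beads[0] = replace(beads[0], vdw_class=core_cls)
    angles: list[tuple[int, int, int, float, float]] = []
    constraints: list[tuple[int, int, float]] = []
    if species in ("Mcoop", "McoopR"):
        q = Q_DIPOLE if species == "Mcoop" else 0.0
        qmass = bead_mass / 3.0
        beads.append(BeadSpec("QP", "charge", qmass, +q, "charge"))
        coords.append(np.array([0.0, 0.0, +D_CHARGE]))
        beads.append(BeadSpec("QM", "charge", qmass, -q, "charge"))
        coords.append(np.array([0.0, 0.0, -D_CHARGE]))
        constraints += [(0, 7, D_CHARGE), (0, 8, D_CHARGE)]
        angles.append((7, 0, 8, K_ANGLE_DIPOLE, 180.0))
    elif species == "C":
        beads.append(BeadSpec("CAP", "cap_shield", bead_mass, 0.0, "cap"))
        coords.append(np.array([0.0, 0.0, R_HEX]))
        bonds.append((0, 7, K_BOND_NN, R_HEX))
        d_sv = math.sqrt(2.0) * R_HEX  # cap to hexagon vertex
        bonds += [(k, 7, K_BOND_NN, d_sv) for k in range(1, 7)]
    return MonomerTopology(species, beads, np.asarray(coords, dtype=float),
                           bonds, angles, constraints)


# ---------------------------------------------------------------------------
# interaction table


@dataclass(frozen=True)
class PairPotential:
    epsilon: float  # kJ/mol
    sigma: float  # nm
    style: str  # lj_cut_shift | wca | none


@dataclass
class InteractionTable:
    """Pairwise non-bonded parameters keyed by vdW class.

    ``coulomb`` enables charge-charge electrostatics (truncated-shifted,
    acting only between dipole beads).  ``pairs`` is keyed by sorted class
    tuples; charge beads never appear with a van der Waals term.
    """

    pairs: dict[tuple[str, str], PairPotential]
    coulomb: bool
    cutoff: float = DEFAULT_CUTOFF
    #: implicit-solvent relative dielectric screening the dipole charges.
    #: With unscreened charges (+-1.4 e at sub-nm separations) the dipole
    #: term would exceed the LJ scale twentyfold and freeze the dynamics;
    #: the Martini-style value 15 puts stacked-dipole attraction at the
    #: ~25 kJ/mol scale that lets eps=20 cores mimic the eps=45 model.
    epsilon_r: float = 15.0

    def get(self, cls_a: str, cls_b: str) -> PairPotential:
        return self.pairs[tuple(sorted((cls_a, cls_b)))]

    def to_arrays(self, class_names: list[str]):
        """Dense (eps, sigma, style-code) matrices for the force kernels.

        Style codes: 0 = no vdW, 1 = LJ truncated & potential-shifted at
        the table cutoff, 2 = WCA (truncated & shifted at 2^(1/6) sigma).
        """
        n = len(class_names)
        eps = np.zeros((n, n))
        sig = np.full((n, n), SIGMA)
        style = np.zeros((n, n), dtype=np.int64)
        code = {"none": 0, "lj_cut_shift": 1, "wca": 2}
        for i, a in enumerate(class_names):
            for j, b in enumerate(class_names):
                p = self.get(a, b)
                eps[i, j] = p.epsilon
                sig[i, j] = p.sigma
                style[i, j] = code[p.style]
        return eps, sig, style


_CORE_EPS = {
    ("core_m", "core_m"): EPS_CORE_M,
    ("core_c", "core_c"): EPS_CORE_M,
    ("core_c", "core_m"): EPS_CORE_M,
    ("core_c", "core_coop"): EPS_CORE_M,
    ("core_coop", "core_coop"): EPS_CORE_COOP,
    ("core_coop", "core_m"): EPS_CORE_M,  # only reachable with allow_mixed
}


def build_interaction_table(species_set, allow_mixed: bool = False,
                            cutoff: float = DEFAULT_CUTOFF,
                            shield_eps: float = EPS_SHIELD) -> InteractionTable:
    """Build the non-bonded table covering every class pair of the system.

    Mixing M and Mcoop in one system is rejected unless ``allow_mixed``;
    likewise the purely repulsive references are never combined with
    attractive species.
    """
    species_set = set(species_set)
    if not species_set:
        raise ValueError("empty species set")
    unknown = species_set - set(SPECIES)
    if unknown:
        raise UnknownSpeciesError(f"unknown species {sorted(unknown)}")
    if {"M", "Mcoop"} <= species_set and not allow_mixed:
        raise ValueError("M and Mcoop are never co-simulated; "
                         "pass allow_mixed=True to override")
    repulsive = bool(species_set & _REPULSIVE)
    if repulsive and (species_set - _REPULSIVE):
        raise ValueError("repulsive reference species cannot be mixed with "
                         "attractive ones")

    classes = {"charge"} if species_set & {"Mcoop", "McoopR"} else set()
    classes |= {_CORE_CLASS[s] for s in species_set}
    classes |= {"shield"}
    if "C" in species_set:
        classes |= {"cap"}

    attr_style = "wca" if repulsive else "lj_cut_shift"
    pairs: dict[tuple[str, str], PairPotential] = {}
    for a in sorted(classes):
        for b in sorted(classes):
            if a > b:
                continue
            key = (a, b)
            if "charge" in key:
                pairs[key] = PairPotential(0.0, SIGMA, "none")
            elif "cap" in key:
                pairs[key] = PairPotential(EPS_CAP, SIGMA, attr_style)
            elif "shield" in key:
                pairs[key] = PairPotential(shield_eps, SIGMA, "wca")
            else:
                pairs[key] = PairPotential(_CORE_EPS[key], SIGMA, attr_style)
    coulomb = "Mcoop" in species_set
    return InteractionTable(pairs=pairs, coulomb=coulomb, cutoff=cutoff)


# ---------------------------------------------------------------------------
# systems


@dataclass
class SystemSpec:
    """Declarative description of one simulation system."""

    counts: dict[str, int]
    box_edge: float  # nm, cubic
    temperature: float = 300.0
    seed: int = 0
    placement_min_distance: float = 0.8  # nm, core-core

    def __post_init__(self):
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative molecule count")
        if not any(self.counts.get(s, 0) > 0 for s in SPECIES if s != "C"):
            raise ValueError("at least one self-assembling species required")


@dataclass
class System:
    """Engine-ready state: flat per-bead arrays plus topology indices.

    Positions are kept unwrapped; the minimum-image convention is applied
    when computing distances, so molecules always stay whole in memory.
    """

    positions: np.ndarray  # (N, 3) nm
    velocities: np.ndarray  # (N, 3) nm/ps
    box_edge: float
    masses: np.ndarray
    charges: np.ndarray
    cls_idx: np.ndarray  # (N,) index into class_names
    class_names: list[str]
    mol: np.ndarray  # (N,) molecule index
    species: list[str]  # per molecule
    bonds: np.ndarray  # (nb, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray  # (na, 3) int
    angle_k: np.ndarray
    angle_theta0: np.ndarray  # radians
    constraints: np.ndarray  # (nc, 2) int
    constraint_d: np.ndarray
    table: InteractionTable
    time: float = 0.0  # ns
    meta: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def core_indices(self) -> np.ndarray:
        """Bead index of the core of each molecule."""
        return np.asarray(self.meta["core_idx"], dtype=np.int64)

    @property
    def assembling(self) -> np.ndarray:
        """Boolean mask over molecules: True for self-assembling species."""
        return np.array([s != "C" for s in self.species])

    def copy(self) -> "System":
        return System(
            self.positions.copy(), self.velocities.copy(), self.box_edge,
            self.masses, self.charges, self.cls_idx, self.class_names,
            self.mol, list(self.species), self.bonds, self.bond_k,
            self.bond_r0, self.angles, self.angle_k, self.angle_theta0,
            self.constraints, self.constraint_d, self.table, self.time,
            dict(self.meta))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _min_image_dist(delta: np.ndarray, box: float) -> np.ndarray:
    delta = delta - box * np.round(delta / box)
    return np.sqrt((delta * delta).sum(axis=-1))


def _assemble(molecules: list[tuple[str, MonomerTopology, np.ndarray, np.ndarray]],
              box_edge: float, table: InteractionTable, temperature: float,
              rng: np.random.Generator) -> System:
    """Flatten per-molecule topologies into a System with MB velocities."""
    pos, masses, charges, cls, mol_idx, species = [], [], [], [], [], []
    bonds, bond_k, bond_r0 = [], [], []
    angles, angle_k, angle_t0 = [], [], []
    cons, cons_d = [], []
    core_idx = []
    class_names = sorted({b.vdw_class for _, t, _, _ in molecules for b in t.beads})
    cls_of = {c: i for i, c in enumerate(class_names)}
    off = 0
    for im, (sp, topo, centre, rot) in enumerate(molecules):
        coords = topo.coords @ rot.T + centre
        for b, xyz in zip(topo.beads, coords):
            pos.append(xyz)
            masses.append(b.mass)
            charges.append(b.charge)
            cls.append(cls_of[b.vdw_class])
            mol_idx.append(im)
        core_idx.append(off)  # core is always bead 0 of the molecule
        species.append(sp)
        for i, j, k, r0 in topo.bonds:
            bonds.append((off + i, off + j)); bond_k.append(k); bond_r0.append(r0)
        for i, j, k, kf, t0 in topo.angles:
            angles.append((off + i, off + j, off + k))
            angle_k.append(kf); angle_t0.append(math.radians(t0))
        for i, j, d in topo.constraints:
            cons.append((off + i, off + j)); cons_d.append(d)
        off += topo.n_beads
    masses = np.asarray(masses)
    vel = rng.normal(size=(off, 3)) * np.sqrt(KB * temperature / masses)[:, None]
    return System(
        positions=np.asarray(pos), velocities=vel, box_edge=box_edge,
        masses=masses, charges=np.asarray(charges),
        cls_idx=np.asarray(cls, dtype=np.int64), class_names=class_names,
        mol=np.asarray(mol_idx, dtype=np.int64), species=species,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_k=np.asarray(bond_k), bond_r0=np.asarray(bond_r0),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        angle_k=np.asarray(angle_k), angle_theta0=np.asarray(angle_t0),
        constraints=np.asarray(cons, dtype=np.int64).reshape(-1, 2),
        constraint_d=np.asarray(cons_d), table=table,
        meta={"core_idx": core_idx, "temperature": temperature})


def _place_molecules(specs: list[tuple[str, MonomerTopology]], box: float,
                     min_dist: float, rng: np.random.Generator,
                     existing_cores: np.ndarray | None = None,
                     max_attempts: int = 500):
    placed = []
    cores = ([] if existing_cores is None else list(existing_cores))
    for n_done, (sp, topo) in enumerate(specs):
        for attempt in range(max_attempts):
            centre = rng.uniform(0.0, box, size=3)
            if not cores or _min_image_dist(np.asarray(cores) - centre, box).min() >= min_dist:
                placed.append((sp, topo, centre, _random_rotation(rng)))
                cores.append(centre)
                break
        else:
            raise PackingError(
                f"could not place molecule {n_done + 1}/{len(specs)} at "
                f"min core-core distance {min_dist} nm in a {box} nm box; "
                f"{n_done} molecules are achievable")
    return placed


def build_system(spec: SystemSpec, bead_mass: float = DEFAULT_BEAD_MASS,
                 allow_mixed: bool = False) -> System:
    """Place the requested molecules uniformly at random in the box.

    Random positions and orientations are drawn from a generator seeded
    with ``spec.seed``; velocities follow the Maxwell-Boltzmann
    distribution at ``spec.temperature``.  Identical specs give
    bit-identical systems.
    """
    counts = {s: int(spec.counts.get(s, 0)) for s in SPECIES}
    table = build_interaction_table({s for s, c in counts.items() if c > 0},
                                    allow_mixed=allow_mixed)
    topo = {s: build_monomer(s, bead_mass) for s, c in counts.items() if c > 0}
    mol_specs = [(s, topo[s]) for s in SPECIES for _ in range(counts[s])]
    rng = np.random.default_rng(spec.seed)
    placed = _place_molecules(mol_specs, spec.box_edge,
                              spec.placement_min_distance, rng)
    sysm = _assemble(placed, spec.box_edge, table, spec.temperature, rng)
    sysm.meta["seed"] = spec.seed
    return sysm


def insert_stoppers(system: System, n_c: int, seed: int,
                    min_distance: float | None = None,
                    bead_mass: float = DEFAULT_BEAD_MASS) -> System:
    """Add chain-stopper molecules at random non-overlapping positions.

    Existing coordinates and velocities are untouched; the returned system
    records the insertion provenance (seed and count) in its metadata.
    """
    if n_c == 0:
        return system.copy()
    if min_distance is None:
        min_distance = 0.8
    rng = np.random.default_rng(seed)
    topo_c = build_monomer("C", bead_mass)
    cores = system.positions[system.core_indices]
    placed = _place_molecules([("C", topo_c)] * n_c, system.box_edge,
                              min_distance, rng, existing_cores=cores)
    species_new = {s for s in system.species} | {"C"}
    table = build_interaction_table(species_new)
    temp = system.meta.get("temperature", 300.0)
    add = _assemble(placed, system.box_edge, table, temp, rng)

    # merge: re-index classes of the combined system
    class_names = sorted(set(system.class_names) | set(add.class_names))
    remap_old = np.array([class_names.index(c) for c in system.class_names])
    remap_new = np.array([class_names.index(c) for c in add.class_names])
    n0, m0 = system.n_beads, system.n_molecules
    merged = System(
        positions=np.vstack([system.positions, add.positions]),
        velocities=np.vstack([system.velocities, add.velocities]),
        box_edge=system.box_edge,
        masses=np.concatenate([system.masses, add.masses]),
        charges=np.concatenate([system.charges, add.charges]),
        cls_idx=np.concatenate([remap_old[system.cls_idx], remap_new[add.cls_idx]]),
        class_names=class_names,
        mol=np.concatenate([system.mol, add.mol + m0]),
        species=list(system.species) + list(add.species),
        bonds=np.vstack([system.bonds, add.bonds + n0]),
        bond_k=np.concatenate([system.bond_k, add.bond_k]),
        bond_r0=np.concatenate([system.bond_r0, add.bond_r0]),
        angles=np.vstack([system.angles, add.angles + n0]) if system.angles.size or add.angles.size
               else system.angles,
        angle_k=np.concatenate([system.angle_k, add.angle_k]),
        angle_theta0=np.concatenate([system.angle_theta0, add.angle_theta0]),
        constraints=np.vstack([system.constraints, add.constraints + n0]),
        constraint_d=np.concatenate([system.constraint_d, add.constraint_d]),
        table=table, time=system.time,
        meta=dict(system.meta))
    merged.meta["core_idx"] = list(system.meta["core_idx"]) + \
        [i + n0 for i in add.meta["core_idx"]]
    merged.meta["stopper_insertion"] = {"seed": seed, "n_C": n_c}
    return merged


def system_density(n_monomers: int, box_edge: float) -> tuple[float, float]:
    """Number density (nm^-3) and molar concentration (mM) of a cubic box."""
    if n_monomers <= 0 or box_edge <= 0:
        raise ValueError("n_monomers and box_edge must be positive")
    volume = box_edge ** 3
    density = n_monomers / volume
    molar = n_monomers / (volume / NM3_PER_LITRE * N_AVOGADRO)
    return density, molar * 1e3
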