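"""Coordinate, topology-summary and table IO.

Supported coordinate dialects:

* GRO (fixed-width, nm, optional velocities, box line mandatory);
* extended XYZ (``Lattice=...`` and a per-atom molecule column).

Bead naming encodes the species (residue names M, MCP, C, MR, MCPR and
atom names CORE, SH1..SH6, CAP, QP, QM), so a file written by the
builder is re-identified molecule by molecule on reading: the molecular
topology (masses, charges, bonds, angles, constraints) is rebuilt from
the species label, never parsed from coordinates.

The topology summary is a plain-text, self-describing listing of beads,
bonds, angles and constraints, sufficient to rebuild a species in a
general MD engine; reading a written summary reproduces the topology
exactly.
"""

from __future__ import annotations

import math

import numpy as np

from .model import (BeadSpec, MonomerTopology, System,
                    build_interaction_table, build_monomer, _assemble)

_RESNAME = {"M": "M", "Mcoop": "MCP", "C": "C", "MR": "MR", "McoopR": "MCPR"}
_SPECIES_OF = {v: k for k, v in _RESNAME.items()}


class FileFormatError(ValueError):
    pass


def _species_systems(species_list, positions, velocities, box_edge):
    """Rebuild a System from per-molecule species labels + coordinates."""
    table = build_interaction_table(set(species_list))
    topos = {s: build_monomer(s) for s in set(species_list)}
    rng = np.random.default_rng(0)
    mols = [(s, topos[s], np.zeros(3), np.eye(3)) for s in species_list]
    system = _assemble(mols, box_edge, table, 300.0, rng)
    system.positions = np.asarray(positions, dtype=float)
    system.velocities = (np.asarray(velocities, dtype=float)
                         if velocities is not None
                         else np.zeros_like(system.positions))
    return system


def write_gro(path, system: System, title: str = "supracg configuration",
              velocities: bool = True) -> None:
    """Write a GRO file; positions are wrapped into the box for output."""
    pos = np.mod(system.positions, system.box_edge)
    vel = system.velocities
    topos = {s: build_monomer(s) for s in set(system.species)}
    with open(path, "w") as fh:
        fh.write(f"{title}, t= {system.time:.3f} ns\n")
        fh.write(f"{system.n_beads:5d}\n")
        bead = 0
        for im, sp in enumerate(system.species):
            names = [b.name for b in topos[sp].beads]
            for name in names:
                line = (f"{(im + 1) % 100000:5d}{_RESNAME[sp]:<5s}"
                        f"{name:>5s}{(bead + 1) % 100000:5d}"
                        f"{pos[bead, 0]:8.3f}{pos[bead, 1]:8.3f}"
                        f"{pos[bead, 2]:8.3f}")
                if velocities:
                    line += (f"{vel[bead, 0]:8.4f}{vel[bead, 1]:8.4f}"
                             f"{vel[bead, 2]:8.4f}")
                fh.write(line + "\n")
                bead += 1
        fh.write(f"{system.box_edge:10.5f}{system.box_edge:10.5f}"
                 f"{system.box_edge:10.5f}\n")


def read_gro(path) -> System:
    """Read a GRO file written by this package (or an equivalent layout)."""
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise FileFormatError(f"{path}: truncated GRO file")
    try:
        natoms = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise FileFormatError(f"{path}:2: bad atom count line")
    if len(lines) < natoms + 3:
        raise FileFormatError(f"{path}: expected {natoms} atom records and "
                              "a box line; file too short (missing box "
                              "line?)")
    box_fields = lines[natoms + 2].split()
    if len(box_fields) < 3:
        raise FileFormatError(f"{path}:{natoms + 3}: missing or malformed "
                              "box line")
    box = [float(x) for x in box_fields[:3]]
    if not math.isclose(box[0], box[1]) or not math.isclose(box[0], box[2]):
        raise FileFormatError(f"{path}: only cubic boxes are supported")
    species, resnrs = [], []
    positions, velocities = [], []
    names = []
    have_vel = True
    for k in range(natoms):
        ln = lines[2 + k]
        lineno = 3 + k
        try:
            resnr = int(ln[0:5])
            resname = ln[5:10].strip()
            atomname = ln[10:15].strip()
            x, y, z = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except ValueError:
            raise FileFormatError(f"{path}:{lineno}: malformed atom record")
        try:
            vx, vy, vz = (float(ln[44:52]), float(ln[52:60]),
                          float(ln[60:68]))
        except (ValueError, IndexError):
            have_vel = False
            vx = vy = vz = 0.0
        if resname not in _SPECIES_OF:
            raise FileFormatError(f"{path}:{lineno}: unknown residue name "
                                  f"{resname!r}")
        positions.append((x, y, z))
        velocities.append((vx, vy, vz))
        resnrs.append(resnr)
        species.append(_SPECIES_OF[resname])
        names.append(atomname)
    # split into molecules on residue-number change
    mol_species, starts = [], []
    for k in range(natoms):
        if k == 0 or resnrs[k] != resnrs[k - 1]:
            starts.append(k)
            mol_species.append(species[k])
    starts.append(natoms)
    unknown = []
    for m, sp in enumerate(mol_species):
        topo = build_monomer(sp)
        got = names[starts[m]:starts[m + 1]]
        want = [b.name for b in topo.beads]
        if got != want:
            unknown.extend(sorted(set(got) - set(want)))
    if unknown:
        raise FileFormatError(f"{path}: unknown bead names {unknown}")
    system = _species_systems(mol_species, positions,
                              velocities if have_vel else None, box[0])
    return system


def write_xyz(path, system: System, comment_extra: str = "") -> None:
    """Write an extended-XYZ frame (species + mol columns, Lattice record)."""
    L = system.box_edge
    topos = {s: build_monomer(s) for s in set(system.species)}
    with open(path, "w") as fh:
        fh.write(f"{system.n_beads}\n")
        fh.write(
            f'Lattice="{L} 0.0 0.0 0.0 {L} 0.0 0.0 0.0 {L}" '
            'Properties=species:S:1:pos:R:3:mol:I:1:resname:S:1 '
            f'Time={system.time} {comment_extra}'.rstrip() + "\n")
        bead = 0
        for im, sp in enumerate(system.species):
            for b in topos[sp].beads:
                p = system.positions[bead]
                fh.write(f"{b.name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                         f"{im} {_RESNAME[sp]}\n")
                bead += 1


def read_xyz(path) -> System:
    with open(path) as fh:
        lines = fh.readlines()
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FileFormatError(f"{path}:1: bad atom count")
    comment = lines[1]
    if "Lattice=" not in comment:
        raise FileFormatError(f"{path}:2: missing Lattice record")
    lat = comment.split('Lattice="')[1].split('"')[0].split()
    box = float(lat[0])
    species, positions, mols, names = [], [], [], []
    for k in range(natoms):
        parts = lines[2 + k].split()
        if len(parts) < 6:
            raise FileFormatError(f"{path}:{3 + k}: malformed record")
        names.append(parts[0])
        positions.append([float(x) for x in parts[1:4]])
        mols.append(int(parts[4]))
        if parts[5] not in _SPECIES_OF:
            raise FileFormatError(f"{path}:{3 + k}: unknown residue name "
                                  f"{parts[5]!r}")
        species.append(_SPECIES_OF[parts[5]])
    mol_species = []
    for k in range(natoms):
        if k == 0 or mols[k] != mols[k - 1]:
            mol_species.append(species[k])
    return _species_systems(mol_species, positions, None, box)


def read_coordinates(path, dialect: str | None = None) -> System:
    """Read a coordinate file; the dialect defaults from the extension."""
    if dialect is None:
        dialect = "gro" if str(path).endswith(".gro") else "xyz_extended"
    if dialect == "gro":
        return read_gro(path)
    if dialect in ("xyz", "xyz_extended"):
        return read_xyz(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# topology summary


def format_topology(topo: MonomerTopology) -> str:
    """Human- and machine-readable topology listing for one species."""
    out = [f"[monomer {topo.species}]",
           "# beads: index name role mass_amu charge_e vdw_class x_nm y_nm z_nm"]
    for i, (b, xyz) in enumerate(zip(topo.beads, topo.coords)):
        out.append(f"bead {i} {b.name} {b.role} {float(b.mass)!r} "
                   f"{float(b.charge)!r} {b.vdw_class} "
                   f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}")
    out.append("# bonds: i j k_kJ_mol_nm2 r0_nm")
    for i, j, k, r0 in topo.bonds:
        out.append(f"bond {i} {j} {k!r} {r0!r}")
    out.append("# angles: i j k force_kJ_mol theta0_deg")
    for i, j, k, kf, t0 in topo.angles:
        out.append(f"angle {i} {j} {k} {kf!r} {t0!r}")
    out.append("# constraints: i j distance_nm")
    for i, j, d in topo.constraints:
        out.append(f"constraint {i} {j} {d!r}")
    return "\n".join(out) + "\n"


def write_topology(path, topo: MonomerTopology) -> None:
    with open(path, "w") as fh:
        fh.write(format_topology(topo))


def parse_topology(text: str) -> MonomerTopology:
    species = None
    beads, coords, bonds, angles, constraints = [], [], [], [], []
    for lineno, raw in enumerate(text.splitlines(), 1):
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("[monomer"):
            species = ln.split()[1].rstrip("]")
            continue
        parts = ln.split()
        try:
            if parts[0] == "bead":
                beads.append(BeadSpec(parts[2], parts[3], float(parts[4]),
                                      float(parts[5]), parts[6]))
                coords.append([float(x) for x in parts[7:10]])
            elif parts[0] == "bond":
                bonds.append((int(parts[1]), int(parts[2]),
                              float(parts[3]), float(parts[4])))
            elif parts[0] == "angle":
                angles.append((int(parts[1]), int(parts[2]), int(parts[3]),
                               float(parts[4]), float(parts[5])))
            elif parts[0] == "constraint":
                constraints.append((int(parts[1]), int(parts[2]),
                                    float(parts[3])))
            else:
                raise FileFormatError(f"line {lineno}: unknown record "
                                      f"{parts[0]!r}")
        except (ValueError, IndexError):
            raise FileFormatError(f"line {lineno}: malformed record")
    if species is None:
        raise FileFormatError("missing [monomer <species>] header")
    return MonomerTopology(species, beads, np.asarray(coords), bonds,
                           angles, constraints)


def read_topology(path) -> MonomerTopology:
    with open(path) as fh:
        return parse_topology(fh.read())
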