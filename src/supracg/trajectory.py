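"""Trajectory container: frames of unwrapped positions plus molecule map.

Positions are stored unwrapped (molecules whole, diffusion trackable);
analyses that need periodic distances apply the minimum-image convention
with the stored cubic box edge.  The container is the common currency of
the analysis modules, and synthetic fixtures serialise to the same
layout, so analyses cannot distinguish fixtures from simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLE_CORE, ROLE_SHIELD, ROLE_CAP, ROLE_QP, ROLE_QM = 0, 1, 2, 3, 4

_ROLES = {
    "M": [ROLE_CORE] + [ROLE_SHIELD] * 6,
    "MR": [ROLE_CORE] + [ROLE_SHIELD] * 6,
    "Mcoop": [ROLE_CORE] + [ROLE_SHIELD] * 6 + [ROLE_QP, ROLE_QM],
    "McoopR": [ROLE_CORE] + [ROLE_SHIELD] * 6 + [ROLE_QP, ROLE_QM],
    "C": [ROLE_CORE] + [ROLE_SHIELD] * 6 + [ROLE_CAP],
    "free": [ROLE_CORE],
}

_DIPOLAR = {"Mcoop", "McoopR"}


def roles_for_species(species: str) -> np.ndarray:
    return np.array(_ROLES[species], dtype=np.int8)


@dataclass
class Trajectory:
    positions: np.ndarray  # (n_frames, n_beads, 3) nm, unwrapped
    times: np.ndarray  # (n_frames,) ns
    box_edge: float
    mol: np.ndarray  # (n_beads,) molecule index
    species: list[str]  # per molecule
    core_idx: np.ndarray  # (n_molecules,) bead index of each core
    roles: np.ndarray  # (n_beads,) role codes
    masses: np.ndarray
    unwrapped: bool = True
    meta: dict = field(default_factory=dict)
    final_state: object | None = None
    energies: object | None = None  # pandas DataFrame

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def assembling(self) -> np.ndarray:
        """Mask over molecules: True for self-assembling species (never C)."""
        return np.array([s != "C" for s in self.species])

    @property
    def sampling_dt_ns(self) -> float:
        """Fixed sampling period; raises if the frame spacing is not uniform."""
        dt = np.diff(self.times)
        if len(dt) == 0:
            raise ValueError("trajectory has a single frame")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("variable sampling step")
        return float(dt[0])

    # -- derived per-molecule quantities ------------------------------------

    def core_positions(self, assembling_only: bool = True) -> np.ndarray:
        """(n_frames, n_sel, 3) core-bead positions."""
        idx = self.core_idx
        if assembling_only:
            idx = idx[self.assembling]
        return self.positions[:, idx, :]

    def com_positions(self) -> np.ndarray:
        """(n_frames, n_molecules, 3) molecular centres of mass (unwrapped)."""
        if not self.unwrapped:
            raise ValueError("centre-of-mass analysis needs unwrapped "
                             "coordinates (no periodic-image information)")
        nm = self.n_molecules
        w = self.masses / np.bincount(self.mol, weights=self.masses)[self.mol]
        wmat = np.zeros((nm, len(self.mol)))
        wmat[self.mol, np.arange(len(self.mol))] = w
        return np.einsum("mn,fnd->fmd", wmat, self.positions)

    def plane_normals(self) -> np.ndarray:
        """(n_frames, n_sel, 3) unit normals of the hexagon planes.

        Defined for hexagonal species only; the normal follows the body
        frame (cross product of the two in-plane diagonals), so its sign
        is continuous in time.
        """
        sel = [m for m, s in enumerate(self.species) if s != "free"]
        c = self.core_idx[sel]
        d1 = self.positions[:, c + 1, :] - self.positions[:, c + 4, :]
        d2 = self.positions[:, c + 2, :] - self.positions[:, c + 5, :]
        n = np.cross(d1, d2)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    def dipole_vectors(self) -> np.ndarray:
        """(n_frames, n_sel, 3) unit dipole vectors (Mcoop variants only)."""
        sel = [m for m, s in enumerate(self.species) if s in _DIPOLAR]
        if not sel:
            raise ValueError("no dipolar (Mcoop/McoopR) molecules in "
                             "this trajectory")
        c = self.core_idx[sel]
        d = self.positions[:, c + 7, :] - self.positions[:, c + 8, :]
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Write to a chunked HDF5 container (positions, times, box, map)."""
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("positions", data=self.positions,
                              chunks=(1,) + self.positions.shape[1:])
            h5.create_dataset("times", data=self.times)
            h5.create_dataset("mol", data=self.mol)
            h5.create_dataset("core_idx", data=self.core_idx)
            h5.create_dataset("roles", data=self.roles)
            h5.create_dataset("masses", data=self.masses)
            h5.create_dataset("species",
                              data=np.array(self.species, dtype="S8"))
            h5.attrs["box_edge"] = self.box_edge
            h5.attrs["unwrapped"] = self.unwrapped
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str, bool)):
                    h5.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as h5:
            meta = {k[5:]: (v.item() if hasattr(v, "item") else v)
                    for k, v in h5.attrs.items() if k.startswith("meta_")}
            return cls(
                positions=h5["positions"][...],
                times=h5["times"][...],
                box_edge=float(h5.attrs["box_edge"]),
                mol=h5["mol"][...],
                species=[s.decode() for s in h5["species"][...]],
                core_idx=h5["core_idx"][...],
                roles=h5["roles"][...],
                masses=h5["masses"][...],
                unwrapped=bool(h5.attrs["unwrapped"]),
                meta=meta)


def from_system_frames(system, frames: list[np.ndarray], times_ns,
                       meta: dict | None = None) -> Trajectory:
    """Assemble a Trajectory from a System and a list of position frames."""
    roles = np.concatenate([roles_for_species(s) for s in system.species])
    return Trajectory(
        positions=np.asarray(frames, dtype=float),
        times=np.asarray(times_ns, dtype=float),
        box_edge=system.box_edge, mol=system.mol.copy(),
        species=list(system.species), core_idx=system.core_indices.copy(),
        roles=roles, masses=system.masses.copy(), unwrapped=True,
        meta=meta or {})
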