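"""Aggregation-state analysis via the dual-cutoff hysteresis bond rule.

Two self-assembling monomers that are unbound become bound when their
core-core (minimum-image) distance drops below the binding cutoff r_b;
an existing bond breaks only when the distance exceeds the unbinding
cutoff r_u > r_b.  The hysteresis suppresses single-frame bond flicker.
Defaults r_b = 0.6 nm, r_u = 0.9 nm.

Assemblies are the connected components of the bond graph; chain-stopper
(C) molecules are excluded before partitioning, so an M bound only to a
C is a free monomer with stacking order phi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import Trajectory

R_BIND_DEFAULT = 0.6
R_UNBIND_DEFAULT = 0.9


def size_range_index(size) -> np.ndarray:
    """Binary (log2) size-range index: {1},{2},{3-4},{5-8},{9-16},..."""
    s = np.asarray(size)
    if np.any(s < 1):
        raise ValueError("assembly sizes are >= 1")
    return np.where(s == 1, 0, np.ceil(np.log2(np.maximum(s, 1))).astype(int))


def size_range_label(index: int) -> str:
    if index == 0:
        return "1"
    lo, hi = 2 ** (index - 1) + 1, 2 ** index
    if index == 1:
        return "2"
    return f"{lo}-{hi}"


@dataclass
class AggregationStateSeries:
    """Per-monomer, per-frame assembly sizes over self-assembling monomers.

    ``sizes`` and ``assembly_id`` are (n_monomers, n_frames); assembly ids
    are the lowest member index of each connected component.  ``bonds``
    holds the per-frame bond sets (pairs of monomer indices), and
    ``bond_events`` the number of bonds formed plus broken at each frame
    relative to the previous one.
    """

    sizes: np.ndarray
    dt_ns: float
    assembly_id: np.ndarray | None = None
    bonds: list | None = None  # per frame: set of (i, j) tuples, i < j
    bond_events: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_monomers(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.sizes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Columnar export: frame, monomer, assembly_id, size."""
        n, f = self.sizes.shape
        frames, monomers = np.meshgrid(np.arange(f), np.arange(n))
        data = {"frame": frames.ravel(), "monomer": monomers.ravel(),
                "size": self.sizes.ravel()}
        if self.assembly_id is not None:
            data["assembly_id"] = self.assembly_id.ravel()
        return pd.DataFrame(data)


def update_bonds(prev_bonded: np.ndarray, distances: np.ndarray,
                 r_b: float = R_BIND_DEFAULT,
                 r_u: float = R_UNBIND_DEFAULT) -> np.ndarray:
    """One hysteresis update of the boolean bond matrix.

    A pair binds when its distance falls below ``r_b`` and unbinds only
    beyond ``r_u``; between the cutoffs the previous state persists.
    """
    if r_b >= r_u:
        raise ValueError("binding cutoff r_b must be below unbinding "
                         "cutoff r_u")
    new = (distances < r_b) | (prev_bonded & (distances <= r_u))
    np.fill_diagonal(new, False)
    return new


def partition(bond_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a bond matrix -> (sizes, assembly ids).

    Components are labelled by their lowest member index, which makes the
    labelling deterministic and stable under monomer ordering.
    """
    n = bond_matrix.shape[0]
    ii, jj = np.nonzero(bond_matrix)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    # relabel by lowest member, compute sizes
    sizes = np.zeros(n, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        sizes[members] = len(members)
        ids[members] = members[0]
    return sizes, ids


def stacking_order(bond_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-monomer coordination phi (bonded core neighbours) and its mean."""
    phi = bond_matrix.sum(axis=1).astype(np.int64)
    return phi, float(phi.mean()) if len(phi) else 0.0


def _core_distance_matrix(cores: np.ndarray, box: float) -> np.ndarray:
    d = cores[:, None, :] - cores[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def aggregation_series(traj: Trajectory, r_b: float = R_BIND_DEFAULT,
                       r_u: float = R_UNBIND_DEFAULT) -> AggregationStateSeries:
    """Aggregation-state series of a trajectory (C monomers excluded).

    The first frame is initialised with the binding criterion alone;
    subsequent frames follow the hysteresis rule.  The result also
    records per-frame bond sets and binding/unbinding event counts.
    """
    if r_b >= r_u:
        raise ValueError("binding cutoff r_b must be below unbinding "
                         "cutoff r_u")
    dt_ns = traj.sampling_dt_ns  # validates fixed sampling step
    cores = traj.core_positions(assembling_only=True)
    n_frames, n_mon = cores.shape[0], cores.shape[1]
    sizes = np.zeros((n_mon, n_frames), dtype=np.int64)
    ids = np.zeros((n_mon, n_frames), dtype=np.int64)
    bonds_list = []
    events = np.zeros(n_frames, dtype=np.int64)
    prev = np.zeros((n_mon, n_mon), dtype=bool)
    for f in range(n_frames):
        dist = _core_distance_matrix(cores[f], traj.box_edge)
        bonded = update_bonds(prev, dist, r_b, r_u)
        if f > 0:
            events[f] = np.triu(bonded ^ prev, 1).sum()
        sizes[:, f], ids[:, f] = partition(bonded)
        iu, ju = np.nonzero(np.triu(bonded, 1))
        bonds_list.append({(int(i), int(j)) for i, j in zip(iu, ju)})
        prev = bonded
    return AggregationStateSeries(
        sizes=sizes, dt_ns=dt_ns, assembly_id=ids, bonds=bonds_list,
        bond_events=events, meta={"r_b": r_b, "r_u": r_u})


def size_distribution(series: AggregationStateSeries,
                      window: slice | None = None) -> pd.DataFrame:
    """Assembly-size histogram over binary size-ranges, in percent.

    For every frame the assemblies (counted once each) are histogrammed
    over the log2 size-ranges and normalised to the number of assemblies
    in that frame; the per-frame fractions are then averaged over the
    window.  Percentages sum to 100.
    """
    if series.assembly_id is None:
        raise ValueError("series lacks assembly labels")
    sizes = series.sizes if window is None else series.sizes[:, window]
    ids = series.assembly_id if window is None else series.assembly_id[:, window]
    if sizes.shape[1] == 0:
        raise ValueError("empty frame window")
    max_idx = int(size_range_index(sizes.max())) if sizes.size else 0
    acc = np.zeros(max_idx + 1)
    for f in range(sizes.shape[1]):
        _, first = np.unique(ids[:, f], return_index=True)
        asm_sizes = sizes[first, f]
        counts = np.bincount(size_range_index(asm_sizes),
                             minlength=max_idx + 1).astype(float)
        acc += counts / counts.sum()
    frac = acc / sizes.shape[1] * 100.0
    return pd.DataFrame({
        "size_range": [size_range_label(i) for i in range(max_idx + 1)],
        "percent": frac})


def mean_assembly_size(series: AggregationStateSeries,
                       window: slice | None = None) -> float:
    """Number-average assembly size over a frame window."""
    if series.assembly_id is None:
        raise ValueError("series lacks assembly labels")
    sizes = series.sizes if window is None else series.sizes[:, window]
    ids = series.assembly_id if window is None else series.assembly_id[:, window]
    vals = []
    for f in range(sizes.shape[1]):
        _, first = np.unique(ids[:, f], return_index=True)
        vals.append(sizes[first, f].mean())
    return float(np.mean(vals))
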