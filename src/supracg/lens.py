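"""LENS (Local Environment and Neighbours Shuffling) analysis.

For every self-assembling monomer core the neighbour set within a fixed
cutoff (default 0.7 nm) is compared between consecutive frames; the LENS
value is the symmetric-difference count normalised by the summed set
sizes,

    lens = (|C_t u C_t+dt| - |C_t n C_t+dt|) / (|C_t| + |C_t+dt|),

zero when the neighbourhood is unchanged (including empty -> empty) and
one for a complete replacement.  In these stiff fibre-forming systems
the values are discrete, and each nonzero level corresponds to a
distinct supramolecular event; events are classified here from the bond
network and assembly-size context:

* ``monomer_exchange``   - a free monomer binds to / unbinds from a fibre
* ``fibre_poly_depoly``  - fusion/fission where both fragments hold >= 2
* ``bend_straighten``    - contact formed/broken inside one assembly
* ``branch``             - a three-centre junction forms or dissolves
* ``four_centre_branch`` - a four-centre junction (rare, ephemeral)
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import AggregationStateSeries, _core_distance_matrix
from .trajectory import Trajectory

LENS_CUTOFF_DEFAULT = 0.7  # nm

EVENT_CLASSES = ("none", "monomer_exchange", "fibre_poly_depoly",
                 "bend_straighten", "branch", "four_centre_branch")


@dataclass
class LENSSeries:
    """values[(monomer, k)] compares frames k and k+1; in [0, 1]."""

    values: np.ndarray  # (n_monomers, n_frames - 1)
    cutoff: float
    dt_ns: float
    neighbour_sets: list | None = None  # per frame: list of sets

    @property
    def n_monomers(self) -> int:
        return self.values.shape[0]


@dataclass
class EventRecord:
    frame: int  # index of the later frame of the pair
    monomers: tuple
    event_class: str
    multimeric: bool


def lens_series(traj: Trajectory, cutoff: float = LENS_CUTOFF_DEFAULT,
                keep_neighbour_sets: bool = False) -> LENSSeries:
    """LENS time series over the self-assembling monomer cores."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dt_ns = traj.sampling_dt_ns
    cores = traj.core_positions(assembling_only=True)
    n_frames, n_mon = cores.shape[0], cores.shape[1]
    neigh = []
    for f in range(n_frames):
        d = _core_distance_matrix(cores[f], traj.box_edge)
        np.fill_diagonal(d, np.inf)
        close = d < cutoff
        neigh.append([set(np.nonzero(close[i])[0].tolist())
                      for i in range(n_mon)])
    values = np.zeros((n_mon, n_frames - 1))
    for f in range(n_frames - 1):
        for i in range(n_mon):
            a, b = neigh[f][i], neigh[f + 1][i]
            tot = len(a) + len(b)
            if tot == 0:
                continue
            values[i, f] = (len(a | b) - len(a & b)) / tot
    return LENSSeries(values, cutoff, dt_ns,
                      neighbour_sets=neigh if keep_neighbour_sets else None)


def _group_changes(changed: set, assembly_of: np.ndarray) -> list[set]:
    """Group changed bonds by the assembly (of the chosen frame) they touch."""
    groups: dict[int, set] = {}
    for (i, j) in changed:
        key = min(int(assembly_of[i]), int(assembly_of[j]))
        groups.setdefault(key, set()).add((i, j))
    # merge groups sharing an assembly id through either endpoint
    merged: list[set] = []
    for g in groups.values():
        placed = False
        for m in merged:
            if {a for e in m for a in e} & {a for e in g for a in e}:
                m |= g
                placed = True
                break
        if not placed:
            merged.append(set(g))
    return merged


def _classify_group(edges: set, cross_assembly: bool, min_part: int,
                    degree_after: np.ndarray) -> tuple[str, bool]:
    centres = {m for e in edges for m in e}
    if len(centres) >= 4:
        return "four_centre_branch", min_part >= 2
    if len(centres) == 3 or max(degree_after[m] for m in centres) >= 3:
        return "branch", min_part >= 2
    if not cross_assembly:
        return "bend_straighten", False
    if min_part == 1:
        return "monomer_exchange", False
    return "fibre_poly_depoly", True


def classify_events(lens: LENSSeries, series: AggregationStateSeries
                    ) -> tuple[list[EventRecord], pd.DataFrame]:
    """Classify the nonzero-LENS transitions into the event classes.

    Uses the hysteresis bond network and the assembly partition of the
    aggregation series (same trajectory and sampling) as mechanistic
    context; classification is deterministic and invariant under monomer
    relabelling.  Returns the event list and a per-class count table
    split into monomeric and multimeric totals.
    """
    if series.bonds is None or series.assembly_id is None:
        raise ValueError("series must carry bond sets and assembly labels")
    if lens.values.shape[1] != series.n_frames - 1:
        raise ValueError("LENS series and aggregation series have "
                         "inconsistent frame counts")
    records: list[EventRecord] = []
    for f in range(series.n_frames - 1):
        before, after = series.bonds[f], series.bonds[f + 1]
        added = after - before
        removed = before - after
        deg_after = np.zeros(series.n_monomers, dtype=np.int64)
        for (i, j) in after:
            deg_after[i] += 1
            deg_after[j] += 1
        deg_before = np.zeros(series.n_monomers, dtype=np.int64)
        for (i, j) in before:
            deg_before[i] += 1
            deg_before[j] += 1
        if added:
            for edges in _group_changes(added, series.assembly_id[:, f + 1]):
                ids_before = series.assembly_id[:, f]
                cross = len({ids_before[m] for e in edges for m in e}) > 1
                min_part = min(series.sizes[m, f]
                               for e in edges for m in e) if cross else 2
                cls, multi = _classify_group(edges, cross, min_part,
                                             deg_after)
                monomers = tuple(sorted({m for e in edges for m in e}))
                records.append(EventRecord(f + 1, monomers, cls, multi))
        if removed:
            for edges in _group_changes(removed, series.assembly_id[:, f]):
                ids_after = series.assembly_id[:, f + 1]
                cross = len({ids_after[m] for e in edges for m in e}) > 1
                min_part = min(series.sizes[m, f + 1]
                               for e in edges for m in e) if cross else 2
                cls, multi = _classify_group(edges, cross, min_part,
                                             deg_before)
                monomers = tuple(sorted({m for e in edges for m in e}))
                records.append(EventRecord(f + 1, monomers, cls, multi))
    counts = Counter((r.event_class, r.multimeric) for r in records)
    rows = []
    for cls in EVENT_CLASSES[1:]:
        rows.append({"event_class": cls,
                     "monomeric": counts.get((cls, False), 0),
                     "multimeric": counts.get((cls, True), 0),
                     "total": counts.get((cls, False), 0)
                     + counts.get((cls, True), 0)})
    return records, pd.DataFrame(rows)


def events_to_frame(records: list[EventRecord]) -> pd.DataFrame:
    """Event table export: frame, monomers, class, multimeric flag."""
    return pd.DataFrame([{
        "frame": r.frame,
        "monomers": ";".join(map(str, r.monomers)),
        "event_class": r.event_class,
        "multimeric": r.multimeric} for r in records])
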