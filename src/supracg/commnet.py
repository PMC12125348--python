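"""Transition-network analytics of aggregation-state series.

Per-monomer transitions between assembly sizes are counted at a fixed
lag, normalised row-wise into transition probability matrices, chained
to longer lags by matrix powers (the Chapman-Kolmogorov relation for a
Markovian series), and summarised into polymerisation/depolymerisation
probabilities, perturbation difference matrices, and the resilience of
each size-range against chain-stopper addition:

    resilience([C]) = (P_poly([C]) / P_poly(0)) / (P_depoly([C]) / P_depoly(0))

which equals 1 for an unperturbed equilibrium balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import (AggregationStateSeries, size_range_index,
                          size_range_label)

#: rows with fewer raw transition counts than this are flagged as
#: low-statistics (mirroring the shading of rare large size-ranges)
MIN_ROW_COUNT_DEFAULT = 500


def molecular_traffic(series: AggregationStateSeries,
                      mode: str = "bonds") -> np.ndarray:
    """Cumulative count T(t) of binding/unbinding events up to each frame.

    ``mode="bonds"`` (default) counts supramolecular bond formation and
    rupture events; ``mode="states"`` counts per-monomer aggregation-state
    changes instead.  T is non-decreasing with T(0) = 0.
    """
    if mode == "bonds":
        if series.bond_events is None:
            raise ValueError("series carries no bond-event record; "
                             "use mode='states' or recompute from a "
                             "trajectory")
        ev = series.bond_events.copy()
        ev[0] = 0
        return np.cumsum(ev)
    if mode == "states":
        changes = (np.diff(series.sizes, axis=1) != 0).sum(axis=0)
        return np.concatenate([[0], np.cumsum(changes)])
    raise ValueError(f"unknown traffic mode {mode!r}")


@dataclass
class TransitionCountMatrix:
    counts: np.ndarray  # (S, S) non-negative integers
    states: list  # size values or size-range labels
    lag_frames: int
    lag_ns: float
    n_monomers: int
    binned: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionProbabilityMatrix:
    """Row-stochastic matrix over sizes (or size-ranges) at a stated lag.

    ``mask`` flags rows with insufficient raw counts; those rows are set
    to self-transition so that matrix powers remain row-stochastic, and
    stay flagged in every derived quantity.
    """

    P: np.ndarray
    mask: np.ndarray  # (S,) True where low statistics
    states: list
    lag_ns: float
    binned: bool = False
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, index=self.states, columns=self.states)
        df.index.name = "from"
        return df


def count_transitions(series: AggregationStateSeries, lag_frames: int,
                      binned: bool = False) -> TransitionCountMatrix:
    """Count per-monomer size transitions at the given frame lag.

    Every monomer contributes one transition per usable frame pair, so
    the total count is n_monomers * (n_frames - lag_frames).
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    if lag_frames >= series.n_frames:
        raise ValueError("lag exceeds series length")
    src = series.sizes[:, :-lag_frames].ravel()
    dst = series.sizes[:, lag_frames:].ravel()
    if binned:
        src = size_range_index(src)
        dst = size_range_index(dst)
        smax = int(max(src.max(), dst.max()))
        states = [size_range_label(i) for i in range(smax + 1)]
        counts = np.zeros((smax + 1, smax + 1), dtype=np.int64)
        np.add.at(counts, (src, dst), 1)
    else:
        smax = int(series.sizes.max())
        states = list(range(1, smax + 1))
        counts = np.zeros((smax, smax), dtype=np.int64)
        np.add.at(counts, (src - 1, dst - 1), 1)
    return TransitionCountMatrix(counts, states, lag_frames,
                                 lag_frames * series.dt_ns,
                                 series.n_monomers, binned)


def bin_counts(tcm: TransitionCountMatrix) -> TransitionCountMatrix:
    """Group a size-resolved count matrix into binary size-ranges.

    Counts are summed into ranges *before* any normalisation so that
    probabilities over ranges remain row-stochastic.
    """
    if tcm.binned:
        return tcm
    idx = size_range_index(np.asarray(tcm.states))
    smax = int(idx.max())
    out = np.zeros((smax + 1, smax + 1), dtype=np.int64)
    np.add.at(out, (idx[:, None].repeat(len(idx), 1),
                    idx[None, :].repeat(len(idx), 0)), tcm.counts)
    labels = [size_range_label(i) for i in range(smax + 1)]
    return TransitionCountMatrix(out, labels, tcm.lag_frames, tcm.lag_ns,
                                 tcm.n_monomers, binned=True)


def normalise(tcm: TransitionCountMatrix,
              min_row_count: int = MIN_ROW_COUNT_DEFAULT
              ) -> TransitionProbabilityMatrix:
    """Row-normalise counts into probabilities, masking sparse rows.

    Rows whose raw count falls below ``min_row_count`` (and empty rows)
    are replaced by self-transition and flagged in ``mask`` rather than
    reported as noisy estimates or NaNs.
    """
    rowsum = tcm.counts.sum(axis=1)
    mask = rowsum < min_row_count
    P = np.zeros_like(tcm.counts, dtype=float)
    ok = rowsum > 0
    P[ok] = tcm.counts[ok] / rowsum[ok, None]
    for i in np.nonzero(~ok)[0]:
        P[i, i] = 1.0
    return TransitionProbabilityMatrix(P, mask, list(tcm.states), tcm.lag_ns,
                                       tcm.binned,
                                       meta={"min_row_count": min_row_count,
                                             "row_counts": rowsum})


def chain(tpm: TransitionProbabilityMatrix, n: int
          ) -> TransitionProbabilityMatrix:
    """Matrix power: transition probabilities at n times the base lag."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("the chaining factor must be a positive integer; "
                         "the target lag must be an integer multiple of "
                         "the base lag")
    P = np.linalg.matrix_power(tpm.P, int(n))
    return TransitionProbabilityMatrix(P, tpm.mask.copy(), list(tpm.states),
                                       tpm.lag_ns * n, tpm.binned,
                                       dict(tpm.meta))


def chain_to_lag(tpm: TransitionProbabilityMatrix, lag_ns: float
                 ) -> TransitionProbabilityMatrix:
    """Chain to a target lag, which must be a multiple of the base lag."""
    ratio = lag_ns / tpm.lag_ns
    n = int(round(ratio))
    if n < 1 or abs(ratio - n) > 1e-6:
        raise ValueError(
            f"target lag {lag_ns} ns is not an integer multiple of the "
            f"base lag {tpm.lag_ns} ns")
    return chain(tpm, n)


def poly_depoly(tpm: TransitionProbabilityMatrix
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polymerisation/depolymerisation probability per size (or range).

    P_poly(s) sums the row probabilities of transitions that increase the
    size, P_depoly(s) those that decrease it; together with the diagonal
    persistence they add to 1.  Returns (P_poly, P_depoly, mask).
    """
    P = tpm.P
    poly = np.triu(P, 1).sum(axis=1)
    depoly = np.tril(P, -1).sum(axis=1)
    return poly, depoly, tpm.mask.copy()


def delta_matrix(perturbed: TransitionProbabilityMatrix,
                 unperturbed: TransitionProbabilityMatrix
                 ) -> TransitionProbabilityMatrix:
    """Entrywise difference P(perturbed) - P(unperturbed); masks OR."""
    if perturbed.P.shape != unperturbed.P.shape or \
            list(perturbed.states) != list(unperturbed.states):
        raise ValueError("matrices have different binning")
    if abs(perturbed.lag_ns - unperturbed.lag_ns) > 1e-9:
        raise ValueError("matrices have different lags")
    return TransitionProbabilityMatrix(
        perturbed.P - unperturbed.P,
        perturbed.mask | unperturbed.mask,
        list(perturbed.states), perturbed.lag_ns, perturbed.binned,
        {"delta": True})


@dataclass
class ResilienceCurve:
    """Perturbation response per size-range across chain-stopper levels."""

    levels: list  # [C] amounts, first must be the unperturbed 0
    states: list  # size-range labels
    rel_poly: np.ndarray  # (n_levels, S)
    rel_depoly: np.ndarray
    resilience: np.ndarray
    mask: np.ndarray  # (n_levels, S)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for li, lev in enumerate(self.levels):
            for si, st in enumerate(self.states):
                rows.append({"C": lev, "size_range": st,
                             "rel_poly": self.rel_poly[li, si],
                             "rel_depoly": self.rel_depoly[li, si],
                             "resilience": self.resilience[li, si],
                             "masked": bool(self.mask[li, si])})
        return pd.DataFrame(rows)


def resilience(p_poly_c, p_depoly_c, p_poly_0, p_depoly_0):
    """Elementwise resilience ratio; masked (NaN) where a denominator is 0.

    resilience = [P_poly([C]) * P_depoly(0)] / [P_depoly([C]) * P_poly(0)],
    i.e. the perturbed-to-unperturbed ratio of the equilibrium balance
    R = P_poly / P_depoly.  Scale-invariant: multiplying both
    probabilities by a common factor leaves it unchanged.
    """
    p_poly_c = np.asarray(p_poly_c, dtype=float)
    p_depoly_c = np.asarray(p_depoly_c, dtype=float)
    p_poly_0 = np.asarray(p_poly_0, dtype=float)
    p_depoly_0 = np.asarray(p_depoly_0, dtype=float)
    denom = p_depoly_c * p_poly_0
    out = np.full(np.broadcast(p_poly_c, denom).shape, np.nan)
    ok = denom != 0
    np.divide(p_poly_c * p_depoly_0, denom, out=out, where=ok)
    return out


def resilience_curves(poly_by_level: dict, depoly_by_level: dict,
                      states: list, masks: dict | None = None
                      ) -> ResilienceCurve:
    """Assemble relative probabilities and resilience across [C] levels.

    ``poly_by_level[level]`` / ``depoly_by_level[level]`` are the per-range
    probabilities at each chain-stopper level; level 0 (unperturbed) must
    be present and defines the reference.
    """
    if 0 not in poly_by_level:
        raise ValueError("the unperturbed level 0 is required")
    levels = sorted(poly_by_level)
    p0 = np.asarray(poly_by_level[0], dtype=float)
    d0 = np.asarray(depoly_by_level[0], dtype=float)
    nl, ns = len(levels), len(states)
    rel_p = np.full((nl, ns), np.nan)
    rel_d = np.full((nl, ns), np.nan)
    res = np.full((nl, ns), np.nan)
    mask = np.zeros((nl, ns), dtype=bool)
    for li, lev in enumerate(levels):
        pc = np.asarray(poly_by_level[lev], dtype=float)
        dc = np.asarray(depoly_by_level[lev], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_p[li] = np.where(p0 != 0, pc / p0, np.nan)
            rel_d[li] = np.where(d0 != 0, dc / d0, np.nan)
        res[li] = resilience(pc, dc, p0, d0)
        mask[li] = ~np.isfinite(res[li])
        if masks is not None and lev in masks:
            mask[li] |= np.asarray(masks[lev], dtype=bool)
    return ResilienceCurve(levels, list(states), rel_p, rel_d, res, mask)


def normalised_resilience(curve: ResilienceCurve) -> np.ndarray:
    """Min-max scaled per-range resilience averaged over [C] levels.

    Averages the resilience of each size-range over all perturbation
    levels, then affinely rescales the averages to [0, 1].  A constant
    profile returns zeros (with a warning in the curve metadata sense).
    """
    if len(curve.states) < 2:
        raise ValueError("need at least two size-ranges")
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(np.where(curve.mask, np.nan, curve.resilience),
                         axis=0)
    lo, hi = np.nanmin(avg), np.nanmax(avg)
    if hi == lo:
        import warnings
        warnings.warn("constant resilience profile; min-max scale "
                      "degenerate, returning zeros")
        return np.zeros_like(avg)
    return (avg - lo) / (hi - lo)


def sankey_flows(series: AggregationStateSeries, times_ns: list,
                 ) -> pd.DataFrame:
    """Monomer flows between size-ranges at the listed times.

    For each consecutive pair of listed times, counts how many monomers
    moved from each source size-range to each target range.  Flows
    conserve the monomer number: each monomer appears exactly once per
    time pair.
    """
    if len(times_ns) < 2:
        raise ValueError("need at least two times")
    t0 = 0.0
    frame_of = []
    for t in times_ns:
        f = (t - t0) / series.dt_ns
        fi = int(round(f))
        if fi < 0 or fi >= series.n_frames or abs(f - fi) > 1e-6:
            raise ValueError(f"time {t} ns outside the series or off the "
                             "sampling grid")
        frame_of.append(fi)
    rows = []
    for (ta, fa), (tb, fb) in zip(zip(times_ns, frame_of),
                                  zip(times_ns[1:], frame_of[1:])):
        src = size_range_index(series.sizes[:, fa])
        dst = size_range_index(series.sizes[:, fb])
        smax = int(max(src.max(), dst.max()))
        counts = np.zeros((smax + 1, smax + 1), dtype=np.int64)
        np.add.at(counts, (src, dst), 1)
        for i in range(smax + 1):
            for j in range(smax + 1):
                if counts[i, j]:
                    rows.append({"time_from_ns": ta, "time_to_ns": tb,
                                 "source_range": size_range_label(i),
                                 "target_range": size_range_label(j),
                                 "monomers": int(counts[i, j])})
    return pd.DataFrame(rows)
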