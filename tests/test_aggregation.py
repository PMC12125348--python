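"""Hysteresis bond rule, assembly partitions and size statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supracg.aggregation import (AggregationStateSeries, aggregation_series,
                                 mean_assembly_size, partition,
                                 size_distribution, size_range_index,
                                 size_range_label, stacking_order,
                                 update_bonds)
from supracg.synthetic import ideal_fibre, scripted_scenarios
from supracg.trajectory import from_system_frames


def _pair_matrix(d):
    m = np.array([[0.0, d], [d, 0.0]])
    return m


@pytest.mark.parametrize("prev,dist,expected", [
    (False, 0.70, False),   # between cutoffs, unbound stays unbound
    (True, 0.70, True),     # between cutoffs, bound persists (hysteresis)
    (True, 0.95, False),    # beyond r_u, bond breaks
    (False, 0.55, True),    # below r_b, bond forms
    (True, 0.899, True),    # just inside r_u
])
def test_update_bonds_rule(prev, dist, expected):
    prev_m = np.array([[False, prev], [prev, False]])
    new = update_bonds(prev_m, _pair_matrix(dist))
    assert bool(new[0, 1]) is expected
    assert new[0, 1] == new[1, 0]


def test_update_bonds_rejects_bad_cutoffs():
    with pytest.raises(ValueError):
        update_bonds(np.zeros((2, 2), bool), _pair_matrix(0.7),
                     r_b=0.9, r_u=0.6)


def test_partition_examples():
    bonds = np.zeros((4, 4), bool)
    bonds[0, 1] = bonds[1, 0] = bonds[1, 2] = bonds[2, 1] = True
    sizes, ids = partition(bonds)
    assert sizes.tolist() == [3, 3, 3, 1]
    assert ids.tolist() == [0, 0, 0, 3]
    sizes, ids = partition(np.zeros((5, 5), bool))
    assert sizes.tolist() == [1] * 5
    assert ids.tolist() == list(range(5))


@given(st.integers(0, 2 ** 28))
@settings(max_examples=25, deadline=None)
def test_partition_conserves_monomers(seed):
    """Sizes are a consistent partition for any symmetric bond matrix."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 20))
    m = rng.random((n, n)) < 0.2
    m = np.triu(m, 1)
    m = m | m.T
    sizes, ids = partition(m)
    assert sizes.min() >= 1
    total = sum(sizes[ids == k][0] for k in np.unique(ids))
    assert total == n
    for k in np.unique(ids):
        assert k == np.nonzero(ids == k)[0][0]  # lowest member labels


def test_stacking_order():
    def chain_matrix(n, ring=False):
        m = np.zeros((n, n), bool)
        for k in range(n - 1):
            m[k, k + 1] = m[k + 1, k] = True
        if ring:
            m[0, n - 1] = m[n - 1, 0] = True
        return m

    phi, mean = stacking_order(chain_matrix(5))
    assert mean == pytest.approx(1.6)  # 2(n-1)/n for a linear pentamer
    _, mean_ring = stacking_order(chain_matrix(6, ring=True))
    assert mean_ring == pytest.approx(2.0)
    _, mean_free = stacking_order(np.zeros((4, 4), bool))
    assert mean_free == 0.0


def test_static_fibre_series():
    fib = ideal_fibre(10)
    traj = from_system_frames(fib, [fib.positions] * 5,
                              np.arange(5) * 0.3)
    series = aggregation_series(traj)
    assert np.all(series.sizes == 10)
    assert series.bond_events[1:].sum() == 0


def test_chain_stopper_bound_monomer_is_free():
    """An M bound only to a C is reported free with phi = 0."""
    from supracg.model import _assemble, build_interaction_table, build_monomer

    rng = np.random.default_rng(0)
    table = build_interaction_table({"M", "C"})
    mols = [("M", build_monomer("M"), np.array([5.0, 5.0, 5.0]), np.eye(3)),
            ("C", build_monomer("C"), np.array([5.0, 5.0, 5.5]), np.eye(3))]
    system = _assemble(mols, 10.0, table, 300.0, rng)
    traj = from_system_frames(system, [system.positions] * 2, [0.0, 0.3])
    series = aggregation_series(traj)
    assert series.sizes.shape[0] == 1  # only the M monomer is tracked
    assert np.all(series.sizes == 1)
    assert all(len(b) == 0 for b in series.bonds)


def test_variable_sampling_rejected():
    fib = ideal_fibre(3)
    traj = from_system_frames(fib, [fib.positions] * 3, [0.0, 0.3, 0.9])
    with pytest.raises(ValueError, match="variable sampling"):
        aggregation_series(traj)


def test_hysteresis_suppresses_flicker(scenarios):
    sc = {s.name: s for s in scenarios}["hysteresis_oscillation"]
    series = aggregation_series(sc.trajectory)
    assert np.array_equal(series.sizes, sc.expected_sizes)
    assert series.bond_events[2:].sum() == 0  # bound once, never flickers


def test_raising_ru_only_reduces_unbinding():
    """On a fixed distance trace, larger r_u means fewer unbinding events."""
    rng = np.random.default_rng(12)
    d = np.clip(0.75 + np.cumsum(rng.normal(0, 0.08, size=400)), 0.3, 1.4)

    def unbind_count(r_u):
        prev = np.zeros((2, 2), bool)
        count = 0
        for dist in d:
            new = update_bonds(prev, _pair_matrix(dist), 0.6, r_u)
            if prev[0, 1] and not new[0, 1]:
                count += 1
            prev = new
        return count

    counts = [unbind_count(ru) for ru in (0.65, 0.8, 0.95, 1.1)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[0] > counts[-1]  # the trace actually flickers


def test_single_cutoff_limit_recovers_plain_clustering():
    """r_u -> r_b degenerates to memoryless distance-cutoff clustering."""
    rng = np.random.default_rng(5)
    prev = np.zeros((2, 2), bool)
    for dist in np.clip(rng.normal(0.7, 0.2, 100), 0.2, 1.5):
        new = update_bonds(prev, _pair_matrix(dist), 0.6, 0.6 + 1e-12)
        assert new[0, 1] == (dist < 0.6)
        prev = new


def test_size_range_binning():
    assert size_range_index([1, 2, 3, 4, 5, 8, 9, 16, 17]).tolist() == \
        [0, 1, 2, 2, 3, 3, 4, 4, 5]
    assert [size_range_label(i) for i in range(5)] == \
        ["1", "2", "3-4", "5-8", "9-16"]


def test_size_distribution_all_free():
    series = AggregationStateSeries(
        sizes=np.ones((6, 4), dtype=int), dt_ns=0.3,
        assembly_id=np.tile(np.arange(6)[:, None], (1, 4)))
    dist = size_distribution(series)
    assert dist["percent"].tolist() == [100.0]


def test_size_distribution_alternating_frames():
    """One 4-mer vs four singletons on alternate frames -> 50/50 split."""
    sizes = np.empty((4, 2), dtype=int)
    ids = np.empty((4, 2), dtype=int)
    sizes[:, 0] = 4
    ids[:, 0] = 0
    sizes[:, 1] = 1
    ids[:, 1] = np.arange(4)
    series = AggregationStateSeries(sizes=sizes, dt_ns=0.3, assembly_id=ids)
    dist = size_distribution(series).set_index("size_range")["percent"]
    assert dist["1"] == pytest.approx(50.0)
    assert dist["3-4"] == pytest.approx(50.0)
    assert dist.sum() == pytest.approx(100.0, abs=1e-9)
    assert mean_assembly_size(series) == pytest.approx((4 + 1) / 2)


def test_size_distribution_rejects_empty_window():
    series = AggregationStateSeries(
        sizes=np.ones((2, 3), dtype=int), dt_ns=0.3,
        assembly_id=np.zeros((2, 3), dtype=int))
    with pytest.raises(ValueError, match="empty"):
        size_distribution(series, window=slice(3, 3))
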