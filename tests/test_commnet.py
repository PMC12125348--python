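"""Transition matrices, traffic, resilience and flow tables."""

import warnings

import numpy as np
import pytest

from supracg.aggregation import AggregationStateSeries
from supracg.commnet import (ResilienceCurve, bin_counts, chain,
                             chain_to_lag, count_transitions, delta_matrix,
                             molecular_traffic, normalise,
                             normalised_resilience, poly_depoly, resilience,
                             resilience_curves, sankey_flows)
from supracg.synthetic import (PlantedChainSpec, planted_markov_series,
                               scripted_scenarios, stationary_distribution)


def _series(sizes, dt=0.3, bond_events=None):
    sizes = np.asarray(sizes)
    return AggregationStateSeries(sizes=sizes, dt_ns=dt,
                                  assembly_id=np.zeros_like(sizes),
                                  bond_events=bond_events)


def test_traffic_static_and_single_event():
    ev = np.array([0, 0, 1, 0, 0])
    s = _series(np.ones((3, 5), int), bond_events=ev)
    T = molecular_traffic(s)
    assert T.tolist() == [0, 0, 1, 1, 1]
    s0 = _series(np.ones((3, 5), int), bond_events=np.zeros(5, int))
    assert molecular_traffic(s0).tolist() == [0] * 5
    # state-change mode counts monomer transitions instead
    sizes = np.array([[1, 2, 2, 1], [1, 2, 2, 1]])
    Ts = molecular_traffic(_series(sizes), mode="states")
    assert Ts.tolist() == [0, 2, 2, 4]
    with pytest.raises(ValueError):
        molecular_traffic(_series(sizes), mode="nope")
    with pytest.raises(ValueError, match="bond-event"):
        molecular_traffic(_series(sizes), mode="bonds")


def test_traffic_matches_planted_switch_count(scenarios=None):
    """Stationary two-state bond process: slope equals the planted rate."""
    rng = np.random.default_rng(17)
    bound = rng.random(2000) < 0.5  # iid -> switches ~ Bernoulli
    from supracg.synthetic import _traj_from_cores
    from supracg.aggregation import aggregation_series

    frames = [np.array([[0.0, 0.0, 0.0],
                        [0.0, 0.0, 0.5 if b else 1.2]]) for b in bound]
    traj = _traj_from_cores(frames)
    series = aggregation_series(traj)
    T = molecular_traffic(series)
    switches = int((bound[1:] != bound[:-1]).sum())
    assert T[-1] == switches


def test_count_transitions_totals_and_diagonal():
    s = _series(np.full((4, 100), 5))
    tcm = count_transitions(s, 1)
    assert tcm.total == 4 * 99
    assert tcm.counts[4, 4] == tcm.total  # all mass on (5, 5)
    with pytest.raises(ValueError):
        count_transitions(s, 0)
    with pytest.raises(ValueError):
        count_transitions(s, 100)


def test_count_transitions_flip_flop():
    sizes = np.tile([1, 2], 50)[None, :]
    tcm = count_transitions(_series(sizes), 1)
    assert tcm.counts[0, 1] == 50
    assert tcm.counts[1, 0] == 49
    assert tcm.counts[0, 0] == tcm.counts[1, 1] == 0


def test_detailed_balance_symmetry():
    """Counts from a reversible stationary chain are symmetric within 3 sigma."""
    C = np.array([[8.0, 2, 1], [2, 6, 3], [1, 3, 9]])  # symmetric flows
    P = C / C.sum(axis=1, keepdims=True)
    spec = PlantedChainSpec(P, [1, 2, 4], n_monomers=40, n_frames=5000,
                            seed=3)
    series, _ = planted_markov_series(spec)
    tcm = count_transitions(series, 1)
    c = tcm.counts
    for i in range(3):
        for j in range(i + 1, 3):
            sigma = np.sqrt(c[i, j] + c[j, i])
            assert abs(c[i, j] - c[j, i]) <= 3 * sigma + 1


def test_normalise_rows_and_masking():
    s = _series(np.full((4, 100), 5))
    tpm = normalise(count_transitions(s, 1), min_row_count=10)
    assert np.allclose(tpm.P.sum(axis=1), 1.0, atol=1e-12)
    assert tpm.P[4, 4] == 1.0
    assert not tpm.mask[4]
    assert tpm.mask[0]  # size-1 row never observed -> masked, not NaN
    assert tpm.P[0, 0] == 1.0  # degenerate row: self-transition, no NaN
    assert np.isfinite(tpm.P).all()


def test_chain_examples_and_stochasticity():
    from supracg.commnet import TransitionProbabilityMatrix

    P = np.array([[0.9, 0.1], [0.1, 0.9]])
    tpm = TransitionProbabilityMatrix(P, np.zeros(2, bool), [1, 2], 0.3)
    assert np.array_equal(chain(tpm, 1).P, P)
    c2 = chain(tpm, 2)
    assert np.allclose(c2.P, [[0.82, 0.18], [0.18, 0.82]])
    assert np.allclose(c2.P.sum(axis=1), 1.0, atol=1e-12)
    assert c2.lag_ns == pytest.approx(0.6)
    with pytest.raises(ValueError):
        chain(tpm, 0)
    with pytest.raises(ValueError, match="integer multiple"):
        chain_to_lag(tpm, 0.7)
    assert chain_to_lag(tpm, 15.0).lag_ns == pytest.approx(15.0)  # n = 50


def test_chapman_kolmogorov_on_markov_data():
    """Chained short-lag matrix matches direct counting at the long lag."""
    C = np.array([[20.0, 5, 1, 0.5], [5, 10, 4, 1], [1, 4, 8, 3],
                  [0.5, 1, 3, 6]])
    P = C / C.sum(axis=1, keepdims=True)
    spec = PlantedChainSpec(P, [1, 2, 4, 8], n_monomers=50, n_frames=8000,
                            seed=11)
    series, _ = planted_markov_series(spec)
    base = normalise(count_transitions(series, 1), min_row_count=1)
    chained = chain(base, 10)
    direct = normalise(count_transitions(series, 10), min_row_count=1)
    # multinomial error with lag-overlap decorrelation factor
    pi = stationary_distribution(P)
    n_eff = 50 * (8000 - 10) / 10
    for i in range(4):
        row_n = n_eff * pi[i]
        sigma = np.sqrt(np.maximum(direct.P[i] * (1 - direct.P[i]), 1e-12)
                        / row_n)
        assert np.all(np.abs(chained.P[i] - direct.P[i])
                      <= 3.5 * sigma + 0.01)


def test_poly_depoly():
    from supracg.commnet import TransitionProbabilityMatrix

    P = np.eye(3)
    tpm = TransitionProbabilityMatrix(P, np.zeros(3, bool), [1, 2, 4], 0.3)
    poly, depoly, _ = poly_depoly(tpm)
    assert np.all(poly == 0) and np.all(depoly == 0)
    P2 = np.array([[0.5, 0.5, 0.0], [0.3, 0.5, 0.2], [0.1, 0.2, 0.7]])
    tpm2 = TransitionProbabilityMatrix(P2, np.zeros(3, bool), [1, 2, 4], 0.3)
    poly, depoly, _ = poly_depoly(tpm2)
    assert poly[1] == pytest.approx(0.2)
    assert depoly[1] == pytest.approx(0.3)
    stay = np.diag(P2)
    assert np.allclose(poly + depoly + stay, 1.0)


def test_delta_matrix():
    from supracg.commnet import TransitionProbabilityMatrix

    A = TransitionProbabilityMatrix(np.array([[0.8, 0.2], [0.4, 0.6]]),
                                    np.array([False, True]), [1, 2], 0.3)
    B = TransitionProbabilityMatrix(np.array([[0.7, 0.3], [0.5, 0.5]]),
                                    np.array([True, False]), [1, 2], 0.3)
    d = delta_matrix(A, B)
    assert np.allclose(d.P, A.P - B.P)
    assert np.allclose(delta_matrix(B, A).P, -d.P)
    assert d.mask.tolist() == [True, True]
    C = TransitionProbabilityMatrix(np.eye(3), np.zeros(3, bool),
                                    [1, 2, 4], 0.3)
    with pytest.raises(ValueError):
        delta_matrix(A, C)


def test_resilience_definition():
    assert resilience(0.2, 0.1, 0.2, 0.1) == pytest.approx(1.0)
    assert resilience(0.1, 0.1, 0.2, 0.1) == pytest.approx(0.5)
    # scale invariance: both probabilities scaled by a common factor
    assert resilience(0.2 * 0.3, 0.1 * 0.3, 0.2, 0.1) == pytest.approx(1.0)
    out = resilience(0.2, 0.0, 0.2, 0.1)
    assert np.isnan(out)  # masked, never infinite


def test_resilience_curves_and_normalisation():
    states = ["1", "2", "3-4"]
    poly = {0: [0.2, 0.3, 0.1], 40: [0.1, 0.3, 0.1]}
    depoly = {0: [0.2, 0.1, 0.1], 40: [0.2, 0.1, 0.2]}
    curve = resilience_curves(poly, depoly, states)
    assert np.allclose(curve.resilience[0], 1.0)  # [C]=0 by construction
    assert curve.resilience[1][0] == pytest.approx(0.5)
    assert curve.resilience[1][2] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        resilience_curves({40: [0.1]}, {40: [0.1]}, ["1"])


def test_normalised_resilience_examples():
    def curve_of(avgs):
        n = len(avgs)
        return ResilienceCurve([0], [str(i) for i in range(n)],
                               np.ones((1, n)), np.ones((1, n)),
                               np.asarray(avgs, float)[None, :],
                               np.zeros((1, n), bool))

    assert normalised_resilience(curve_of([2, 4])).tolist() == [0.0, 1.0]
    assert normalised_resilience(curve_of([1, 2, 3])).tolist() == \
        [0.0, 0.5, 1.0]
    # affine invariance: y -> 2y + 1 leaves the scaled profile unchanged
    a = normalised_resilience(curve_of([1, 2, 5]))
    assert np.allclose(a, normalised_resilience(curve_of([3, 5, 11])))
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        out = normalised_resilience(curve_of([2, 2, 2]))
    assert out.tolist() == [0.0, 0.0, 0.0]
    assert any("constant" in str(w.message) for w in rec)
    with pytest.raises(ValueError):
        normalised_resilience(curve_of([1.0]))


def test_sankey_flows():
    sizes = np.full((16, 3), 8)
    sizes[:, 2] = 16  # two 8-mers merge into a 16-mer
    series = AggregationStateSeries(sizes=sizes, dt_ns=5.0,
                                    assembly_id=np.zeros_like(sizes))
    flows = sankey_flows(series, [0.0, 5.0, 10.0])
    first = flows[flows.time_from_ns == 0.0]
    assert first.iloc[0]["source_range"] == "5-8"
    assert first.iloc[0]["target_range"] == "5-8"
    second = flows[flows.time_from_ns == 5.0]
    assert second.iloc[0]["source_range"] == "5-8"
    assert second.iloc[0]["target_range"] == "9-16"
    assert second.iloc[0]["monomers"] == 16
    # conservation: outflow equals occupancy at the earlier time
    for t in (0.0, 5.0):
        sub = flows[flows.time_from_ns == t]
        assert sub["monomers"].sum() == 16
    with pytest.raises(ValueError):
        sankey_flows(series, [0.0, 50.0])
    with pytest.raises(ValueError):
        sankey_flows(series, [0.0])
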