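"""Cross-correlograms, exact Poisson thresholds, monosynaptic edge
detection and spike transmission."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminarkit.connectivity import (Ccg, baseline_predictor, ccg_identity,
                                     compare_state_transmission, compute_ccg,
                                     detect_edges, detect_network_edges,
                                     poisson_bounds,
                                     state_dependent_transmission,
                                     transmission_probability, Edge)
from laminarkit.synthetic import poisson_train, simulate_spike_network


def _flat_ccg(count=50, n_pre=1000):
    n_bins = 200
    lags = (np.arange(n_bins) - n_bins / 2 + 0.5) * 0.5
    return Ccg(np.full(n_bins, count), lags, 0.5, n_pre, n_pre)


class TestComputeCcg:
    def test_identical_sparse_train_zero_lag_empty(self):
        t = np.arange(100) * 0.5  # no two spikes within the CCG halfwidth/2
        ccg = compute_ccg(t, t, halfwidth_ms=50.0)
        zero_bin = np.argmin(np.abs(ccg.lags_ms - 0.25))
        assert ccg.counts[zero_bin] == 0  # self pairs excluded

    def test_shifted_copy_concentrates_in_one_bin(self):
        t = np.arange(200) * 0.5
        ccg = compute_ccg(t, t + 0.0022)
        k = np.argmax(ccg.counts)
        assert ccg.lags_ms[k] == pytest.approx(2.25)
        assert ccg.counts[k] == 200

    def test_independent_poisson_matches_analytic_mean(self):
        rng = np.random.default_rng(0)
        a = poisson_train(5.0, 600.0, rng)
        b = poisson_train(5.0, 600.0, rng)
        ccg = compute_ccg(a, b)
        expected = ccg.n_pre * 5.0 * 0.0005     # n_pre * rate * bin width
        assert ccg.counts.mean() == pytest.approx(expected, rel=0.05)

    def test_interval_restriction_excludes_outside_spikes(self):
        a = np.array([1.0, 10.0])
        b = np.array([1.002, 10.002])
        ccg = compute_ccg(a, b, intervals=[(0.0, 5.0)])
        assert ccg.n_pre == 1
        assert ccg.counts.sum() == 1

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            compute_ccg(np.empty(0), np.array([1.0]))

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(1)
        a = poisson_train(8.0, 120.0, rng)
        b = poisson_train(8.0, 120.0, rng)
        ab = compute_ccg(a, b)
        ba = compute_ccg(b, a)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])


class TestBaselinePredictor:
    def test_flat_ccg_preserved(self):
        ccg = _flat_ccg(count=37)
        pred = baseline_predictor(ccg)
        np.testing.assert_allclose(pred[20:-20], 37.0, rtol=1e-6)

    def test_delta_ccg_gives_gaussian(self):
        ccg = _flat_ccg(count=0)
        ccg.counts = ccg.counts.copy()
        ccg.counts[100] = 1000
        pred = baseline_predictor(ccg)
        assert np.argmax(pred) == 100
        sigma_bins = 14.0
        half = pred[100] * np.exp(-0.5)  # value one SD away
        assert pred[100 + 14] == pytest.approx(half, rel=0.05)

    def test_total_count_preserved(self):
        rng = np.random.default_rng(0)
        ccg = _flat_ccg()
        ccg.counts = rng.poisson(20, ccg.counts.size)
        pred = baseline_predictor(ccg)
        assert pred.sum() == pytest.approx(ccg.counts.sum(), rel=1e-6)


class TestPoissonBounds:
    def test_zero_rate(self):
        assert poisson_bounds(0.0) == (0, -1)

    def test_matches_arbitrary_precision_summation(self):
        import sympy

        p_hi = sympy.Rational(999999, 1000000)
        for lam_str in ("1/100", "1/10", "1", "5", "10", "50"):
            lam = sympy.Rational(lam_str)
            k_hi, k_lo = poisson_bounds(float(lam))
            assert k_hi == _oracle_k_hi(lam, p_hi)
            assert k_lo == _oracle_k_lo(lam, 1 - p_hi)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_bounds(-1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.01, 200.0), st.floats(0.01, 200.0))
    def test_upper_bound_monotone_in_rate(self, a, b):
        lo, hi = sorted((a, b))
        assert poisson_bounds(lo)[0] <= poisson_bounds(hi)[0]


def _oracle_k_hi(lam, p_hi):
    """Smallest k with Poisson CDF >= p_hi by exact term-by-term summation
    in arbitrary precision."""
    import sympy

    acc = sympy.Integer(0)
    term_k = 0
    while True:
        acc += lam**term_k / sympy.factorial(term_k)
        cdf = (sympy.exp(-lam) * acc).evalf(60)
        if cdf >= p_hi.evalf(60):
            return term_k
        term_k += 1


def _oracle_k_lo(lam, q):
    import sympy

    acc = sympy.Integer(0)
    best = -1
    for k in range(0, 10000):
        acc += lam**k / sympy.factorial(k)
        cdf = (sympy.exp(-lam) * acc).evalf(60)
        if cdf <= q.evalf(60):
            best = k
        else:
            break
    return best


class TestDetectEdges:
    def test_flat_ccg_no_edge(self):
        ccg = _flat_ccg(count=40)
        pred = baseline_predictor(ccg)
        assert detect_edges(ccg, pred) == []

    def test_two_consecutive_bin_rule(self):
        ccg = _flat_ccg(count=10)
        pred = baseline_predictor(ccg)
        win = np.flatnonzero((ccg.lags_ms > 1.5) & (ccg.lags_ms <= 4.0))
        # a single extreme bin is NOT an edge ...
        counts = ccg.counts.copy()
        counts[win[2]] = 500
        one = Ccg(counts, ccg.lags_ms, 0.5, 1000, 1000)
        assert detect_edges(one, pred) == []
        # ... two consecutive extreme bins are
        counts2 = ccg.counts.copy()
        counts2[win[2]] = counts2[win[3]] = 500
        two = Ccg(counts2, ccg.lags_ms, 0.5, 1000, 1000)
        edges = detect_edges(two, pred, pre=1, post=2)
        assert len(edges) == 1 and edges[0].sign == "E"

    def test_planted_pair_detected(self):
        ds, _ = simulate_spike_network([5.0, 5.0], 600.0, [(0, 1, 0.1)], seed=1)
        ccg = compute_ccg(ds.spike_times[0], ds.spike_times[1])
        pred = baseline_predictor(ccg)
        edges = detect_edges(ccg, pred, pre=0, post=1)
        assert [e.sign for e in edges] == ["E"]

    def test_inhibitory_trough_detected_at_high_rates(self):
        ds, _ = simulate_spike_network([30.0, 30.0], 900.0, [(0, 1, -0.8)],
                                       seed=2)
        ccg = compute_ccg(ds.spike_times[0], ds.spike_times[1])
        pred = baseline_predictor(ccg)
        edges = detect_edges(ccg, pred, pre=0, post=1)
        assert [e.sign for e in edges] == ["I"]

    def test_misaligned_predictor_rejected(self):
        ccg = _flat_ccg()
        with pytest.raises(ValueError):
            detect_edges(ccg, np.zeros(10))


class TestTransmission:
    def test_counts_equal_predictor_zero(self):
        ccg = _flat_ccg(count=25)
        tp, p2b = transmission_probability(ccg, ccg.counts.astype(float))
        assert tp == 0.0
        assert p2b == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.1, 0.2])
    def test_planted_probability_recovered(self, p):
        ests = []
        for seed in range(3):
            ds, _ = simulate_spike_network([5.0, 5.0], 600.0, [(0, 1, p)],
                                           seed=10 + seed)
            ccg = compute_ccg(ds.spike_times[0], ds.spike_times[1])
            ests.append(transmission_probability(ccg)[0])
        assert np.mean(ests) == pytest.approx(p, rel=0.25)

    def test_inhibitory_thinning_negative(self):
        ds, _ = simulate_spike_network([20.0, 20.0], 600.0, [(0, 1, -0.2)],
                                       seed=3)
        ccg = compute_ccg(ds.spike_times[0], ds.spike_times[1])
        assert transmission_probability(ccg)[0] < 0


class TestStateDependence:
    STATES = [(0.0, 300.0, "WAKE"), (300.0, 600.0, "NREM")]

    def test_wake_doubling_detected_across_population(self):
        per_edge = []
        for i in range(20):
            ds, _ = simulate_spike_network(
                [6.0, 6.0], 600.0, [(0, 1, 0.08)], seed=200 + i,
                state_intervals=self.STATES,
                state_edge_scale={"WAKE": 2.0, "NREM": 1.0})
            per_edge.append(state_dependent_transmission(
                ds.spike_times[0], ds.spike_times[1], self.STATES,
                min_pre_spikes=500))
        n, med, p = compare_state_transmission(per_edge)
        assert n >= 20
        assert med > 0
        assert p < 0.05

    def test_null_population_rarely_significant(self):
        pvals = []
        for i in range(15):
            per_edge = []
            for j in range(8):
                ds, _ = simulate_spike_network(
                    [6.0, 6.0], 600.0, [(0, 1, 0.08)], seed=1000 + 8 * i + j,
                    state_intervals=self.STATES)
                per_edge.append(state_dependent_transmission(
                    ds.spike_times[0], ds.spike_times[1], self.STATES,
                    min_pre_spikes=500))
            pvals.append(compare_state_transmission(per_edge)[2])
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.2

    def test_insufficient_state_excluded(self):
        ds, _ = simulate_spike_network([5.0, 5.0], 600.0, [], seed=0,
                                       state_intervals=self.STATES)
        out = state_dependent_transmission(
            ds.spike_times[0], ds.spike_times[1],
            [(0.0, 300.0, "WAKE"), (300.0, 310.0, "NREM")])
        assert out["NREM"] is None

    def test_single_state_comparison_refused(self):
        with pytest.raises(ValueError):
            compare_state_transmission([{"WAKE": {"transmission": 0.1},
                                         "NREM": None}])


class TestCcgIdentity:
    def test_outgoing_edge_signs(self):
        edges = [Edge(1, 2, "E", np.array([2.0])),
                 Edge(3, 4, "I", np.array([2.0])),
                 Edge(5, 6, "E", np.array([2.0])),
                 Edge(5, 7, "I", np.array([2.0]))]
        ident = ccg_identity(edges)
        assert ident[1] == "E" and ident[3] == "I"
        assert ident[5] == "AMBIGUOUS"

    def test_network_identity_matches_truth(self, spike_network):
        ds, true_edges = spike_network
        edges = detect_network_edges(ds)
        ident = ccg_identity(edges)
        true_sign = {pre: sign for pre, _, sign, *_ in true_edges}
        agree = [ident[u] == true_sign[u] for u in ident if u in true_sign]
        assert agree and np.mean(agree) >= 0.95
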