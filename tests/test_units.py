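"""Unit classification and per-unit statistics."""

import numpy as np
import pytest

from laminarkit.synthetic import make_waveform, poisson_train
from laminarkit.units import (burst_index, classify_units, classify_waveform,
                              cluster_by_ic_coupling, detect_down_active,
                              optotag, state_rate_table, up_state_dynamics)

FS_WF = 20000.0


class TestWaveformClassification:
    @pytest.mark.parametrize("tp,expected", [(0.60, "E"), (0.40, "I"),
                                             (0.90, "E"), (0.30, "I")])
    def test_trough_to_peak_boundary(self, tp, expected):
        cls, got_tp = classify_waveform(make_waveform(tp), FS_WF)
        assert cls == expected
        assert got_tp == pytest.approx(tp, abs=0.1)

    def test_positive_waveform(self):
        cls, tp = classify_waveform(make_waveform(0.5, positive=True), FS_WF)
        assert cls == "POSITIVE"

    def test_scale_invariance(self):
        wf = make_waveform(0.7)
        for alpha in (0.01, 1.0, 250.0):
            assert classify_waveform(alpha * wf, FS_WF)[0] == "E"

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError):
            classify_waveform(np.zeros(64), FS_WF)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            classify_waveform(np.zeros(16), FS_WF)

    def test_fiber_outlier_flagged_population(self):
        # the 5 SD rule needs a reasonably sized population: the largest
        # possible z-score in a sample of n is (n-1)/sqrt(n)
        rng = np.random.default_rng(0)
        waveforms = {}
        for u in range(40):
            tp = 0.3 if u % 4 == 0 else 0.8
            waveforms[u] = make_waveform(tp + 0.02 * rng.standard_normal())
        # fiber volley: very narrow spiky triphasic event
        t = np.arange(64) / FS_WF * 1e3
        waveforms[99] = (-np.exp(-0.5 * ((t - 1.0) / 0.03) ** 2)
                         + 0.8 * np.exp(-0.5 * ((t - 1.12) / 0.025) ** 2))
        out = classify_units(waveforms, FS_WF)
        assert out.loc[99, "waveform_class"] == "FIBER"
        # ordinary narrow waveforms must NOT be swept up as fibers
        narrow = [u for u in range(40) if u % 4 == 0]
        assert (out.loc[narrow, "waveform_class"] == "I").all()


class TestOptotag:
    def _pulses(self, n=500):
        return np.arange(n) * 1.0 + 5.0

    def test_planted_response_tagged(self):
        rng = np.random.default_rng(0)
        pulses = self._pulses()
        base = poisson_train(2.0, 520.0, rng)
        resp = pulses[rng.random(pulses.size) < 0.8] + 0.003
        spk = np.sort(np.concatenate([base, resp]))
        tagged, peak, mu, sd, degen = optotag(spk, pulses)
        assert tagged and not degen

    def test_no_response_not_tagged(self):
        rng = np.random.default_rng(1)
        spk = poisson_train(2.0, 520.0, rng)
        assert not optotag(spk, self._pulses())[0]

    def test_null_false_positive_rate(self):
        """Rate-matched pulse-independent units tagged in < 1% of trials."""
        false = 0
        n_trials = 200
        for i in range(n_trials):
            rng = np.random.default_rng(100 + i)
            spk = poisson_train(4.0, 520.0, rng)
            if optotag(spk, self._pulses())[0]:
                false += 1
        assert false / n_trials < 0.01

    def test_silent_baseline_degenerate_path(self):
        pulses = self._pulses(150)
        spk = pulses[:120] + 0.002  # responds, never fires otherwise
        tagged, *_, degen = optotag(np.sort(spk), pulses)
        assert tagged and degen

    def test_too_few_pulses_rejected(self):
        with pytest.raises(ValueError):
            optotag(np.arange(10.0), np.arange(50.0))


class TestBurstIndex:
    def test_poisson_near_one(self):
        vals = [burst_index(poisson_train(20.0, 500.0, np.random.default_rng(i)))
                for i in range(30)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_refractory_near_zero(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(0.02 + rng.exponential(0.03, 5000))
        assert burst_index(t) < 0.05

    def test_planted_burster_exceeds_two(self):
        rng = np.random.default_rng(1)
        base = poisson_train(5.0, 600.0, rng)
        doublets = base[rng.random(base.size) < 0.5] + 0.004
        assert burst_index(np.sort(np.concatenate([base, doublets]))) > 2.0

    def test_results_variant_windows(self):
        rng = np.random.default_rng(2)
        t = poisson_train(20.0, 300.0, rng)
        v = burst_index(t, numerator_ms=(3.0, 10.0))
        assert v == pytest.approx(1.0, abs=0.2)

    def test_empty_baseline_flagged_nan(self):
        # tight bursts 500 ms apart: no spike pairs at 200-300 ms lags
        t = np.sort((np.arange(100) * 0.5)[:, None]
                    + np.array([0.0, 0.004, 0.008])).ravel()
        with pytest.warns(UserWarning):
            assert np.isnan(burst_index(t))


class TestUpStateDynamics:
    def _onsets(self, n=300):
        return np.arange(n) * 1.0 + 0.5

    def test_constant_rate_ratio_near_one(self):
        rng = np.random.default_rng(0)
        spk = poisson_train(20.0, 320.0, rng)
        ratio, _ = up_state_dynamics(spk, self._onsets())
        assert 1.0 <= ratio < 1.5  # max/mean of a flat PETH, binomial noise

    def test_onset_burst_ratio_exceeds_two(self):
        rng = np.random.default_rng(1)
        onsets = self._onsets()
        base = poisson_train(5.0, 320.0, rng)
        burst = np.repeat(onsets, 2) + rng.uniform(0, 0.05, onsets.size * 2)
        ratio, _ = up_state_dynamics(np.sort(np.concatenate([base, burst])),
                                     onsets)
        assert ratio > 2.0

    def test_planted_first_spike_latency(self):
        rng = np.random.default_rng(2)
        onsets = self._onsets()
        first = onsets + 0.010 + 0.001 * rng.standard_normal(onsets.size)
        later = np.repeat(onsets, 3) + rng.uniform(0.1, 0.9, onsets.size * 3)
        _, latency = up_state_dynamics(np.sort(np.concatenate([first, later])),
                                       onsets)
        assert latency == pytest.approx(0.010, abs=0.003)

    def test_silent_unit_flagged(self):
        with pytest.warns(UserWarning):
            ratio, _ = up_state_dynamics(np.array([1000.0]), self._onsets())
        assert np.isnan(ratio)

    def test_too_few_onsets_rejected(self):
        with pytest.raises(ValueError):
            up_state_dynamics(np.arange(100.0), np.arange(10.0))


def _alternating_events(n=150, down_s=0.1, up_s=0.9):
    downs, ups = [], []
    t = 0.0
    for _ in range(n):
        downs.append((t, t + down_s))
        ups.append((t + down_s, t + down_s + up_s))
        t += down_s + up_s
    return downs, ups


class TestDownActive:
    def test_planted_down_active_flagged(self, nrem_down_active_session):
        cfg, rec, spikes, _, truth = nrem_down_active_session
        da = truth.unit_table.loc[truth.unit_table.true_class == "DOWN_ACTIVE",
                                  "unit_id"]
        assert len(da) == 1
        res = detect_down_active(spikes.spike_times[int(da.iloc[0])],
                                 truth.down_intervals(), truth.up_intervals())
        assert res.flagged
        assert res.rate_down_hz > res.rate_up_hz

    def test_regular_up_active_unit_not_flagged(self, nrem_down_active_session):
        cfg, rec, spikes, _, truth = nrem_down_active_session
        regular = truth.unit_table.loc[truth.unit_table.true_class == "E",
                                       "unit_id"].iloc[0]
        res = detect_down_active(spikes.spike_times[int(regular)],
                                 truth.down_intervals(), truth.up_intervals())
        assert not res.flagged

    def test_null_false_positive_rate_below_alpha(self):
        downs, ups = _alternating_events()
        false = 0
        n_trials = 500
        for i in range(n_trials):
            rng = np.random.default_rng(i)
            spk = poisson_train(5.0, 150.0, rng)  # state-independent
            if detect_down_active(spk, downs, ups).flagged:
                false += 1
        assert false / n_trials <= 0.05

    def test_silent_unit_not_flagged(self):
        downs, ups = _alternating_events(60)
        res = detect_down_active(np.empty(0), downs, ups)
        assert not res.flagged


class TestCouplingClusters:
    def _planted_profiles(self, k=3, per=20, sep=1.0, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.random((k, 6)) * 0.2
        for j in range(k):
            centers[j, j % 6] += sep
        X = np.vstack([c + 0.03 * rng.standard_normal((per, 6))
                       for c in centers])
        labels = np.repeat(np.arange(k), per)
        return X, labels

    def test_three_separated_profiles_recovered_exactly(self):
        X, labels = self._planted_profiles()
        res = cluster_by_ic_coupling(X, seed=0)
        assert res.k == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, res.assignment) == 1.0

    def test_identical_profiles_degenerate_single_cluster(self):
        X = np.ones((25, 6)) * 0.4
        res = cluster_by_ic_coupling(X, seed=0)
        assert res.degenerate and res.k == 1

    def test_deterministic_given_seed(self):
        X, _ = self._planted_profiles(seed=3)
        a = cluster_by_ic_coupling(X, seed=7)
        b = cluster_by_ic_coupling(X, seed=7)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            cluster_by_ic_coupling(np.ones((5, 6)))


class TestStateRates:
    STATES = [(0.0, 100.0, "WAKE"), (100.0, 200.0, "NREM")]

    def test_equal_rates_unit_ratio(self):
        spk = np.arange(0, 200, 0.1)
        df = state_rate_table(spk, self.STATES)
        assert df.attrs["wake_nrem_ratio"] == pytest.approx(1.0)

    def test_planted_wake_elevation(self, three_state_session):
        cfg, rec, spikes, _, truth = three_state_session
        deep = truth.unit_table[(truth.unit_table.layer >= 5)
                                & (truth.unit_table.true_class != "DOWN_ACTIVE")]
        ratios = []
        for _, row in deep.iterrows():
            df = state_rate_table(spikes.spike_times[int(row.unit_id)],
                                  truth.state_intervals)
            expected = row.expected_rate_wake_hz / row.expected_rate_nrem_hz
            ratios.append(df.attrs["wake_nrem_ratio"] / expected)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)

    def test_zero_nrem_spikes_infinite_ratio(self):
        spk = np.arange(0, 100, 0.5)  # silent during NREM
        df = state_rate_table(spk, self.STATES)
        assert np.isinf(df.attrs["wake_nrem_ratio"])

    def test_missing_state_undefined(self):
        df = state_rate_table(np.arange(0, 90, 0.5), [(0.0, 100.0, "WAKE")])
        assert np.isnan(df.attrs["wake_nrem_ratio"])
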