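"""Delay estimation, transfer probabilities, asymmetry and vectors."""

import numpy as np
import pytest

from modgate.bursts import NetworkBurst
from modgate.propagation import (DelayEstimate, burst_delay, classify_sender,
                                 conditional_propagation_map,
                                 count_transmitted, longterm_asymmetry,
                                 propagation_speed, propagation_variability,
                                 propagation_vector,
                                 rate_correlation_model,
                                 transfer_probability_model,
                                 transfer_probability_recording,
                                 _peak_lag)

BIN = 2.0


def _bump(center_ms, total_ms=4000.0, sigma_ms=20.0, amp=10.0):
    t = np.arange(0, total_ms, BIN)
    return amp * np.exp(-0.5 * ((t - center_ms) / sigma_ms) ** 2)


class TestBurstDelay:
    def test_identical_traces_zero_lag(self):
        a = _bump(1000)
        est = burst_delay(a, a.copy())
        assert est.lag_ms == 0.0
        assert est.peak_corr == pytest.approx(1.0, abs=1e-6)

    def test_known_shift_recovered(self):
        a = _bump(1000)
        b = _bump(1030)            # b trails a by 30 ms -> a leads
        est = burst_delay(a, b)
        assert est.lag_ms == pytest.approx(30.0, abs=BIN)
        assert burst_delay(b, a).lag_ms == pytest.approx(-30.0, abs=BIN)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            burst_delay(_bump(1000), np.zeros(2000))

    def test_tie_breaks_to_smallest_lag(self):
        lags = np.arange(-5, 6)
        c = np.zeros(11)
        c[lags == 2] = 1.0
        c[lags == 5] = 1.0
        assert _peak_lag(lags, c)[0] == 2
        c[:] = 0
        c[lags == -3] = 1.0
        c[lags == 3] = 1.0
        assert abs(_peak_lag(lags, c)[0]) == 3


def test_classify_sender_keeps_leading_bursts():
    bursts = [NetworkBurst(start=i * 1000.0, end=i * 1000.0 + 100,
                           peak=i * 1000.0 + 50) for i in range(10)]
    lags = [30, 10, -5, 40, -20, 15, 5, -1, 25, 60]   # 7 positive
    delays = [DelayEstimate(lag_ms=l, peak_corr=0.9) for l in lags]
    kept, rejected = classify_sender(bursts, delays)
    assert len(kept) == 7 and len(rejected) == 3
    all_pos = [DelayEstimate(lag_ms=1.0, peak_corr=1.0)] * 10
    kept, rejected = classify_sender(bursts, all_pos)
    assert len(kept) == 10 and not rejected


class TestConditionalPropagation:
    def test_identical_intensities_correlate_fully(self):
        rng = np.random.default_rng(0)
        s = rng.random(200)
        _, cond, r = conditional_propagation_map(s, s)
        assert r == pytest.approx(1.0)
        assert np.allclose(cond.sum(axis=0)[cond.sum(axis=0) > 0], 1.0)

    def test_shuffled_pairs_uncorrelated(self):
        rng = np.random.default_rng(1)
        s = rng.random(2000)
        r = conditional_propagation_map(s, rng.permutation(s))[2]
        assert abs(r) < 2 / np.sqrt(s.size) * 2

    def test_threshold_rule_projects_bimodally(self):
        """Receiver responds only above a sender threshold: the identity
        projection of the pairs is bimodal."""
        from modgate.patterns import bimodality_coefficient, identity_projection
        rng = np.random.default_rng(2)
        s = rng.random(3000)
        recv = np.where(s > 0.5, s + rng.normal(0, 0.05, s.size), 0.0)
        proj = identity_projection(s, recv)
        assert bimodality_coefficient(proj) > 5.0 / 9.0


class TestTransferProbability:
    def _bursts(self, starts):
        return [NetworkBurst(start=s, end=s + 100.0, peak=s + 40.0)
                for s in starts]

    def test_mirrored_and_empty(self):
        a = self._bursts([1000, 5000, 9000])
        assert transfer_probability_recording(a, a) == 1.0
        assert transfer_probability_recording(a, []) == 0.0
        with pytest.raises(ValueError):
            transfer_probability_recording([], a)

    def test_hand_counted_fraction(self):
        a = self._bursts(np.arange(10) * 5000.0)
        b = self._bursts([s + 300 for s in np.arange(7) * 5000.0])
        assert transfer_probability_recording(a, b) == pytest.approx(0.7)

    def test_model_baseline_correction(self):
        a = self._bursts(np.arange(10) * 5000.0)
        b = self._bursts([s + 100 for s in np.arange(6) * 5000.0])
        assert count_transmitted(a, b) == 6
        assert transfer_probability_model(a, b, baseline_transmitted=1) == \
            pytest.approx(5.0 / 9.0)
        assert transfer_probability_model(a, b, baseline_transmitted=6) == 0.0
        full = transfer_probability_model(a, self._bursts(
            [s + 100 for s in np.arange(10) * 5000.0]), baseline_transmitted=0)
        assert full == 1.0
        with pytest.raises(ValueError):
            transfer_probability_model(a, b, baseline_transmitted=10)


class TestLongtermAsymmetry:
    def test_autocorrelation_is_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.random(4000)
        assert longterm_asymmetry(a, a) == 0.0

    def test_exact_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(4000), rng.random(4000)
        assert longterm_asymmetry(a, b) == -longterm_asymmetry(b, a)

    def test_all_mass_at_positive_lags(self):
        a = _bump(1000, sigma_ms=15.0)
        b = _bump(1100, sigma_ms=15.0)
        assert longterm_asymmetry(a, b, max_lag_ms=500) == pytest.approx(1.0,
                                                                        abs=0.05)
        assert longterm_asymmetry(b, a, max_lag_ms=500) == pytest.approx(-1.0,
                                                                        abs=0.05)

    def test_mixed_lead_fraction_sets_sign_and_scale(self):
        """70% of bursts a leads by 20 ms, 30% b leads: asymmetry is
        positive with magnitude near (0.7 - 0.3)."""
        rng = np.random.default_rng(5)
        n_bins = int(600_000 / BIN)
        a = np.zeros(n_bins)
        b = np.zeros(n_bins)
        tloc = np.arange(-50, 51) * BIN
        bump = 10 * np.exp(-0.5 * (tloc / 8.0) ** 2)
        shift = int(20 / BIN)
        for t0 in np.arange(2000, 598_000, 2000.0):
            i = int(t0 / BIN) - 50
            if rng.random() < 0.7:
                a[i:i + 101] += bump
                b[i + shift:i + shift + 101] += bump
            else:
                b[i:i + 101] += bump
                a[i + shift:i + shift + 101] += bump
        asym = longterm_asymmetry(a, b, max_lag_ms=100)
        assert 0.2 < asym < 0.6


class TestPropagationVector:
    def test_single_neighbor_east(self):
        c = _bump(1000)
        n = _bump(1040)            # neighbor trails by 40 ms
        v = propagation_vector(c, [n], [(500.0, 0.0)])
        assert v.theta == pytest.approx(0.0, abs=1e-9)
        assert v.magnitude == pytest.approx(40.0, abs=BIN)

    def test_opposite_neighbors_cancel(self):
        c = _bump(1000)
        n = _bump(1040)
        v = propagation_vector(c, [n, n], [(500.0, 0.0), (-500.0, 0.0)])
        assert not v.defined
        assert np.isnan(v.theta)

    def test_planar_wave_direction(self):
        """A rightward wave across a chain gives theta = 0 everywhere."""
        delays = [0.0, 30.0, 60.0, 90.0]
        traces = [_bump(1000 + d) for d in delays]
        for i in (1, 2):
            nbrs = [traces[i - 1], traces[i + 1]]
            dirs = [(-500.0, 0.0), (500.0, 0.0)]
            v = propagation_vector(traces[i], nbrs, dirs)
            assert v.theta == pytest.approx(0.0, abs=1e-9)

    def test_variability_shrinks_when_directions_collapse(self):
        rng = np.random.default_rng(6)
        diverse = [rng.uniform(-np.pi, np.pi, 50) for _ in range(4)]
        collapsed = [np.full(50, 0.3) + rng.normal(0, 0.05, 50)
                     for _ in range(4)]
        assert propagation_variability(collapsed) < \
            propagation_variability(diverse)


class TestRateCorrelation:
    def test_identical_counts_correlate_fully(self):
        rng = np.random.default_rng(7)
        starts = np.arange(40) * 2000.0
        bursts = [NetworkBurst(start=s, end=s + 200, peak=s + 50)
                  for s in starts]
        times, clusters = [], []
        for s in starts:
            k = rng.integers(20, 100)
            tt = rng.uniform(s, s + 400, k)
            times.extend(tt)
            clusters.extend([1] * k)
            times.extend(tt)           # receiver mirrors sender
            clusters.extend([2] * k)
        r = rate_correlation_model(np.array(times), np.array(clusters), bursts)
        assert r == pytest.approx(1.0)

    def test_independent_counts_uncorrelated(self):
        rng = np.random.default_rng(8)
        starts = np.arange(200) * 2000.0
        bursts = [NetworkBurst(start=s, end=s + 200, peak=s + 50)
                  for s in starts]
        times, clusters = [], []
        for s in starts:
            for c in (1, 2):
                k = rng.integers(20, 100)
                times.extend(rng.uniform(s, s + 400, k))
                clusters.extend([c] * k)
        r = rate_correlation_model(np.array(times), np.array(clusters), bursts)
        assert abs(r) < 2 / np.sqrt(len(bursts)) * 2


def test_propagation_speed_conversion():
    assert propagation_speed(500.0, 100.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        propagation_speed(500.0, 0.0)
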