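"""Synthetic-recording generator and ground-truth recovery."""

import numpy as np
import pytest

from modgate.bursts import BurstDetectionParams, detect_bursts_channel
from modgate.patterns import entropy_from_probs, pattern_entropy
from modgate.propagation import burst_delay
from modgate.signal import compute_ai
from modgate.synth import (ClusterGeometry, cells_from_area, make_schedule,
                           preset_geometry, render_voltage)


class TestCellsFromArea:
    @pytest.mark.parametrize("area,expected", [
        (1000.0, 6.0), (10_000.0, 77.1), (100.0, 0.0), (0.0, 0.0)])
    def test_calibration(self, area, expected):
        assert cells_from_area(area) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            cells_from_area(-1.0)


class TestGeometry:
    def test_grid_positions(self):
        g = preset_geometry("grid6x10")
        pos = g.positions()
        assert pos.shape == (60, 2)
        assert pos[:, 0].max() == 9 * 500.0
        assert pos[:, 1].max() == 5 * 500.0
        assert set(g.neighbors(0)) == {1, 10}

    def test_cell_counts_from_diameters(self):
        g = ClusterGeometry(rows=1, cols=2, diameters_um=[80.0, 200.0])
        counts = g.cell_counts()
        assert counts[0] == pytest.approx(
            max(0.0079 * np.pi * 40 ** 2 - 1.9, 0.0))
        assert counts[1] > counts[0]


class TestSchedule:
    def test_determinism(self):
        g = preset_geometry("chain3")
        s1 = make_schedule(g, seed=5)
        s2 = make_schedule(g, seed=5)
        assert len(s1.bursts) == len(s2.bursts)
        for a, b in zip(s1.bursts, s2.bursts):
            assert a.t0 == b.t0 and a.onsets == b.onsets

    def test_failure_prob_extremes(self):
        g = preset_geometry("chain3")
        full = [(0, (0, 1, 2))]
        s0 = make_schedule(g, full, [1.0], failure_prob=0.0, seed=1)
        assert all(b.participants == (0, 1, 2) for b in s0.bursts)
        s1 = make_schedule(g, full, [1.0], failure_prob=1.0, seed=1)
        assert all(b.participants == (0,) for b in s1.bursts)

    def test_onsets_follow_hop_delays(self):
        g = preset_geometry("chain3")
        s = make_schedule(g, [(0, (0, 1, 2))], [1.0], hop_delay_mean=30.0,
                          hop_delay_sd=0.0, seed=2)
        for b in s.bursts:
            assert b.onsets[1] - b.onsets[0] == pytest.approx(30.0)
            assert b.onsets[2] - b.onsets[1] == pytest.approx(30.0)

    def test_pattern_entropy_recovered(self):
        """Empirical pattern entropy matches the table's entropy."""
        g = preset_geometry("pair")
        pats = [(0, (0,)), (1, (1,)), (0, (0, 1))]
        probs = [0.25, 0.25, 0.5]
        s = make_schedule(g, pats, probs, rate_hz=2.0,
                          duration_ms=400_000.0, min_interval_ms=100.0, seed=3)
        participation = [row for row in s.participation_matrix()]
        est = pattern_entropy(participation, 2).entropy
        true_h = entropy_from_probs(probs)
        n = len(s.bursts)
        # binomial SE of each pattern propagated to the entropy, ~3 SE
        assert est == pytest.approx(true_h, abs=3 * 1.2 / np.sqrt(n))


class TestRenderRoundTrip:
    def test_noise_only_recording(self):
        g = preset_geometry("pair")
        with pytest.warns(UserWarning, match="expected burst count"):
            s = make_schedule(g, [(0, (0, 1))], [1.0], rate_hz=0.001,
                              duration_ms=30_000.0, seed=4)
        s.bursts.clear()
        rec = render_voltage(s, noise_sigma=5.0, sporadic_rate_hz=0.0, seed=5)
        ai = compute_ai(rec)
        assert np.allclose(ai.nt, 5.0 * np.sqrt(2 / np.pi), atol=0.1)
        for ch in range(2):
            assert detect_bursts_channel(
                ai.ai[ch], ai.bin_ms, BurstDetectionParams.experiment_channel(),
                counts=False, active_floor=ai.floor()[ch]) == []

    def test_detection_sensitivity_and_precision(self, pair_data):
        schedule, _, ai = pair_data
        floors = ai.floor()
        params = BurstDetectionParams.experiment_channel()
        for ch in range(2):
            detected = detect_bursts_channel(ai.ai[ch], ai.bin_ms, params,
                                             counts=False,
                                             active_floor=floors[ch])
            truth = [b.onsets[ch] for b in schedule.bursts if ch in b.onsets]
            hits = sum(1 for t in truth
                       if any(b.start - 100 <= t <= b.end for b in detected))
            assert hits / len(truth) >= 0.95        # sensitivity
            false = sum(1 for b in detected
                        if not any(b.start - 100 <= t <= b.end for t in truth))
            assert false / max(len(detected), 1) <= 0.05   # precision

    def test_scheduled_delay_recovered(self, pair_data):
        """Mean recovered inter-cluster delay within one AI bin of the
        scheduled 30 ms hop delay."""
        schedule, _, ai = pair_data
        lags = []
        for b in schedule.bursts:
            if 0 not in b.onsets or 1 not in b.onsets:
                continue
            lo = max(0, int((b.t0 - 500) / ai.bin_ms))
            hi = min(ai.ai.shape[1], int((b.t0 + 800) / ai.bin_ms))
            est = burst_delay(ai.ai[0, lo:hi], ai.ai[1, lo:hi], ai.bin_ms)
            lags.append(est.lag_ms)
        assert len(lags) >= 10
        assert np.mean(lags) == pytest.approx(30.0, abs=2.0 + 3 *
                                              schedule.hop_delay_sd /
                                              np.sqrt(len(lags)))

    def test_amplitude_scales_intensity(self):
        from modgate.bursts import burst_intensity
        from modgate.synth import default_spike_template
        g = preset_geometry("pair")
        s = make_schedule(g, [(0, (0, 1))], [1.0], rate_hz=0.3,
                          duration_ms=60_000.0, seed=6, scale_sd=0.0)
        kw = dict(noise_sigma=1.0, sporadic_rate_hz=0.0, seed=7)
        rec1 = render_voltage(s, default_spike_template(), **kw)
        rec2 = render_voltage(s, 2 * default_spike_template(), **kw)
        out = []
        for rec in (rec1, rec2):
            ai = compute_ai(rec)
            b = detect_bursts_channel(ai.ai[0], ai.bin_ms,
                                      counts=False,
                                      active_floor=float(ai.floor()[0]))
            out.append(np.mean([burst_intensity(x, ai.ai[0], ai.bin_ms)
                                for x in b]))
        assert out[1] / out[0] == pytest.approx(2.0, rel=0.05)

    def test_distinct_seeds_similar_statistics(self):
        """Different seeds give statistically indistinguishable per-burst
        intensity distributions (two-sample KS sanity check)."""
        from scipy.stats import ks_2samp
        from modgate.bursts import burst_intensity
        g = preset_geometry("pair")
        intensities = []
        for seed in (8, 9):
            s = make_schedule(g, [(0, (0, 1))], [1.0], rate_hz=0.4,
                              duration_ms=120_000.0, seed=seed)
            rec = render_voltage(s, seed=seed + 10)
            ai = compute_ai(rec)
            bursts = detect_bursts_channel(ai.ai[0], ai.bin_ms, counts=False,
                                           active_floor=float(ai.floor()[0]))
            intensities.append([burst_intensity(b, ai.ai[0], ai.bin_ms)
                                for b in bursts])
        assert ks_2samp(*intensities).pvalue > 0.001
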