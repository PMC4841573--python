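"""Similarity matrices, pattern entropy, bimodality and burst sizes."""

import numpy as np
import pytest

from modgate.bursts import NetworkBurst
from modgate.patterns import (bimodality_coefficient, bimodality_reference,
                              burst_similarity, burst_size_stats,
                              entropy_from_probs, identity_projection,
                              pattern_entropy)
from modgate.signal import ActivityIntensitySeries
from modgate.synth import preset_geometry

BIN = 2.0


def _ai_with_bursts(templates, peaks_ms, total_ms=60_000.0, noise=0.0,
                    seed=0):
    """Two-channel AI with template bursts placed at the given peaks."""
    rng = np.random.default_rng(seed)
    n = int(total_ms / BIN)
    ai = np.zeros((len(templates[0]), n))
    for tmpl, pk in zip(templates, peaks_ms):
        c = int(pk / BIN)
        for ch, shape in enumerate(tmpl):
            w = len(shape)
            ai[ch, c - w // 2: c - w // 2 + w] += shape
    if noise:
        ai += rng.random(ai.shape) * noise
    return ActivityIntensitySeries(ai=np.maximum(ai, 0), bin_ms=BIN,
                                   nt=np.zeros(ai.shape[0]))


def _bump(width=100, amp=10.0):
    t = np.arange(width)
    return amp * np.exp(-0.5 * ((t - width / 2) / (width / 8)) ** 2)


class TestBurstSimilarity:
    def test_identical_bursts_fully_similar(self):
        tmpl = [_bump(), _bump(80, 5.0)]
        peaks = [5000.0, 15_000.0, 25_000.0]
        ai = _ai_with_bursts([tmpl] * 3, peaks)
        bursts = [NetworkBurst(start=p - 100, end=p + 100, peak=p)
                  for p in peaks]
        sim = burst_similarity(ai, bursts)
        assert np.allclose(sim.R, 1.0, atol=1e-6)

    def test_time_shift_within_window_ignored(self):
        """The lag-maximization makes similarity shift-invariant."""
        tmpl = [_bump(), _bump(80, 5.0)]
        ai = _ai_with_bursts([tmpl] * 2, [5000.0, 15_000.0])
        bursts = [NetworkBurst(start=4900, end=5100, peak=5000.0),
                  NetworkBurst(start=14_780, end=15_220,
                               peak=15_120.0)]   # peak estimate off by 120 ms
        sim = burst_similarity(ai, bursts)
        # small deficit from the non-overlapping window edges is expected
        assert sim.R[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        ai = ActivityIntensitySeries(ai=rng.random((2, 30_000)), bin_ms=BIN,
                                     nt=np.zeros(2))
        bursts = [NetworkBurst(start=p - 100, end=p + 100, peak=float(p))
                  for p in (5000.0, 15_000.0, 25_000.0)]
        sim = burst_similarity(ai, bursts)
        off = sim.R[~np.eye(3, dtype=bool)]
        # max over ~500 lags of a ~n=500 correlation: small but positive
        assert np.all(off < 0.25)

    def test_two_template_groups_recovered(self):
        """Clustering the similarity matrix separates two burst shapes."""
        a = [_bump(), np.zeros(100)]          # channel-0 bursts
        b = [np.zeros(100), _bump()]          # channel-1 bursts
        peaks = np.arange(10) * 5000.0 + 5000.0
        labels_true = [0, 1] * 5
        tmpls = [a if l == 0 else b for l in labels_true]
        ai = _ai_with_bursts(tmpls, peaks, noise=0.3, seed=2)
        bursts = [NetworkBurst(start=p - 100, end=p + 100, peak=p)
                  for p in peaks]
        sim = burst_similarity(ai, bursts)
        labels = sim.group_labels(2)
        same = np.array(labels_true) == np.array(labels_true)[0]
        grp = labels == labels[0]
        agreement = max((grp == same).mean(), (grp == ~same).mean())
        assert agreement >= 0.95

    def test_amplitude_rescaling_invariance(self):
        tmpl = [_bump(), _bump(80, 5.0)]
        peaks = [5000.0, 15_000.0]
        ai1 = _ai_with_bursts([tmpl] * 2, peaks)
        ai2 = ActivityIntensitySeries(ai=ai1.ai * 7.3, bin_ms=BIN,
                                      nt=np.zeros(2))
        bursts = [NetworkBurst(start=p - 100, end=p + 100, peak=p)
                  for p in peaks]
        r1 = burst_similarity(ai1, bursts).R
        r2 = burst_similarity(ai2, bursts).R
        np.testing.assert_allclose(r1, r2, atol=1e-9)


class TestPatternEntropy:
    def test_single_pattern_zero_entropy(self):
        s = pattern_entropy([(1, 0)] * 20, n_clusters=2)
        assert s.entropy == 0.0
        assert s.entropy_normalized == 0.0

    def test_two_equiprobable_patterns(self):
        s = pattern_entropy([(1, 0), (0, 1)] * 10, n_clusters=2)
        assert s.entropy == pytest.approx(1.0)
        assert s.entropy_normalized == pytest.approx(1.0 / np.log2(3))

    def test_printed_probabilities_in_nats(self):
        """The worked five-group example gives about 1.006 nats."""
        probs = [0.137, 0.673, 0.103, 0.005, 0.082]
        e = entropy_from_probs(probs, log_base=np.e)
        assert e == pytest.approx(1.006, abs=0.005)
        # the same probabilities in bits are materially larger
        assert entropy_from_probs(probs, 2.0) == pytest.approx(e / np.log(2))

    def test_relabeling_invariance(self):
        pats = [(1, 0, 0), (0, 1, 0), (0, 1, 0), (1, 1, 1)] * 5
        swapped = [(p[2], p[1], p[0]) for p in pats]
        e1 = pattern_entropy(pats, 3).entropy
        e2 = pattern_entropy(swapped, 3).entropy
        assert e1 == pytest.approx(e2)

    def test_coarsening_never_increases_entropy(self):
        rng = np.random.default_rng(3)
        pats = [tuple(rng.integers(0, 2, 3)) for _ in range(200)]
        pats = [p if any(p) else (1, 0, 0) for p in pats]
        merged = [(p[0] | p[1], p[2], 0) for p in pats]
        merged = [p if any(p) else (1, 0, 0) for p in merged]
        assert pattern_entropy(merged, 3).entropy <= \
            pattern_entropy(pats, 3).entropy + 1e-12

    def test_all_zero_pattern_rejected(self):
        with pytest.raises(ValueError):
            pattern_entropy([(0, 0)], 2)
        with pytest.raises(ValueError):
            pattern_entropy([], 2)


class TestBimodality:
    def test_reference_values(self):
        assert bimodality_reference() == pytest.approx(5.0 / 9.0)
        assert bimodality_reference(0.0, 0.0) == pytest.approx(1.0 / 3.0)
        assert bimodality_reference(0.0, -2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("sampler,target", [
        (lambda rng, n: rng.uniform(size=n), 5.0 / 9.0),
        (lambda rng, n: rng.normal(size=n), 1.0 / 3.0),
        (lambda rng, n: (rng.random(n) < 0.5).astype(float), 1.0),
    ])
    def test_estimator_converges(self, sampler, target):
        rng = np.random.default_rng(4)
        n = 10_000
        bc = bimodality_coefficient(sampler(rng, n))
        assert bc == pytest.approx(target, abs=5.0 / np.sqrt(n))

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            bimodality_coefficient(np.ones(100))
        with pytest.raises(ValueError):
            bimodality_coefficient([1.0, 2.0, 3.0])


def test_identity_projection():
    assert identity_projection([1.0], [1.0])[0] == pytest.approx(np.sqrt(2))
    assert identity_projection([0.0], [0.0])[0] == 0.0
    np.testing.assert_allclose(identity_projection([0.3], [0.9]),
                               identity_projection([0.9], [0.3]))


class TestBurstSizes:
    def test_single_electrode_degenerate_area(self):
        geom = preset_geometry("grid6x10")
        b = NetworkBurst(start=0, end=100, peak=50,
                         channel_ids=np.array([7]))
        df = burst_size_stats([b], geom.positions())
        assert df.loc[0, "bounding_area"] == 0.0

    def test_full_grid_area(self):
        geom = preset_geometry("grid6x10")
        full = NetworkBurst(start=0, end=100, peak=50,
                            channel_ids=np.arange(60))
        single = NetworkBurst(start=500, end=600, peak=550,
                              channel_ids=np.array([3]))
        df = burst_size_stats([full, single], geom.positions())
        assert df.loc[0, "bounding_area"] == pytest.approx((9 * 500) * (5 * 500))
        assert df.loc[0, "bounding_area_norm"] == 1.0
        assert df.loc[0, "n_active_norm"] == 1.0

    def test_intensity_per_cluster(self):
        geom = preset_geometry("pair")
        bursts = [NetworkBurst(start=0, end=100, peak=50,
                               channel_ids=np.arange(2)),
                  NetworkBurst(start=500, end=600, peak=550,
                               channel_ids=np.array([0]))]
        df = burst_size_stats(bursts, geom.positions(), intensities=[10.0, 5.0])
        assert df["intensity_per_cluster_norm"].max() == 1.0
        assert df.loc[0, "intensity_per_cluster_norm"] == 1.0
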