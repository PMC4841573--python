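"""Propagation statistics between clusters.

Delays are read off the peak of the Pearson-normalized cross-covariance
of Gaussian-smoothed activity traces; the sign convention throughout is
that a positive lag means the first argument *leads* the second.  On top
of burst-level delays the module builds the sending/receiving
classification, conditional-propagation maps, transfer probabilities
(recording and model variants, the latter with the disconnected-network
baseline correction), the long-term directional asymmetry, planar
propagation vectors, and distance-resolved profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bursts import NetworkBurst
from .signal import ActivityIntensitySeries, gaussian_smooth

__all__ = [
    "DelayEstimate", "PropagationVector", "normalized_xcov", "burst_delay",
    "classify_sender", "conditional_propagation_map",
    "transfer_probability_recording", "count_transmitted",
    "initiated_in_first", "transfer_probability_model", "longterm_asymmetry",
    "propagation_vector", "propagation_variability", "distance_profiles",
    "rate_correlation_model", "propagation_speed",
]


@dataclass
class DelayEstimate:
    lag_ms: float                 # positive: first trace leads the second
    peak_corr: float
    burst_id: Optional[int] = None


@dataclass
class PropagationVector:
    """Lag-weighted mean flow direction of one cluster during one burst."""

    vx: float
    vy: float
    cluster_id: Optional[int] = None
    burst_id: Optional[int] = None

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.vx, self.vy))

    @property
    def defined(self) -> bool:
        return self.magnitude > 0

    @property
    def theta(self) -> float:
        """Angle vs the positive x-axis, in (-pi, pi]; NaN if undefined."""
        if not self.defined:
            return float("nan")
        return float(np.arctan2(self.vy, self.vx))


def normalized_xcov(a: np.ndarray, b: np.ndarray, max_lag_bins: int):
    """Pearson-normalized cross-covariance c(k) = <a(t) b(t+k)> / (sd_a sd_b).

    Returns ``(lags, c)`` with integer lags in [-max_lag, max_lag]; at
    lag 0 the value is the Pearson correlation of the two series.
    Raises on zero-variance input.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must share one time grid")
    ac = a - a.mean()
    bc = b - b.mean()
    sa, sb = ac.std(), bc.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance trace: delay undefined")
    full = np.correlate(bc, ac, mode="full")   # index k: sum a(t) b(t+k)
    lags = np.arange(-(a.size - 1), a.size)
    keep = np.abs(lags) <= max_lag_bins
    return lags[keep], full[keep] / (a.size * sa * sb)


def _peak_lag(lags: np.ndarray, c: np.ndarray) -> tuple[int, float]:
    """Lag of the maximum; exact ties resolve to the smallest |lag|."""
    best = np.nonzero(c == c.max())[0]
    order = sorted(best, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    i = order[0]
    return int(lags[i]), float(c[i])


def burst_delay(ai_a: np.ndarray, ai_b: np.ndarray, bin_ms: float = 2.0,
                smooth_sigma: float = 10.0, max_lag_ms: float = 500.0,
                burst_id: Optional[int] = None) -> DelayEstimate:
    """Delay between two activity snippets covering the same burst.

    Both traces are smoothed (sigma 10 ms) and the lag of the
    cross-covariance peak is returned in ms; positive means ``ai_a``
    leads ``ai_b``.
    """
    a = gaussian_smooth(ai_a, smooth_sigma, bin_ms)
    b = gaussian_smooth(ai_b, smooth_sigma, bin_ms)
    lags, c = normalized_xcov(a, b, int(round(max_lag_ms / bin_ms)))
    lag, peak = _peak_lag(lags, c)
    return DelayEstimate(lag_ms=lag * bin_ms, peak_corr=peak, burst_id=burst_id)


def classify_sender(bursts: Sequence[NetworkBurst],
                    delays: Sequence[DelayEstimate]):
    """Split a burst pool into sender-leading and rejected bursts.

    ``delays[i]`` is the sender-vs-receiver delay of ``bursts[i]``;
    bursts whose sending cluster leads (positive lag) are kept.
    """
    if len(bursts) != len(delays):
        raise ValueError("one delay per burst required")
    kept, rejected = [], []
    for b, d in zip(bursts, delays):
        (kept if d.lag_ms > 0 else rejected).append(b)
    return kept, rejected


def conditional_propagation_map(sender: np.ndarray, receiver: np.ndarray,
                                n_bins: int = 20):
    """Joint map of normalized burst intensities, column-normalized.

    Returns ``(bin_edges, cond_map, pearson_r)`` where column ``j`` of
    ``cond_map`` is the conditional probability distribution of the
    receiving cluster's intensity given the sending cluster's intensity
    falls in bin ``j``.
    """
    sender = np.asarray(sender, dtype=float)
    receiver = np.asarray(receiver, dtype=float)
    if sender.size != receiver.size:
        raise ValueError("paired intensities required")
    if sender.size < 30:
        warnings.warn("fewer than 30 bursts: correlation is low-power",
                      stacklevel=2)
    if sender.std() == 0 or receiver.std() == 0:
        raise ValueError("degenerate intensities: correlation undefined")
    lo = min(sender.min(), receiver.min())
    hi = max(sender.max(), receiver.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _, _ = np.histogram2d(receiver, sender, bins=[edges, edges])
    col = hist.sum(axis=0, keepdims=True)
    cond = np.divide(hist, col, out=np.zeros_like(hist), where=col > 0)
    r = float(stats.pearsonr(sender, receiver).statistic)
    return edges, cond, r


def transfer_probability_recording(bursts_a: Sequence[NetworkBurst],
                                   bursts_b: Sequence[NetworkBurst],
                                   window_ms: float = 1000.0) -> float:
    """Fraction of bursts in ``a`` followed by a burst onset in ``b``
    within ``window_ms``."""
    if len(bursts_a) == 0:
        raise ValueError("no bursts in the conditioning cluster")
    onsets_b = np.sort([b.start for b in bursts_b])
    hits = sum(
        bool(np.any((onsets_b >= b.start) & (onsets_b <= b.start + window_ms)))
        for b in bursts_a)
    return hits / len(bursts_a)


def initiated_in_first(bursts_1: Sequence[NetworkBurst],
                       bursts_2: Sequence[NetworkBurst],
                       window_ms: float = 200.0) -> list[NetworkBurst]:
    """Bursts of cluster 1 that were not preceded by cluster-2 activity.

    A cluster-1 burst whose onset falls within ``window_ms`` *after* a
    cluster-2 burst peak was initiated by the other cluster and does not
    belong in the pool of bursts that could propagate 1 -> 2.
    """
    peaks_2 = np.sort([b.peak for b in bursts_2])
    return [b for b in bursts_1
            if not np.any((peaks_2 >= b.start - window_ms)
                          & (peaks_2 < b.start))]


def count_transmitted(bursts_1: Sequence[NetworkBurst],
                      bursts_2: Sequence[NetworkBurst],
                      window_ms: float = 200.0) -> int:
    """Bursts of cluster 1 followed by a cluster-2 burst *peak* within
    ``window_ms`` of their onset."""
    peaks_2 = np.sort([b.peak for b in bursts_2])
    return int(sum(
        bool(np.any((peaks_2 >= b.start) & (peaks_2 <= b.start + window_ms)))
        for b in bursts_1))


def transfer_probability_model(bursts_1: Sequence[NetworkBurst],
                               bursts_2: Sequence[NetworkBurst],
                               window_ms: float = 200.0,
                               baseline_transmitted: int = 0,
                               baseline_total: Optional[int] = None) -> float:
    """Baseline-corrected model transfer probability.

    With ``T`` transmitted bursts out of ``N`` and ``T0`` transmitted
    counts measured in a disconnected (modularity 0) control of the same
    duration, returns ``(T - T0) / (N - T0)`` clamped to [0, 1]: chance
    coincidences of two independently bursting clusters are removed from
    both numerator and denominator.  Passing ``baseline_total`` switches
    the denominator to ``N - N0`` (the alternative reading that removes
    the λ = 0 *total* burst count instead).
    """
    n = len(bursts_1)
    t = count_transmitted(bursts_1, bursts_2, window_ms)
    t0 = baseline_transmitted
    sub = t0 if baseline_total is None else baseline_total
    if n <= sub:
        raise ValueError("baseline exceeds total burst count; undefined")
    return float(np.clip((t - t0) / (n - sub), 0.0, 1.0))


def longterm_asymmetry(trace_a: np.ndarray, trace_b: np.ndarray,
                       bin_ms: float = 2.0, max_lag_ms: float = 2000.0) -> float:
    """Directional asymmetry of the rectified cross-correlation.

    Negative correlation values are zeroed; the result is
    (sum over positive lags - sum over negative lags) / total, in
    [-1, 1].  Positive values mean ``trace_a`` tends to lead.  The
    cross-covariance is averaged over both evaluation orders so that
    swapping the arguments flips the sign exactly (bit-for-bit).
    """
    max_lag = int(round(max_lag_ms / bin_ms))
    lags, c_ab = normalized_xcov(trace_a, trace_b, max_lag)
    _, c_ba = normalized_xcov(trace_b, trace_a, max_lag)
    c = 0.5 * (c_ab + c_ba[::-1])
    c = np.maximum(c, 0.0)
    # both sides summed in ascending |lag| order: swap is bit-exact
    pos = c[lags > 0].sum()
    neg = np.ascontiguousarray(c[lags < 0][::-1]).sum()
    if pos + neg == 0:
        raise ValueError("no positive correlation mass: asymmetry undefined")
    return float((pos - neg) / (pos + neg))


def propagation_vector(center_trace: np.ndarray,
                       neighbor_traces: Sequence[np.ndarray],
                       directions: Sequence[Sequence[float]],
                       bin_ms: float = 2.0, smooth_sigma: float = 50.0,
                       max_lag_ms: float = 500.0,
                       cluster_id: Optional[int] = None,
                       burst_id: Optional[int] = None) -> PropagationVector:
    """Mean lag-weighted flow vector of one cluster during one burst.

    ``directions[i]`` is the physical direction (um, need not be unit)
    from the cluster to its i-th active neighbor.  Each neighbor
    contributes ``lag * unit_direction``: a positive lag (cluster leads)
    points the contribution toward that neighbor.  Neighbors with flat
    traces are skipped.
    """
    vecs = []
    for trace, d in zip(neighbor_traces, directions):
        d = np.asarray(d, dtype=float)
        norm = np.hypot(*d)
        if norm == 0:
            raise ValueError("zero direction vector")
        try:
            est = burst_delay(center_trace, trace, bin_ms, smooth_sigma,
                              max_lag_ms)
        except ValueError:
            continue
        vecs.append(est.lag_ms * d / norm)
    if not vecs:
        raise ValueError("no active neighbor with a defined delay")
    v = np.mean(vecs, axis=0)
    return PropagationVector(vx=float(v[0]), vy=float(v[1]),
                             cluster_id=cluster_id, burst_id=burst_id)


def propagation_variability(thetas_by_cluster: Sequence[np.ndarray]) -> float:
    """Network propagation variability: mean over clusters of the
    circular standard deviation of the vector angle across bursts (rad)."""
    sds = []
    for thetas in thetas_by_cluster:
        thetas = np.asarray(thetas, dtype=float)
        thetas = thetas[~np.isnan(thetas)]
        if thetas.size < 2:
            continue
        sds.append(stats.circstd(thetas, high=np.pi, low=-np.pi))
    if not sds:
        raise ValueError("no cluster with enough defined angles")
    return float(np.mean(sds))


def distance_profiles(ai: ActivityIntensitySeries,
                      bursts_by_channel: Sequence[Sequence[NetworkBurst]],
                      positions: Optional[np.ndarray] = None,
                      bin_um: float = 250.0,
                      transfer_window_ms: float = 1000.0,
                      delay_smooth_sigma: float = 10.0,
                      max_lag_ms: float = 500.0) -> pd.DataFrame:
    """Correlation, mean |delay| and transfer probability vs distance.

    For every channel pair the long-run Pearson correlation of the AI
    traces, the mean absolute per-burst delay (bursts of the first
    channel of the pair), and the 1 s transfer probability are computed
    and then averaged within ``bin_um``-wide distance bins.
    """
    positions = ai.positions if positions is None else np.asarray(positions)
    if positions is None:
        raise ValueError("channel positions required")
    nch = ai.n_channels
    rows = []
    for i in range(nch):
        for j in range(i + 1, nch):
            dist = float(np.hypot(*(positions[i] - positions[j])))
            try:
                corr = float(stats.pearsonr(ai.ai[i], ai.ai[j]).statistic)
            except Exception:
                corr = np.nan
            delays = []
            for k, b in enumerate(bursts_by_channel[i]):
                b0 = max(0, int((b.start - max_lag_ms) / ai.bin_ms))
                b1 = min(ai.ai.shape[1], int((b.end + max_lag_ms) / ai.bin_ms) + 1)
                try:
                    est = burst_delay(ai.ai[i, b0:b1], ai.ai[j, b0:b1],
                                      ai.bin_ms, delay_smooth_sigma, max_lag_ms,
                                      burst_id=k)
                    delays.append(abs(est.lag_ms))
                except ValueError:
                    continue
            delay = float(np.mean(delays)) if delays else np.nan
            try:
                transfer = transfer_probability_recording(
                    bursts_by_channel[i], bursts_by_channel[j],
                    transfer_window_ms)
            except ValueError:
                transfer = np.nan
            rows.append((dist, corr, delay, transfer))
    df = pd.DataFrame(rows, columns=["distance_um", "corr", "delay_ms",
                                     "transfer_prob"])
    df["distance_bin"] = (df["distance_um"] // bin_um) * bin_um
    prof = df.groupby("distance_bin").agg(
        corr=("corr", "mean"), delay_ms=("delay_ms", "mean"),
        transfer_prob=("transfer_prob", "mean"),
        n_pairs=("corr", "size")).reset_index()
    return prof


def rate_correlation_model(spike_times: np.ndarray, spike_clusters: np.ndarray,
                           bursts_1: Sequence[NetworkBurst],
                           window_ms: float = 500.0,
                           clusters: tuple[int, int] = (1, 2)) -> float:
    """Pearson correlation over bursts of cluster-summed spike counts.

    For each burst initiated in the sending cluster, spikes of the
    sending and receiving clusters within ``window_ms`` of burst onset
    are counted; the correlation of these paired totals quantifies how
    much rate information crosses the bridge.
    """
    if len(bursts_1) < 2:
        raise ValueError("need at least two bursts")
    if len(bursts_1) < 30:
        warnings.warn("fewer than 30 bursts: correlation is low-power",
                      stacklevel=2)
    t = np.asarray(spike_times, dtype=float)
    counts = {c: np.sort(t[np.asarray(spike_clusters) == c]) for c in clusters}
    totals = np.empty((len(bursts_1), 2))
    for i, b in enumerate(bursts_1):
        for col, c in enumerate(clusters):
            ts = counts[c]
            totals[i, col] = np.searchsorted(ts, b.start + window_ms) - \
                np.searchsorted(ts, b.start)
    if totals[:, 0].std() == 0 or totals[:, 1].std() == 0:
        raise ValueError("degenerate burst counts: correlation undefined")
    return float(stats.pearsonr(totals[:, 0], totals[:, 1]).statistic)


def propagation_speed(distance_um: float, delay_ms: float) -> float:
    """Propagation speed in um/ms (e.g. 500 um / 100 ms = 5 um/ms)."""
    if delay_ms <= 0:
        raise ValueError("delay must be > 0")
    return distance_um / delay_ms
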