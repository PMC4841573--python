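"""Network-burst (NB) detection and parameter extraction.

Bursts are detected on an event series defined on the AI grid: for
recordings each 2 ms bin contributes 1 if its AI is non-zero, for model
rasters the per-bin spike count is used directly.  The cascade is

1. count events in moving windows of length ``W`` ms placed every
   ``step`` ms;
2. zero window counts below the threshold ``T`` (suppresses sporadic
   single spikes and brief threshold crossings);
3. convolve the thresholded counts a second time with the same boxcar
   kernel and binarize at 1, which stretches detections so that
   activity near burst edges is included;
4. take runs of positive values as candidate bursts and merge candidates
   whose end-to-start gap is below ``G`` ms;
5. refine each burst on the original grid: start/end are the first/last
   non-zero bins inside the candidate interval and the peak is the
   (earliest) maximum of the Gaussian-smoothed activity.

The network-level variant pools event counts over all channels, uses a
1 s merge gap, drops channels active for less than ``min_active_dur``
ms inside a burst from its participant set, and can discard bursts with
fewer than ``min_active_clusters`` participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signal import ActivityIntensitySeries, gaussian_smooth

__all__ = [
    "BurstDetectionParams", "NetworkBurst",
    "detect_bursts_channel", "detect_bursts_network",
    "recruitment_time", "burst_intensity", "normalized_intensities",
]


@dataclass
class BurstDetectionParams:
    W: float = 100.0              # counting window, ms
    step: float = 10.0            # window stride, ms
    T: float = 10.0               # count threshold
    G: float = 100.0              # merge gap, ms
    peak_sigma: float = 50.0      # peak-smoothing sigma, ms
    min_active_dur: float = 0.0   # participant filter, ms (network variant)
    min_active_clusters: int = 0  # burst filter (network variant)

    def __post_init__(self) -> None:
        if self.W <= 0 or self.step <= 0 or self.T < 0 or self.G < 0:
            raise ValueError("invalid detection parameters")

    @classmethod
    def experiment_channel(cls) -> "BurstDetectionParams":
        return cls(W=100.0, step=10.0, T=10.0, G=100.0, peak_sigma=50.0)

    @classmethod
    def experiment_network(cls) -> "BurstDetectionParams":
        return cls(W=100.0, step=10.0, T=10.0, G=1000.0, peak_sigma=50.0,
                   min_active_dur=10.0, min_active_clusters=5)

    @classmethod
    def model(cls) -> "BurstDetectionParams":
        # spike counts are clean, so shorter windows and a lower threshold
        return cls(W=10.0, step=2.0, T=5.0, G=50.0, peak_sigma=50.0)

    @classmethod
    def preset(cls, name: str) -> "BurstDetectionParams":
        try:
            return {"channel": cls.experiment_channel,
                    "network": cls.experiment_network,
                    "model": cls.model}[name]()
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None


@dataclass
class NetworkBurst:
    """One detected burst; times in ms on the recording clock.

    For network-level bursts, ``channel_ids`` lists participating
    channels with per-channel refined times aligned by position;
    single-channel bursts leave them empty.
    """

    start: float
    end: float
    peak: float
    channel_ids: np.ndarray = field(default_factory=lambda: np.array([], int))
    channel_starts: np.ndarray = field(default_factory=lambda: np.array([]))
    channel_ends: np.ndarray = field(default_factory=lambda: np.array([]))
    channel_peaks: np.ndarray = field(default_factory=lambda: np.array([]))
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start <= self.peak <= self.end:
            raise ValueError("burst must satisfy start <= peak <= end")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def recruitment_time(self) -> float:
        return self.peak - self.start


def _window_counts(events: np.ndarray, bin_ms: float, W: float, step: float):
    """Sliding-window event counts; returns (counts, bins_per_step, w_bins)."""
    w_bins = int(round(W / bin_ms))
    s_bins = int(round(step / bin_ms))
    if w_bins < 1 or s_bins < 1:
        raise ValueError("W and step must cover at least one bin")
    if events.size < w_bins:
        return np.array([]), s_bins, w_bins
    csum = np.concatenate([[0.0], np.cumsum(events)])
    starts = np.arange(0, events.size - w_bins + 1, s_bins)
    return csum[starts + w_bins] - csum[starts], s_bins, w_bins


def _candidate_intervals(events: np.ndarray, bin_ms: float,
                         params: BurstDetectionParams):
    """Steps 1-4 of the cascade; yields (start_bin, end_bin) half-open."""
    counts, s_bins, w_bins = _window_counts(events, bin_ms, params.W, params.step)
    if counts.size == 0:
        return []
    counts = np.where(counts < params.T, 0.0, counts)
    k = max(1, int(round(params.W / params.step)))   # same kernel, in windows
    kernel = np.ones(k)
    spread = np.convolve(counts, kernel, mode="same")
    positive = spread >= 1.0
    # runs of positive windows
    edges = np.diff(np.concatenate([[0], positive.astype(int), [0]]))
    run_starts = np.nonzero(edges == 1)[0]
    run_ends = np.nonzero(edges == -1)[0]
    intervals = []
    for w0, w1 in zip(run_starts, run_ends):
        b0 = w0 * s_bins
        b1 = min((w1 - 1) * s_bins + w_bins, events.size)
        intervals.append((b0, b1))
    # merge gaps shorter than G (end of previous to start of next)
    g_bins = params.G / bin_ms
    merged = []
    for b0, b1 in intervals:
        if merged and b0 - merged[-1][1] < g_bins:
            merged[-1] = (merged[-1][0], b1)
        else:
            merged.append((b0, b1))
    return merged


def _refine(activity: np.ndarray, bin_ms: float, interval,
            params: BurstDetectionParams, floor: float = 0.0):
    """Step 5: start/end from first/last active bin, peak from smoothed AI."""
    b0, b1 = interval
    seg = activity[b0:b1]
    nz = np.nonzero(seg > floor)[0]
    if nz.size == 0:
        return None
    start_bin, end_bin = b0 + nz[0], b0 + nz[-1]
    smooth = gaussian_smooth(activity[start_bin:end_bin + 1],
                             params.peak_sigma, bin_ms)
    peak_bin = start_bin + int(np.argmax(smooth))   # earliest maximum
    return start_bin * bin_ms, end_bin * bin_ms, peak_bin * bin_ms


def detect_bursts_channel(activity: np.ndarray, bin_ms: float = 2.0,
                          params: Optional[BurstDetectionParams] = None,
                          counts: Optional[bool] = None,
                          active_floor: float = 0.0) -> list[NetworkBurst]:
    """Detect bursts on one channel's AI trace (or model spike counts).

    With ``counts=True`` the series is treated as per-bin spike counts
    (model rasters) and the window statistic is the spike count; with
    ``counts=False`` (AI traces) it is the number of active bins, a bin
    being active when its AI exceeds ``active_floor`` (see
    :func:`modgate.signal.activity_floor`; 0 means any non-zero AI).
    The default guesses: an all-integer series is taken to be counts.
    """
    params = params or BurstDetectionParams.experiment_channel()
    activity = np.asarray(activity, dtype=float)
    if activity.size == 0:
        return []
    if counts is None:
        counts = _looks_like_counts(activity)
    events = activity if counts else (activity > active_floor).astype(float)
    floor = 0.0 if counts else active_floor
    bursts = []
    for interval in _candidate_intervals(events, bin_ms, params):
        refined = _refine(activity, bin_ms, interval, params, floor)
        if refined is not None:
            bursts.append(NetworkBurst(start=refined[0], end=refined[1],
                                       peak=refined[2]))
    return bursts


def _looks_like_counts(activity: np.ndarray) -> bool:
    """Model spike-count series are small non-negative integers; AI is not."""
    return bool(np.all(activity == np.round(activity)))


def detect_bursts_network(ai: ActivityIntensitySeries | np.ndarray,
                          bin_ms: Optional[float] = None,
                          params: Optional[BurstDetectionParams] = None,
                          counts: Optional[bool] = None,
                          active_floor: Optional[np.ndarray] = None,
                          ) -> list[NetworkBurst]:
    """Detect bursts pooled over all channels of a recording.

    Event counts are summed over channels before the cascade.  Each
    burst's participant set keeps only channels active for at least
    ``min_active_dur`` ms within the burst window, and bursts with fewer
    than ``min_active_clusters`` participants are discarded.
    ``active_floor`` (per channel) defaults to the AI series' own noise
    floor when one is available.
    """
    params = params or BurstDetectionParams.experiment_network()
    if isinstance(ai, ActivityIntensitySeries):
        traces, bin_ms = ai.ai, ai.bin_ms
        if active_floor is None:
            active_floor = ai.floor()
    else:
        traces = np.atleast_2d(np.asarray(ai, dtype=float))
        if bin_ms is None:
            raise ValueError("bin_ms required for raw arrays")
    if traces.shape[0] < 2:
        raise ValueError("network detection needs at least two channels")
    if active_floor is None:
        active_floor = np.zeros(traces.shape[0])
    active_floor = np.broadcast_to(np.asarray(active_floor, dtype=float),
                                   (traces.shape[0],))
    if counts is None:
        counts = _looks_like_counts(traces)
    if counts:
        events = traces.sum(axis=0)
        active_floor = np.zeros(traces.shape[0])
    else:
        events = (traces > active_floor[:, None]).sum(axis=0).astype(float)
    pooled = traces.sum(axis=0)
    pooled_floor = float(np.sqrt((active_floor ** 2).sum()))
    bursts = []
    for interval in _candidate_intervals(events, bin_ms, params):
        refined = _refine(pooled, bin_ms, interval, params, pooled_floor)
        if refined is None:
            continue
        b0, b1 = interval
        ids, starts, ends, peaks = [], [], [], []
        for ch in range(traces.shape[0]):
            r = _refine(traces[ch], bin_ms, (b0, b1), params, active_floor[ch])
            if r is None:
                continue
            active_ms = (traces[ch, b0:b1] > active_floor[ch]).sum() * bin_ms
            if active_ms < params.min_active_dur:
                continue
            ids.append(ch)
            starts.append(r[0])
            ends.append(r[1])
            peaks.append(r[2])
        if params.min_active_clusters and len(ids) < params.min_active_clusters:
            continue
        bursts.append(NetworkBurst(
            start=refined[0], end=refined[1], peak=refined[2],
            channel_ids=np.array(ids, int), channel_starts=np.array(starts),
            channel_ends=np.array(ends), channel_peaks=np.array(peaks)))
    return bursts


def recruitment_time(burst: NetworkBurst) -> float:
    """Time from burst onset to burst peak (ms)."""
    return burst.recruitment_time


def burst_intensity(burst: NetworkBurst, activity: np.ndarray,
                    bin_ms: float = 2.0) -> float:
    """Sum of AI over the burst window [start, end] (inclusive)."""
    b0 = int(round(burst.start / bin_ms))
    b1 = int(round(burst.end / bin_ms)) + 1
    return float(np.asarray(activity, dtype=float)[b0:b1].sum())


def normalized_intensities(bursts: Sequence[NetworkBurst], activity: np.ndarray,
                           bin_ms: float = 2.0) -> np.ndarray:
    """Burst intensities divided by their standard deviation over bursts."""
    vals = np.array([burst_intensity(b, activity, bin_ms) for b in bursts])
    sd = vals.std()
    if sd == 0:
        raise ZeroDivisionError("intensity standard deviation is zero")
    return vals / sd
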