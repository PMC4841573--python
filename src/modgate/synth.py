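"""Surrogate MEA recordings with known ground truth.

Cultured clustered networks are emulated at the statistical level: a
burst schedule places synchronized population bursts on a grid of
clusters (one electrode per cluster) with prescribed activation
patterns, per-hop propagation delays and hop-failure probabilities, and
the renderer turns the schedule into 10 kHz voltage traces by summing
biphasic extracellular spike waveforms whose instantaneous rate follows
a gamma-shaped burst envelope, on top of i.i.d. Gaussian noise and a low
sporadic firing rate.  Every analysis stage can therefore be checked
against the schedule: delays against hop delays, transfer probabilities
against failure rates, pattern entropy against the pattern table.

The geometry mirrors the patterned cultures: a 6 x 10 grid of circular
islands, 80-200 um diameters, 500 um pitch; the cell count of an island
of area S um^2 follows the calibration N = 0.0079 S - 1.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .signal import VoltageRecording

__all__ = [
    "ClusterGeometry", "ScheduledBurst", "BurstSchedule",
    "cells_from_area", "make_schedule", "render_voltage",
    "preset_geometry", "preset_patterns", "default_spike_template",
]


def cells_from_area(area_um2: float) -> float:
    """Expected cell count of an island of ``area_um2``: max(0.0079 S - 1.9, 0)."""
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return max(0.0079 * area_um2 - 1.9, 0.0)


@dataclass
class ClusterGeometry:
    """Rectangular grid of circular clusters, one electrode per cluster."""

    rows: int = 6
    cols: int = 10
    pitch_um: float = 500.0
    diameters_um: Optional[np.ndarray] = None   # per cluster; default 140 um

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be > 0")
        if self.diameters_um is None:
            self.diameters_um = np.full(self.n_clusters, 140.0)
        else:
            self.diameters_um = np.asarray(self.diameters_um, dtype=float)
            if self.diameters_um.size != self.n_clusters:
                raise ValueError("one diameter per cluster required")

    @property
    def n_clusters(self) -> int:
        return self.rows * self.cols

    def positions(self) -> np.ndarray:
        """(n, 2) positions in um; x rightward along columns, y upward."""
        r, c = np.divmod(np.arange(self.n_clusters), self.cols)
        return np.column_stack([c * self.pitch_um, r * self.pitch_um]).astype(float)

    def areas(self) -> np.ndarray:
        return np.pi * (self.diameters_um / 2.0) ** 2

    def cell_counts(self) -> np.ndarray:
        return np.array([cells_from_area(s) for s in self.areas()])

    def neighbors(self, i: int) -> list[int]:
        """4-neighborhood on the grid."""
        r, c = divmod(i, self.cols)
        out = []
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.rows and 0 <= cc < self.cols:
                out.append(rr * self.cols + cc)
        return out


def preset_geometry(name: str) -> ClusterGeometry:
    presets = {
        "pair": ClusterGeometry(rows=1, cols=2),
        "chain3": ClusterGeometry(rows=1, cols=3),
        "chain5": ClusterGeometry(rows=1, cols=5),
        "grid6x10": ClusterGeometry(rows=6, cols=10),
    }
    try:
        return presets[name]
    except KeyError:
        raise ValueError(f"unknown geometry preset {name!r}") from None


@dataclass
class ScheduledBurst:
    """Ground truth for one scheduled burst."""

    t0: float                     # initiator onset, ms
    initiator: int
    onsets: dict                  # cluster -> onset ms (participants only)
    scale: float = 1.0            # intensity multiplier

    @property
    def participants(self) -> tuple:
        return tuple(sorted(self.onsets))


@dataclass
class BurstSchedule:
    bursts: list
    duration_ms: float
    geometry: ClusterGeometry
    patterns: list                # (initiator, participants) tuples
    pattern_probs: np.ndarray
    hop_delay_mean: float
    hop_delay_sd: float
    failure_prob: float
    seed: Optional[int] = None

    def participation_matrix(self) -> np.ndarray:
        """(n_bursts, n_clusters) binary participation (post failures)."""
        out = np.zeros((len(self.bursts), self.geometry.n_clusters), dtype=int)
        for k, b in enumerate(self.bursts):
            out[k, list(b.onsets)] = 1
        return out

    def onsets_by_cluster(self) -> dict:
        out: dict[int, list] = {c: [] for c in range(self.geometry.n_clusters)}
        for b in self.bursts:
            for c, t in b.onsets.items():
                out[c].append(t)
        return {c: np.array(v) for c, v in out.items()}


def preset_patterns(geometry: ClusterGeometry):
    """A realistic default pattern table: each cluster initiates; bursts
    either stay local or spread to the whole network, with a dominant
    initiator to create directional asymmetry."""
    n = geometry.n_clusters
    all_clusters = tuple(range(n))
    patterns, probs = [], []
    for c in range(n):
        patterns.append((c, (c,)))
        probs.append(0.3 / n)
        patterns.append((c, all_clusters))
        # cluster 0 dominates initiation of global bursts
        probs.append(0.7 * (0.55 if c == 0 else 0.45 / max(n - 1, 1)))
    return patterns, np.array(probs) / np.sum(probs)


def make_schedule(
    geometry: ClusterGeometry,
    patterns: Optional[Sequence] = None,
    pattern_probs: Optional[Sequence[float]] = None,
    hop_delay_mean: float = 30.0,
    hop_delay_sd: float = 5.0,
    failure_prob: float = 0.0,
    rate_hz: float = 0.25,
    duration_ms: float = 120_000.0,
    min_interval_ms: float = 1500.0,
    scale_sd: float = 0.3,
    seed: Optional[int] = None,
) -> BurstSchedule:
    """Draw a burst schedule with known ground truth.

    Burst times form a stationary Poisson process at ``rate_hz`` thinned
    to a ``min_interval_ms`` dead time (bursts in culture do not overlap).
    Each burst draws an activation pattern ``(initiator, participants)``
    from the pattern table; onsets spread from the initiator along grid
    edges restricted to the pattern's participants, each hop adding an
    independent positive delay ~ N(hop_delay_mean, hop_delay_sd) and
    failing with ``failure_prob`` (failed subtrees drop out).  Intensity
    scales are lognormal with spread ``scale_sd``.
    """
    if patterns is None or pattern_probs is None:
        patterns, pattern_probs = preset_patterns(geometry)
    pattern_probs = np.asarray(pattern_probs, dtype=float)
    if pattern_probs.min() < 0 or not np.isclose(pattern_probs.sum(), 1.0):
        raise ValueError("pattern probabilities must be a distribution")
    if len(patterns) != pattern_probs.size:
        raise ValueError("one probability per pattern required")
    rng = np.random.default_rng(seed)
    if rate_hz * duration_ms / 1000.0 < 1:
        import warnings
        warnings.warn("expected burst count below 1", stacklevel=2)

    # Poisson process with dead time
    times, t = [], 0.0
    while True:
        t += rng.exponential(1000.0 / rate_hz)
        if t >= duration_ms:
            break
        if not times or t - times[-1] >= min_interval_ms:
            times.append(t)

    bursts = []
    for t0 in times:
        k = rng.choice(len(patterns), p=pattern_probs)
        initiator, participants = patterns[k]
        participants = set(participants) | {initiator}
        onsets = {initiator: t0}
        frontier = [initiator]
        visited = {initiator}
        while frontier:
            nxt = []
            for c in frontier:
                for nb in geometry.neighbors(c):
                    if nb in visited or nb not in participants:
                        continue
                    visited.add(nb)
                    if rng.random() < failure_prob:
                        continue
                    delay = max(rng.normal(hop_delay_mean, hop_delay_sd), 1.0)
                    onsets[nb] = onsets[c] + delay
                    nxt.append(nb)
            frontier = nxt
        scale = float(rng.lognormal(mean=-scale_sd ** 2 / 2, sigma=scale_sd))
        bursts.append(ScheduledBurst(t0=t0, initiator=initiator,
                                     onsets=onsets, scale=scale))
    return BurstSchedule(bursts=bursts, duration_ms=duration_ms,
                         geometry=geometry, patterns=list(patterns),
                         pattern_probs=pattern_probs,
                         hop_delay_mean=hop_delay_mean,
                         hop_delay_sd=hop_delay_sd,
                         failure_prob=failure_prob, seed=seed)


def default_spike_template(rate_hz: float = 10_000.0,
                           amplitude_uv: float = 60.0) -> np.ndarray:
    """Biphasic 1.2 ms extracellular waveform (negative-leading)."""
    n = int(round(1.2e-3 * rate_hz))
    t = np.linspace(0, 1, n)
    return amplitude_uv * (-np.sin(2 * np.pi * t)) * np.exp(-3 * t)


def _burst_envelope(rng: np.random.Generator, n_spikes: float,
                    recruit_ms: float) -> np.ndarray:
    """Spike offsets (ms from onset) under a gamma-shaped rate envelope
    with mode ``recruit_ms`` (shape 2, so mode = scale)."""
    count = rng.poisson(n_spikes)
    return rng.gamma(2.0, recruit_ms, size=count)


def render_voltage(
    schedule: BurstSchedule,
    spike_template: Optional[np.ndarray] = None,
    noise_sigma: float = 5.0,
    rate_hz: float = 10_000.0,
    spikes_per_burst: float = 120.0,
    recruit_ms: float = 40.0,
    sporadic_rate_hz: float = 0.5,
    seed: Optional[int] = None,
) -> VoltageRecording:
    """Render a schedule into multichannel voltage at ``rate_hz``.

    Each participating channel receives ~``spikes_per_burst`` (scaled by
    the burst's intensity scale) spike waveforms whose offsets from the
    scheduled onset follow a gamma envelope peaking ``recruit_ms`` after
    onset; sporadic out-of-burst spikes occur at ``sporadic_rate_hz``
    per channel; Gaussian noise of ``noise_sigma`` uV is added throughout.
    """
    rng = np.random.default_rng(seed)
    template = (default_spike_template(rate_hz) if spike_template is None
                else np.asarray(spike_template, dtype=float))
    n_ch = schedule.geometry.n_clusters
    n_samp = int(round(schedule.duration_ms / 1000.0 * rate_hz))
    volts = rng.normal(0.0, noise_sigma, size=(n_ch, n_samp))

    for ch in range(n_ch):
        offsets_ms = []
        n_spor = rng.poisson(sporadic_rate_hz * schedule.duration_ms / 1000.0)
        offsets_ms.extend(rng.uniform(0, schedule.duration_ms, size=n_spor))
        for b in schedule.bursts:
            if ch not in b.onsets:
                continue
            offs = _burst_envelope(rng, spikes_per_burst * b.scale,
                                   recruit_ms)
            offsets_ms.extend(b.onsets[ch] + offs)
        samples = np.round(np.asarray(offsets_ms) / 1000.0 * rate_hz).astype(int)
        samples = samples[(samples >= 0) & (samples < n_samp - template.size)]
        for k, v in enumerate(template):
            volts[ch, samples + k] += v

    return VoltageRecording(volts=volts, rate=rate_hz,
                            positions=schedule.geometry.positions())
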