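"""Activity-intensity (AI) representation of multichannel voltage.

The AI of a channel is the mean absolute voltage per time bin (default
2 ms) minus a per-channel noise threshold NT, clipped at zero.  NT is
the mean absolute voltage over 20 ms segments whose (non-excess,
unbiased) kurtosis stays at the Gaussian value: segments with kurtosis
above 3.1 contain super-Gaussian spike activity and are rejected, so NT
estimates the noise floor alone.  AI is a robust proxy for the
instantaneous multi-unit firing rate of the neurons seen by an
electrode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "VoltageRecording", "ActivityIntensitySeries",
    "estimate_noise_threshold", "activity_intensity", "gaussian_smooth",
    "activity_floor", "compute_ai",
]


@dataclass
class VoltageRecording:
    """Multichannel extracellular voltage (uV) at a common sampling rate."""

    volts: np.ndarray             # (n_channels, n_samples)
    rate: float                   # Hz
    positions: Optional[np.ndarray] = None   # (n_channels, 2) um
    cluster_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.volts = np.atleast_2d(np.asarray(self.volts, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.volts.shape[0]:
                raise ValueError("positions/channels mismatch")

    @property
    def n_channels(self) -> int:
        return self.volts.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.volts.shape[1] / self.rate * 1000.0

    def highpass(self, cutoff_hz: float = 200.0, order: int = 2) -> "VoltageRecording":
        """Butterworth high-pass, for synthetic data lacking the hardware filter."""
        sos = butter(order, cutoff_hz, btype="highpass", fs=self.rate, output="sos")
        return VoltageRecording(sosfiltfilt(sos, self.volts, axis=1), self.rate,
                                self.positions, self.cluster_ids)


@dataclass
class ActivityIntensitySeries:
    """Per-channel AI on a uniform grid; always non-negative."""

    ai: np.ndarray                # (n_channels, n_bins)
    bin_ms: float
    nt: np.ndarray                # (n_channels,) noise thresholds
    positions: Optional[np.ndarray] = None
    cluster_ids: Optional[np.ndarray] = None
    samples_per_bin: Optional[int] = None

    def __post_init__(self) -> None:
        self.ai = np.atleast_2d(np.asarray(self.ai, dtype=float))
        if (self.ai < 0).any():
            raise ValueError("AI must be non-negative")

    def floor(self, k: float = 3.0) -> np.ndarray:
        """Per-channel active-bin floor (see :func:`activity_floor`)."""
        if self.samples_per_bin is None:
            return np.zeros(self.n_channels)
        return activity_floor(self.nt, self.samples_per_bin, k)

    @property
    def n_channels(self) -> int:
        return self.ai.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.ai.shape[1]) * self.bin_ms


def estimate_noise_threshold(voltage: np.ndarray, rate: float,
                             kurtosis_bin_ms: float = 20.0,
                             kurtosis_cutoff: float = 3.1) -> float:
    """Kurtosis-gated noise floor of one channel.

    Splits the trace into ``kurtosis_bin_ms`` segments, computes the
    unbiased non-excess kurtosis of each, rejects segments above
    ``kurtosis_cutoff`` and returns the mean absolute voltage of the
    retained samples.  A trailing partial segment is dropped.
    """
    voltage = np.asarray(voltage, dtype=float)
    m = int(round(kurtosis_bin_ms * rate / 1000.0))
    if m < 4:
        raise ValueError("kurtosis bin too short for an unbiased estimate")
    n_bins = voltage.size // m
    if n_bins == 0:
        raise ValueError("trace shorter than one kurtosis bin")
    if n_bins < 100:
        warnings.warn(f"only {n_bins} kurtosis bins; noise threshold unreliable",
                      stacklevel=2)
    segs = voltage[: n_bins * m].reshape(n_bins, m)
    with np.errstate(invalid="ignore"):
        kurt = stats.kurtosis(segs, axis=1, fisher=False, bias=False)
    keep = ~(kurt > kurtosis_cutoff)   # constant segments (NaN kurtosis) kept
    if not keep.any():
        raise ValueError("all kurtosis bins rejected; no noise floor estimable")
    return float(np.abs(segs[keep]).mean())


def activity_intensity(voltage: np.ndarray, nt: float, rate: float,
                       bin_ms: float = 2.0) -> np.ndarray:
    """AI of one channel: per-bin mean |V| minus ``nt``, clipped at zero."""
    voltage = np.asarray(voltage, dtype=float)
    m = int(round(bin_ms * rate / 1000.0))
    if m < 1:
        raise ValueError("bin shorter than one sample")
    n_bins = voltage.size // m
    a = np.abs(voltage[: n_bins * m]).reshape(n_bins, m).mean(axis=1) - nt
    return np.maximum(a, 0.0)


def gaussian_smooth(series: np.ndarray, sigma_ms: float,
                    bin_ms: float = 2.0) -> np.ndarray:
    """Convolve with a unit-area Gaussian (sigma in ms; reflect padding)."""
    if sigma_ms <= 0:
        raise ValueError("sigma must be > 0")
    return gaussian_filter1d(np.asarray(series, dtype=float),
                             sigma_ms / bin_ms, axis=-1, mode="reflect")


def activity_floor(nt: float | np.ndarray, samples_per_bin: int,
                   k: float = 3.0):
    """Detection floor separating active AI bins from noise fluctuations.

    For pure Gaussian noise the AI-bin mean absolute voltage fluctuates
    around NT with standard deviation NT * sqrt((pi/2 - 1) / M); bins are
    only counted as active when AI exceeds ``k`` of these.  With k = 0
    every strictly positive AI bin counts as active.
    """
    return k * np.asarray(nt) * np.sqrt((np.pi / 2.0 - 1.0) / samples_per_bin)


def compute_ai(rec: VoltageRecording, bin_ms: float = 2.0,
               kurtosis_bin_ms: float = 20.0,
               kurtosis_cutoff: float = 3.1) -> ActivityIntensitySeries:
    """Full AI pipeline for a recording: one NT per channel, then AI."""
    nts = np.array([estimate_noise_threshold(v, rec.rate, kurtosis_bin_ms,
                                             kurtosis_cutoff)
                    for v in rec.volts])
    ai = np.vstack([activity_intensity(v, nt, rec.rate, bin_ms)
                    for v, nt in zip(rec.volts, nts)])
    return ActivityIntensitySeries(ai=ai, bin_ms=bin_ms, nt=nts,
                                   positions=rec.positions,
                                   cluster_ids=rec.cluster_ids,
                                   samples_per_bin=int(round(bin_ms * rec.rate
                                                             / 1000.0)))
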