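"""Burst-pattern similarity, activation entropy, bimodality and sizes.

Bursts are compared by the lag-maximized, channel-averaged normalized
cross-covariance of their AI snippets (a time-invariant similarity), and
grouped by average-linkage hierarchical clustering of the similarity
rows.  Cluster-activation patterns (which clusters participated in a
burst) are summarized by their Shannon entropy, normalized by the
entropy of the uniform distribution over the 2^N - 1 non-empty patterns.
The bimodality coefficient BC = (m3^2 + 1) / (m4 + 3(n-1)^2/((n-2)(n-3)))
(sample skewness m3, excess kurtosis m4) quantifies the two-regime
structure of sender/receiver intensity pairs projected on the identity
line; its large-sample value is 5/9 for a uniform distribution and 1/3
for a Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .bursts import NetworkBurst
from .signal import ActivityIntensitySeries, gaussian_smooth

__all__ = [
    "SimilarityMatrix", "PatternSummary", "burst_similarity",
    "pattern_entropy", "entropy_from_probs", "bimodality_coefficient",
    "bimodality_reference", "identity_projection", "burst_size_stats",
]


@dataclass
class SimilarityMatrix:
    """Burst-by-burst similarity with its clustering by-products."""

    R: np.ndarray                 # (n, n), symmetric, unit diagonal
    D: np.ndarray                 # Euclidean distances between rows of R
    linkage: np.ndarray           # scipy hierarchy linkage (average)
    order: np.ndarray             # dendrogram leaf order

    def group_labels(self, n_groups: int) -> np.ndarray:
        """Cut the dendrogram into ``n_groups`` flat groups (labels 1..k)."""
        return hierarchy.fcluster(self.linkage, n_groups, criterion="maxclust")

    def reordered(self) -> np.ndarray:
        return self.R[np.ix_(self.order, self.order)]

    def group_cv(self, labels: np.ndarray) -> dict[int, float]:
        """Coefficient of variation of off-diagonal similarity per group."""
        out = {}
        for g in np.unique(labels):
            idx = np.nonzero(labels == g)[0]
            if idx.size < 2:
                continue
            sub = self.R[np.ix_(idx, idx)]
            vals = sub[~np.eye(idx.size, dtype=bool)]
            out[int(g)] = float(vals.std() / vals.mean()) if vals.mean() else np.nan
        return out


def _snippets(ai: ActivityIntensitySeries, bursts: Sequence[NetworkBurst],
              window_ms: float, sigma_ms: float) -> np.ndarray:
    half = int(round(window_ms / 2 / ai.bin_ms))
    n_bins = ai.ai.shape[1]
    out = np.zeros((len(bursts), ai.n_channels, 2 * half))
    for k, b in enumerate(bursts):
        c = int(round(b.peak / ai.bin_ms))
        lo, hi = c - half, c + half
        src_lo, src_hi = max(lo, 0), min(hi, n_bins)
        out[k, :, src_lo - lo: src_lo - lo + (src_hi - src_lo)] = \
            ai.ai[:, src_lo:src_hi]
    return gaussian_smooth(out, sigma_ms, ai.bin_ms)


def burst_similarity(ai: ActivityIntensitySeries,
                     bursts: Sequence[NetworkBurst],
                     window_ms: float = 1000.0,
                     sigma_ms: float = 10.0) -> SimilarityMatrix:
    """Time-invariant similarity between bursts.

    AI snippets of ``window_ms`` around each burst peak are smoothed
    (sigma 10 ms); for each burst pair the normalized cross-covariance is
    computed per channel, averaged over channels at each lag, and the
    maximum over lags taken as R_ij.  Channels that are flat during a
    snippet contribute zero correlation.  The distance matrix D between
    rows of R feeds an average-linkage dendrogram whose leaf order
    reorders R for display.
    """
    if len(bursts) < 2:
        raise ValueError("need at least two bursts")
    snips = _snippets(ai, bursts, window_ms, sigma_ms)
    nb, nch, L = snips.shape
    centered = snips - snips.mean(axis=2, keepdims=True)
    sd = centered.std(axis=2)
    R = np.eye(nb)
    for i in range(nb):
        for j in range(i + 1, nb):
            acc = np.zeros(2 * L - 1)
            for n in range(nch):
                if sd[i, n] == 0 or sd[j, n] == 0:
                    continue
                acc += np.correlate(centered[j, n], centered[i, n],
                                    mode="full") / (L * sd[i, n] * sd[j, n])
            R[i, j] = R[j, i] = acc.max() / nch
    diff = R[:, None, :] - R[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    link = hierarchy.linkage(squareform(D, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    return SimilarityMatrix(R=R, D=D, linkage=link, order=order)


@dataclass
class PatternSummary:
    """Cluster-activation patterns of a burst population."""

    patterns: np.ndarray          # (n_patterns, n_clusters) binary
    probs: np.ndarray
    entropy: float
    entropy_normalized: float
    n_clusters: int
    log_base: float

    def as_dataframe(self) -> pd.DataFrame:
        bits = ["".join(str(int(b)) for b in p) for p in self.patterns]
        return pd.DataFrame({"pattern": bits, "probability": self.probs})


def entropy_from_probs(probs: Sequence[float], log_base: float = 2.0) -> float:
    """Shannon entropy -sum p log p in the requested base (2 or e)."""
    p = np.asarray(probs, dtype=float)
    p = p[p > 0]
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    return float(-(p * np.log(p)).sum() / np.log(log_base))


def pattern_entropy(participation: Sequence, n_clusters: int,
                    log_base: float = 2.0) -> PatternSummary:
    """Empirical entropy of binary cluster-activation patterns.

    ``participation`` holds per burst either a binary vector of length
    ``n_clusters`` or an iterable of active cluster indices (0-based).
    All-zero patterns must be excluded upstream.  The normalization
    divides by log(2^N - 1), the entropy of a uniform distribution over
    all non-empty patterns.
    """
    if len(participation) == 0:
        raise ValueError("no bursts: entropy undefined")
    rows = []
    for p in participation:
        arr = np.zeros(n_clusters, dtype=int)
        p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p)
        if p.size == n_clusters and np.isin(p, (0, 1)).all() and n_clusters > 1:
            arr[:] = p
        else:
            arr[np.asarray(p, dtype=int)] = 1
        if arr.sum() == 0:
            raise ValueError("all-zero activation pattern encountered")
        rows.append(tuple(arr))
    uniq, counts = np.unique(np.array(rows), axis=0, return_counts=True)
    probs = counts / counts.sum()
    e = entropy_from_probs(probs, log_base)
    e_max = np.log(2 ** n_clusters - 1) / np.log(log_base)
    return PatternSummary(patterns=uniq, probs=probs, entropy=e,
                          entropy_normalized=float(e / e_max),
                          n_clusters=n_clusters, log_base=log_base)


def bimodality_coefficient(samples: Sequence[float]) -> float:
    """Sample bimodality coefficient (sample-size-corrected).

    Values above the uniform-distribution reference (5/9, about 0.555)
    indicate a tendency toward bimodality.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if x.std() == 0:
        raise ValueError("zero variance: bimodality undefined")
    m3 = stats.skew(x, bias=False)
    m4 = stats.kurtosis(x, fisher=True, bias=False)
    return float((m3 ** 2 + 1.0) / (m4 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def bimodality_reference(skewness: float = 0.0,
                         excess_kurtosis: float = -1.2) -> float:
    """Large-sample limit of the bimodality coefficient for a
    distribution with the given moments (defaults: continuous uniform)."""
    return float((skewness ** 2 + 1.0) / (excess_kurtosis + 3.0))


def identity_projection(sender: Sequence[float],
                        receiver: Sequence[float]) -> np.ndarray:
    """Scalar projection (x + y)/sqrt(2) of intensity pairs on the
    identity line; the 1-D sample fed to the bimodality coefficient."""
    s = np.asarray(sender, dtype=float)
    r = np.asarray(receiver, dtype=float)
    if s.shape != r.shape:
        raise ValueError("paired intensities required")
    return (s + r) / np.sqrt(2.0)


def burst_size_stats(bursts: Sequence[NetworkBurst], positions: np.ndarray,
                     intensities: Optional[Sequence[float]] = None,
                     ) -> pd.DataFrame:
    """Per-burst active-electrode counts and bounding areas, normalized.

    The bounding area is the minimal axis-aligned rectangle covering all
    active electrodes (0 for a single electrode).  Both statistics are
    normalized by their maxima over the burst population.  If per-burst
    ``intensities`` are given, the intensity per active cluster, again
    normalized by its maximum, is added.
    """
    positions = np.asarray(positions, dtype=float)
    rows = []
    for b in bursts:
        ids = np.asarray(b.channel_ids, dtype=int)
        n_active = ids.size
        if n_active == 0:
            area = 0.0
        else:
            pos = positions[ids]
            span = pos.max(axis=0) - pos.min(axis=0)
            area = float(span[0] * span[1])
        rows.append((n_active, area))
    df = pd.DataFrame(rows, columns=["n_active", "bounding_area"])
    for col, norm in (("n_active", "n_active_norm"),
                      ("bounding_area", "bounding_area_norm")):
        mx = df[col].max()
        df[norm] = df[col] / mx if mx > 0 else 0.0
    if intensities is not None:
        per = np.asarray(intensities, dtype=float) / np.maximum(df["n_active"], 1)
        mx = per.max()
        df["intensity_per_cluster_norm"] = per / mx if mx > 0 else 0.0
    return df
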