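"""Readers and writers for recordings, rasters, AI series and bursts.

HDF5 is the primary container for voltage recordings (datasets
``volts`` (channels x samples) and ``positions``, attribute ``rate_hz``,
optional JSON ``config`` attribute for provenance); a plain-text CSV
alternative stores one column per channel with the sampling rate in a
``# rate_hz=`` header line.  Spike rasters are two-column CSV
(neuron_id, time_ms).  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .bursts import NetworkBurst
from .signal import ActivityIntensitySeries, VoltageRecording

__all__ = [
    "read_recording", "write_recording", "read_raster", "write_raster",
    "write_ai", "read_ai", "write_bursts", "read_bursts", "atomic_write",
]


class atomic_write:
    """Context manager yielding a temp path renamed to ``path`` on success."""

    def __init__(self, path: str):
        self.path = str(path)

    def __enter__(self) -> str:
        d = os.path.dirname(os.path.abspath(self.path)) or "."
        fd, self.tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        os.close(fd)
        return self.tmp

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            os.replace(self.tmp, self.path)
        elif os.path.exists(self.tmp):
            os.unlink(self.tmp)
        return False


def write_recording(rec: VoltageRecording, path: str,
                    config: Optional[dict] = None) -> None:
    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("volts", data=rec.volts)
            f.attrs["rate_hz"] = float(rec.rate)
            if rec.positions is not None:
                f.create_dataset("positions", data=rec.positions)
            if rec.cluster_ids is not None:
                f.create_dataset("cluster_ids", data=np.asarray(rec.cluster_ids))
            if config is not None:
                f.attrs["config"] = json.dumps(config)


def read_recording(path: str) -> VoltageRecording:
    path = str(path)
    if path.endswith(".csv"):
        return _read_recording_csv(path)
    with h5py.File(path, "r") as f:
        if "volts" not in f:
            raise KeyError("missing dataset 'volts'")
        if "rate_hz" not in f.attrs:
            raise KeyError("missing attribute 'rate_hz'")
        return VoltageRecording(
            volts=f["volts"][()],
            rate=float(f.attrs["rate_hz"]),
            positions=f["positions"][()] if "positions" in f else None,
            cluster_ids=f["cluster_ids"][()] if "cluster_ids" in f else None,
        )


def write_recording_csv(rec: VoltageRecording, path: str) -> None:
    df = pd.DataFrame(rec.volts.T,
                      columns=[f"ch{i}" for i in range(rec.n_channels)])
    with atomic_write(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write(f"# rate_hz={rec.rate}\n")
            df.to_csv(fh, index=False)


def _read_recording_csv(path: str) -> VoltageRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# rate_hz="):
            raise ValueError("CSV recording must start with '# rate_hz=' line")
        rate = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    if df.isna().any().any():
        raise ValueError("channel columns have mismatched lengths")
    return VoltageRecording(volts=df.to_numpy().T, rate=rate)


def write_raster(neuron_ids: np.ndarray, times_ms: np.ndarray, path: str) -> None:
    df = pd.DataFrame({"neuron_id": np.asarray(neuron_ids, dtype=int),
                       "time_ms": np.asarray(times_ms, dtype=float)})
    with atomic_write(path) as tmp:
        df.to_csv(tmp, index=False)


def read_raster(path: str, n_neurons: Optional[int] = None):
    """Load a (neuron_id, time_ms) CSV; sorted by (neuron, time) on read.

    Duplicate rows are preserved; negative times and (when ``n_neurons``
    is given) out-of-range ids are rejected.
    """
    df = pd.read_csv(path)
    for col in ("neuron_id", "time_ms"):
        if col not in df.columns:
            raise ValueError(f"raster CSV missing column {col!r}")
    if (df["time_ms"] < 0).any():
        raise ValueError("negative spike times")
    if n_neurons is not None and len(df):
        ids = df["neuron_id"]
        if (ids < 0).any() or (ids >= n_neurons).any():
            raise ValueError("unknown neuron ids")
    df = df.sort_values(["neuron_id", "time_ms"], kind="stable")
    return (df["neuron_id"].to_numpy(dtype=int),
            df["time_ms"].to_numpy(dtype=float))


def write_ai(ai: ActivityIntensitySeries, path: str,
             config: Optional[dict] = None) -> None:
    with atomic_write(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("ai", data=ai.ai)
            f.create_dataset("nt", data=ai.nt)
            f.attrs["bin_ms"] = float(ai.bin_ms)
            if ai.positions is not None:
                f.create_dataset("positions", data=ai.positions)
            if config is not None:
                f.attrs["config"] = json.dumps(config)


def read_ai(path: str) -> ActivityIntensitySeries:
    with h5py.File(path, "r") as f:
        return ActivityIntensitySeries(
            ai=f["ai"][()], bin_ms=float(f.attrs["bin_ms"]), nt=f["nt"][()],
            positions=f["positions"][()] if "positions" in f else None)


def write_bursts(bursts, path: str) -> None:
    """Bursts as tidy CSV: one row per burst-channel (or per burst when
    no participant data exists)."""
    rows = []
    for k, b in enumerate(bursts):
        if len(b.channel_ids):
            for ch, s, e, p in zip(b.channel_ids, b.channel_starts,
                                   b.channel_ends, b.channel_peaks):
                rows.append((k, int(ch), s, p, e, b.intensity))
        else:
            rows.append((k, -1, b.start, b.peak, b.end, b.intensity))
    df = pd.DataFrame(rows, columns=["burst_id", "channel", "start_ms",
                                     "peak_ms", "end_ms", "intensity"])
    with atomic_write(path) as tmp:
        df.to_csv(tmp, index=False)


def read_bursts(path: str) -> list[NetworkBurst]:
    df = pd.read_csv(path)
    bursts = []
    for bid, grp in df.groupby("burst_id"):
        if (grp["channel"] == -1).all():
            r = grp.iloc[0]
            bursts.append(NetworkBurst(start=r.start_ms, end=r.end_ms,
                                       peak=r.peak_ms))
        else:
            start = grp.start_ms.min()
            end = grp.end_ms.max()
            peak = min(max(grp.peak_ms.min(), start), end)
            bursts.append(NetworkBurst(
                start=start, end=end, peak=peak,
                channel_ids=grp.channel.to_numpy(int),
                channel_starts=grp.start_ms.to_numpy(),
                channel_ends=grp.end_ms.to_numpy(),
                channel_peaks=grp.peak_ms.to_numpy()))
    return bursts
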