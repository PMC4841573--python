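"""End-to-end pipeline: synthesize/simulate -> AI -> detect -> analyze.

Driven by a plain dict (typically loaded from YAML).  Every stage logs
its parameters and seed, and all outputs are written atomically with the
resolved configuration embedded for provenance.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional

import numpy as np
import yaml

from . import io as mio
from .bursts import BurstDetectionParams, detect_bursts_channel, detect_bursts_network
from .connectivity import build_modular_connectivity, sample_strengths
from .dynamics import simulate
from .params import (Condition, InhibitionLevel, NoiseParams, Scheme,
                     SimulationConfig)
from .patterns import pattern_entropy
from .propagation import burst_delay, longterm_asymmetry
from .signal import compute_ai
from .synth import make_schedule, preset_geometry, render_voltage

log = logging.getLogger("modgate")

__all__ = ["load_config", "run_pipeline", "simulate_from_config"]


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def simulate_from_config(cfg: dict, seed: Optional[int] = None):
    """Build, wire and simulate a network from a config mapping.

    Recognized sections (all optional): ``neurons`` (``excitatory`` /
    ``inhibitory`` parameter overrides), ``connectivity`` (n_per_cluster,
    p_intra, lam, scheme, condition), ``synapses`` (inhibition_level),
    ``noise`` (mu, sigma), ``integration`` (dt, duration, warmup, ...).
    """
    from .params import NeuronParams
    neuron_cfg = dict(cfg.get("neurons", {}))
    exc = NeuronParams(**{**vars(NeuronParams.excitatory()),
                          **neuron_cfg.get("excitatory", {})})
    inh = NeuronParams(**{**vars(NeuronParams.inhibitory()),
                          **neuron_cfg.get("inhibitory", {})})
    conn_cfg = dict(cfg.get("connectivity", {}))
    syn_cfg = dict(cfg.get("synapses", {}))
    noise = NoiseParams(**cfg.get("noise", {}))
    integ = dict(cfg.get("integration", {}))
    if seed is not None:
        integ["seed"] = seed
    sim_cfg = SimulationConfig(**integ)
    ss = np.random.SeedSequence(sim_cfg.seed)
    s_conn, s_str = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                     for s in ss.spawn(2)]
    conn = build_modular_connectivity(
        n_per_cluster=int(conn_cfg.get("n_per_cluster", 50)),
        p_intra=tuple(conn_cfg.get("p_intra", (0.25, 0.2))),
        lam=float(conn_cfg.get("lam", 0.0)),
        scheme=Scheme(conn_cfg.get("scheme", "proportional")),
        condition=Condition(conn_cfg.get("condition", "control")),
        seed=conn_cfg.get("seed", s_conn))
    sample_strengths(conn,
                     InhibitionLevel(syn_cfg.get("inhibition_level", "low")),
                     seed=syn_cfg.get("seed", s_str))
    log.info("simulate: lam=%s scheme=%s condition=%s seed=%s",
             conn.lambda_used, conn.scheme.value, conn.condition.value,
             sim_cfg.seed)
    return simulate(conn, noise, sim_cfg, neuron_exc=exc, neuron_inh=inh), conn


def run_pipeline(cfg: dict, outdir: str) -> dict:
    """Execute synth -> AI -> detect -> analyze and write results.

    Returns a dict with file paths and headline numbers.  Any stage
    error aborts with a stage-tagged RuntimeError.
    """
    os.makedirs(outdir, exist_ok=True)
    results: dict = {"outdir": outdir}
    seed = int(cfg.get("seed", 0))

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        name = stage("synth")
        synth_cfg = dict(cfg.get("synth", {}))
        geometry = preset_geometry(synth_cfg.pop("preset", "pair"))
        schedule = make_schedule(geometry, seed=seed, **{
            k: v for k, v in synth_cfg.items()
            if k in ("hop_delay_mean", "hop_delay_sd", "failure_prob",
                     "rate_hz", "duration_ms", "min_interval_ms")})
        rec = render_voltage(schedule, seed=seed + 1,
                             **{k: v for k, v in synth_cfg.items()
                                if k in ("noise_sigma", "spikes_per_burst",
                                         "recruit_ms", "sporadic_rate_hz")})
        rec_path = os.path.join(outdir, "recording.h5")
        mio.write_recording(rec, rec_path, config={"seed": seed, **cfg})
        results["recording"] = rec_path

        name = stage("ai")
        ai = compute_ai(rec)
        ai_path = os.path.join(outdir, "ai.h5")
        mio.write_ai(ai, ai_path, config={"seed": seed, **cfg})
        results["ai"] = ai_path

        name = stage("detect")
        det_cfg = cfg.get("detect", {})
        params = BurstDetectionParams.preset(det_cfg.get("preset", "network"))
        if "min_active_clusters" in det_cfg:
            params.min_active_clusters = int(det_cfg["min_active_clusters"])
        net_bursts = detect_bursts_network(ai, params=params)
        floors = ai.floor()
        ch_bursts = [detect_bursts_channel(
                         ai.ai[c], ai.bin_ms,
                         BurstDetectionParams.experiment_channel(),
                         counts=False, active_floor=floors[c])
                     for c in range(ai.n_channels)]
        bursts_path = os.path.join(outdir, "bursts.csv")
        mio.write_bursts(net_bursts, bursts_path)
        results["bursts"] = bursts_path
        results["n_network_bursts"] = len(net_bursts)

        name = stage("analyze")
        analysis: dict = {"seed": seed}
        delays = []
        for k, b in enumerate(net_bursts):
            b0 = max(0, int((b.start - 500) / ai.bin_ms))
            b1 = min(ai.ai.shape[1], int((b.end + 500) / ai.bin_ms) + 1)
            try:
                est = burst_delay(ai.ai[0, b0:b1], ai.ai[1, b0:b1], ai.bin_ms,
                                  burst_id=k)
                delays.append({"burst_id": k, "lag_ms": est.lag_ms,
                               "peak_corr": est.peak_corr})
            except ValueError:
                continue
        analysis["delays"] = delays
        try:
            analysis["asymmetry_ch0_ch1"] = longterm_asymmetry(
                ai.ai[0], ai.ai[1], ai.bin_ms)
        except ValueError:
            analysis["asymmetry_ch0_ch1"] = None
        participation = [b.channel_ids for b in net_bursts
                         if len(b.channel_ids)]
        if participation:
            summ = pattern_entropy(participation, ai.n_channels)
            analysis["pattern_entropy_bits"] = summ.entropy
            analysis["pattern_entropy_normalized"] = summ.entropy_normalized
        analysis_path = os.path.join(outdir, "analysis.json")
        with mio.atomic_write(analysis_path) as tmp:
            with open(tmp, "w") as fh:
                json.dump(analysis, fh, indent=2)
        results["analysis"] = analysis_path
        results["n_delays"] = len(delays)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return results
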