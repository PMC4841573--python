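"""Morris-Lecar / modified Tsodyks-Markram network dynamics.

Single-step reference operations (:func:`gating_steady_states`,
:func:`neuron_derivatives`, :func:`synapse_step`) are plain NumPy and
define the model; :func:`simulate` integrates the whole network with a
numba-compiled forward-Euler kernel implementing exactly the same
equations.

Membrane equation (conductances mS/cm2, voltages mV, time ms)::

    C_m dV/dt = I_ext - g_Ca M_ss(V) (V - V_Ca) - g_K W (V - V_K) - g_L (V - V_L)
    dW/dt     = phi (W_ss(V) - W) cosh((V - V3) / (2 V4))

with sigmoidal steady states M_ss, W_ss.  Synaptic resources cycle
through recovered (x), active (y) and inactive (z) pools; the recovery
rate carries a tangent saturation, -tan(1.2 z - 1.2), which stalls
recovery at full depletion (z = 1) and prevents tonic run-away firing.
On each presynaptic spike a fraction u of recovered resources activates
instantaneously; for inhibitory synapses u itself facilitates
(u += U0 (1 - u)) and decays with tau_facil.  The synaptic current onto
a neuron is the strength-weighted sum of active fractions of its
afferent synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .connectivity import ConnectivityMatrix
from .params import (InhibitionLevel, NeuronParams, NoiseParams,
                     SimulationConfig, synapse_table)

__all__ = [
    "NeuronState", "SynapseState", "SimulationResult",
    "gating_steady_states", "neuron_derivatives", "synapse_step", "simulate",
]


@dataclass
class NeuronState:
    V: float                      # membrane potential, mV
    W_gate: float                 # K+ channel open fraction
    last_spike_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.W_gate <= 1.0:
            raise ValueError("W_gate must lie in [0, 1]")


@dataclass
class SynapseState:
    """Fractions of synaptic resources (x + y + z = 1) and utilization u."""

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0
    u: float = 0.2

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "u"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def gating_steady_states(V, params: NeuronParams):
    """Steady-state open fractions (M_ss, W_ss) of the Ca2+ and K+ gates."""
    m_ss = 0.5 * (1.0 + np.tanh((V - params.V1) / params.V2))
    w_ss = 0.5 * (1.0 + np.tanh((V - params.V3) / params.V4))
    return m_ss, w_ss


def neuron_derivatives(state: NeuronState, params: NeuronParams, I_ext: float):
    """Right-hand sides (dV/dt, dW/dt) of the Morris-Lecar equations."""
    V, W = state.V, state.W_gate
    m_ss, w_ss = gating_steady_states(V, params)
    dV = (I_ext
          - params.g_Ca * m_ss * (V - params.V_Ca)
          - params.g_K * W * (V - params.V_K)
          - params.g_L * (V - params.V_L)) / params.C_m
    dW = params.phi * (w_ss - W) * np.cosh((V - params.V3) / (2.0 * params.V4))
    return dV, dW


_Z_TOL = 1e-9


def _recovery_rate(z: float, tau_rec: float) -> float:
    return z * (-np.tan(1.2 * z - 1.2)) / tau_rec


def synapse_step(state: SynapseState, params, spike_arrived: bool,
                 dt: float) -> SynapseState:
    """Advance one synapse by one Euler step of length ``dt`` (ms).

    The continuous flow (decay of active resources, tangent-saturated
    recovery of inactive ones, facilitation decay for dynamic u) is
    integrated first; if a presynaptic spike arrived this step the
    discrete jumps are applied afterwards: for dynamic u the
    facilitation jump precedes the resource jump x -> x - u x,
    y -> y + u x.  States are clamped to the unit simplex after the step.
    """
    if not -_Z_TOL <= state.z <= 1.0 + _Z_TOL:
        raise FloatingPointError(f"z = {state.z} outside [0, 1]")
    rec = _recovery_rate(min(max(state.z, 0.0), 1.0), params.tau_rec)
    x = state.x + dt * rec
    y = state.y + dt * (-state.y / params.tau_d)
    z = state.z + dt * (state.y / params.tau_d - rec)
    u = state.u
    if params.u_dynamic:
        u = u + dt * (-u / params.tau_facil)
    if spike_arrived:
        if params.u_dynamic:
            u = u + params.U0 * (1.0 - u)
        jump = u * x
        x -= jump
        y += jump
    x, y, z = (min(max(v, 0.0), 1.0) for v in (x, y, z))
    total = x + y + z
    if total > 0:
        x, y, z = x / total, y / total, z / total
    return SynapseState(x=x, y=y, z=z, u=min(max(u, 0.0), 1.0))


@dataclass
class SimulationResult:
    """Spike raster and bookkeeping from one network simulation."""

    spike_neurons: np.ndarray     # (n_spikes,) int32
    spike_times: np.ndarray       # (n_spikes,) float64, ms in (0, duration)
    cluster_of: np.ndarray
    type_of: np.ndarray
    config: SimulationConfig
    v_traces: Optional[np.ndarray] = None   # (n_samples, N) if recorded
    trace_times: Optional[np.ndarray] = None

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def spikes_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"neuron_id": self.spike_neurons,
                             "time_ms": self.spike_times})

    def cluster_count_series(self, bin_ms: float = 2.0, clusters=(1, 2)):
        """Per-cluster spike counts on a uniform grid.

        Returns ``(bin_edges_start_ms, counts)`` with ``counts`` of shape
        (n_clusters, n_bins).  This series is the model-side analogue of
        the activity-intensity trace and feeds burst detection directly.
        """
        n_bins = int(np.floor(self.config.duration / bin_ms))
        counts = np.zeros((len(clusters), n_bins))
        idx = np.floor(self.spike_times / bin_ms).astype(np.int64)
        ok = idx < n_bins
        for row, c in enumerate(clusters):
            mask = ok & (self.cluster_of[self.spike_neurons] == c)
            np.add.at(counts[row], idx[mask], 1.0)
        t = np.arange(n_bins) * bin_ms
        return t, counts


@njit(cache=True)
def _integrate(V, W, Cm, g_Ca, g_K, g_L, V_Ca, V_K, V_L, V1, V2, V3, V4, phi,
               pre, post, A, u_dyn, U0, tau_rec, tau_d, tau_facil,
               x, y, z, u,
               mu, sigma, dt, n_steps, warm_steps, threshold, refr_steps,
               v_bound, spike_cap, rec_stride, v_rec, seed):
    np.random.seed(seed)
    N = V.size
    M = pre.size
    spike_n = np.empty(spike_cap, dtype=np.int32)
    spike_t = np.empty(spike_cap, dtype=np.float64)
    n_spikes = 0
    last_spike = np.full(N, -10 ** 9, dtype=np.int64)
    spiked = np.zeros(N, dtype=np.bool_)
    I_syn = np.zeros(N)
    rec_rows = v_rec.shape[0]
    rec_i = 0
    status = 0
    for step in range(n_steps):
        for i in range(N):
            I_syn[i] = 0.0
        for s in range(M):
            I_syn[post[s]] += A[s] * y[s]
        for i in range(N):
            spiked[i] = False
            I = mu + sigma * np.random.normal() + I_syn[i]
            v = V[i]
            m_ss = 0.5 * (1.0 + np.tanh((v - V1) / V2))
            w_ss = 0.5 * (1.0 + np.tanh((v - V3) / V4))
            dV = (I - g_Ca * m_ss * (v - V_Ca) - g_K * W[i] * (v - V_K)
                  - g_L * (v - V_L)) / Cm[i]
            dW = phi * (w_ss - W[i]) * np.cosh((v - V3) / (2.0 * V4))
            v_new = v + dt * dV
            W[i] = W[i] + dt * dW
            if W[i] < 0.0:
                W[i] = 0.0
            elif W[i] > 1.0:
                W[i] = 1.0
            if abs(v_new) > v_bound:
                status = 1
                return spike_n[:n_spikes], spike_t[:n_spikes], status, rec_i
            if v_new >= threshold and v < threshold and step - last_spike[i] > refr_steps:
                spiked[i] = True
                last_spike[i] = step
                if step >= warm_steps:
                    if n_spikes >= spike_cap:
                        status = 2
                        return spike_n[:n_spikes], spike_t[:n_spikes], status, rec_i
                    spike_n[n_spikes] = i
                    spike_t[n_spikes] = (step + 1 - warm_steps) * dt
                    n_spikes += 1
            V[i] = v_new
        for s in range(M):
            zs = z[s]
            if zs < 0.0:
                zs = 0.0
            elif zs > 1.0:
                zs = 1.0
            rec = zs * (-np.tan(1.2 * zs - 1.2)) / tau_rec[s]
            xn = x[s] + dt * rec
            yn = y[s] + dt * (-y[s] / tau_d[s])
            zn = z[s] + dt * (y[s] / tau_d[s] - rec)
            un = u[s]
            if u_dyn[s]:
                un = un + dt * (-un / tau_facil[s])
            if spiked[pre[s]]:
                if u_dyn[s]:
                    un = un + U0[s] * (1.0 - un)
                jump = un * xn
                xn -= jump
                yn += jump
            if xn < 0.0:
                xn = 0.0
            elif xn > 1.0:
                xn = 1.0
            if yn < 0.0:
                yn = 0.0
            elif yn > 1.0:
                yn = 1.0
            if zn < 0.0:
                zn = 0.0
            elif zn > 1.0:
                zn = 1.0
            tot = xn + yn + zn
            if tot > 0.0:
                xn /= tot
                yn /= tot
                zn /= tot
            x[s] = xn
            y[s] = yn
            z[s] = zn
            u[s] = un
        if rec_stride > 0 and step >= warm_steps and (step - warm_steps) % rec_stride == 0:
            if rec_i < rec_rows:
                for i in range(N):
                    v_rec[rec_i, i] = V[i]
                rec_i += 1
    return spike_n[:n_spikes], spike_t[:n_spikes], status, rec_i


def simulate(
    conn: ConnectivityMatrix,
    noise: NoiseParams | None = None,
    config: SimulationConfig | None = None,
    neuron_exc: NeuronParams | None = None,
    neuron_inh: NeuronParams | None = None,
) -> SimulationResult:
    """Forward-Euler simulation of the two-cluster network.

    ``conn`` must have sampled strengths.  Initial membrane potentials
    are drawn uniformly in [-50, -30] mV with the K+ gate at its steady
    state; synapses start fully recovered.  Spikes during the warm-up
    interval are discarded and reported times are measured from the end
    of warm-up.  Given identical inputs and seed the raster is
    bit-identical.
    """
    if conn.strengths is None:
        raise ValueError("sample_strengths must run before simulate")
    noise = noise or NoiseParams()
    config = config or SimulationConfig()
    neuron_exc = neuron_exc or NeuronParams.excitatory()
    neuron_inh = neuron_inh or NeuronParams.inhibitory()
    for name in ("g_Ca", "g_K", "g_L", "V_Ca", "V_K", "V_L",
                 "V1", "V2", "V3", "V4", "phi"):
        if getattr(neuron_exc, name) != getattr(neuron_inh, name):
            raise ValueError("E and I neurons may differ only in C_m")

    N = conn.n_neurons
    rng = np.random.default_rng(config.seed)
    V0 = rng.uniform(-50.0, -30.0, size=N)
    _, W0 = gating_steady_states(V0, neuron_exc)
    Cm = np.where(conn.type_of == "I", neuron_inh.C_m, neuron_exc.C_m).astype(float)

    pre, post = conn.edges()
    A = conn.strengths[pre, post]
    table = synapse_table(conn.inhibition_level)
    M = pre.size
    u_dyn = np.zeros(M, dtype=bool)
    U0 = np.empty(M)
    tau_rec = np.empty(M)
    tau_d = np.empty(M)
    tau_facil = np.ones(M)
    for klass, params in table.items():
        mask = (conn.type_of[pre] == klass[0]) & (conn.type_of[post] == klass[1])
        u_dyn[mask] = params.u_dynamic
        U0[mask] = params.U0
        tau_rec[mask] = params.tau_rec
        tau_d[mask] = params.tau_d
        if params.u_dynamic:
            tau_facil[mask] = params.tau_facil
    x = np.ones(M)
    y = np.zeros(M)
    z = np.zeros(M)
    u = U0.copy()  # dynamic u starts at U0; static u is U0 throughout

    n_steps = int(round((config.duration + config.warmup) / config.dt))
    warm_steps = int(round(config.warmup / config.dt))
    refr_steps = int(round(config.refractory / config.dt))
    spike_cap = max(1000, int(N * (config.duration / 1000.0)
                              * config.max_mean_rate_hz))
    if config.record_states:
        n_rec = (n_steps - warm_steps) // config.record_stride + 1
        v_rec = np.empty((n_rec, N))
        rec_stride = config.record_stride
    else:
        v_rec = np.empty((0, N))
        rec_stride = 0

    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    spike_n, spike_t, status, rec_i = _integrate(
        V0, W0, Cm,
        neuron_exc.g_Ca, neuron_exc.g_K, neuron_exc.g_L,
        neuron_exc.V_Ca, neuron_exc.V_K, neuron_exc.V_L,
        neuron_exc.V1, neuron_exc.V2, neuron_exc.V3, neuron_exc.V4,
        neuron_exc.phi,
        pre.astype(np.int64), post.astype(np.int64), A.astype(float),
        u_dyn, U0, tau_rec, tau_d, tau_facil, x, y, z, u,
        noise.mu, noise.sigma, config.dt, n_steps, warm_steps,
        config.spike_threshold, refr_steps, config.v_bound, spike_cap,
        rec_stride, v_rec, kernel_seed,
    )
    if status == 1:
        raise FloatingPointError("membrane potential diverged beyond v_bound")
    if status == 2:
        raise RuntimeError("spike buffer overflow; raise max_mean_rate_hz")

    traces = v_rec[:rec_i] if config.record_states else None
    trace_t = (np.arange(rec_i) * config.record_stride * config.dt
               if config.record_states else None)
    return SimulationResult(
        spike_neurons=spike_n.copy(), spike_times=spike_t.copy(),
        cluster_of=conn.cluster_of, type_of=conn.type_of,
        config=config, v_traces=traces, trace_times=trace_t,
    )
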