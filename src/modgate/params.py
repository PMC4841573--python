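"""Parameter containers for the two-cluster network model.

Default values reproduce the published parameter tables for the
Morris-Lecar neurons and the modified Tsodyks-Markram synapses used
throughout: excitatory and inhibitory neurons share all membrane
parameters except the capacitance (1 vs 2 uF/cm2), and the four synapse
classes (E->E, E->I, I->E, I->I) differ in strength, utilization dynamics
and time constants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict


class InhibitionLevel(str, enum.Enum):
    """The three inhibitory-synapse configurations explored in the model.

    ``LOW``      A = 10 mV (magnitude), tau_d = 6 ms
    ``HIGH_A``   A = 20 mV, tau_d = 6 ms (doubled strength)
    ``HIGH_TAU`` A = 10 mV, tau_d = 12 ms (doubled depression decay)
    """

    LOW = "low"
    HIGH_A = "high_A"
    HIGH_TAU = "high_tau"

    @property
    def a_inhib(self) -> float:
        return 20.0 if self is InhibitionLevel.HIGH_A else 10.0

    @property
    def tau_d_inhib(self) -> float:
        return 12.0 if self is InhibitionLevel.HIGH_TAU else 6.0


class Condition(str, enum.Enum):
    """Inhibition manipulation applied to a connectivity matrix."""

    CONTROL = "control"
    INHIBITION_BLOCK = "inhibition_block"  # all inhibitory strengths zeroed
    LOCAL_INHIBITION = "local_inhibition"  # only inter-cluster inhibitory zeroed


class Scheme(str, enum.Enum):
    """Inter-cluster wiring scheme."""

    PROPORTIONAL = "proportional"
    FEEDFORWARD = "feedforward"
    TARGETING = "targeting"


@dataclass
class NeuronParams:
    """Morris-Lecar membrane parameters (conductances mS/cm2, voltages mV)."""

    g_Ca: float = 1.0
    g_K: float = 2.0
    g_L: float = 0.5
    V_Ca: float = 100.0
    V_K: float = -70.0
    V_L: float = -50.0
    V1: float = -1.0
    V2: float = 15.0
    V3: float = 10.0
    V4: float = 14.5
    C_m: float = 1.0
    phi: float = 1.0 / 3.0
    is_inhibitory: bool = False

    def __post_init__(self) -> None:
        for name in ("g_Ca", "g_K", "g_L", "C_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def excitatory(cls) -> "NeuronParams":
        return cls(C_m=1.0, is_inhibitory=False)

    @classmethod
    def inhibitory(cls) -> "NeuronParams":
        return cls(C_m=2.0, is_inhibitory=True)


@dataclass
class SynapseParams:
    """Modified Tsodyks-Markram synapse parameters.

    ``A_nom`` is the nominal strength in mV; negative for inhibitory
    synapses.  ``u_dynamic`` switches on the facilitating utilization
    variable used by inhibitory synapses (du/dt = -u/tau_facil with jumps
    u += U0(1-u) on each presynaptic spike); excitatory synapses use the
    constant u = U0.
    """

    A_nom: float
    U0: float
    u_dynamic: bool
    tau_rec: float
    tau_d: float
    tau_facil: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_rec <= 0 or self.tau_d <= 0:
            raise ValueError("tau_rec and tau_d must be > 0")
        if self.u_dynamic and self.tau_facil <= 0:
            raise ValueError("tau_facil must be > 0 for dynamic-u synapses")

    @classmethod
    def e_to_e(cls) -> "SynapseParams":
        return cls(A_nom=6.25, U0=0.2, u_dynamic=False, tau_rec=100.0, tau_d=6.0)

    @classmethod
    def e_to_i(cls) -> "SynapseParams":
        return cls(A_nom=10.0, U0=0.2, u_dynamic=False, tau_rec=100.0, tau_d=6.0)

    @classmethod
    def inhibitory(cls, level: InhibitionLevel = InhibitionLevel.LOW) -> "SynapseParams":
        """I->E and I->I synapses share one parameter set per inhibition level."""
        level = InhibitionLevel(level)
        return cls(
            A_nom=-level.a_inhib,
            U0=0.06,
            u_dynamic=True,
            tau_rec=800.0,
            tau_d=level.tau_d_inhib,
            tau_facil=1000.0,
        )


def synapse_table(level: InhibitionLevel = InhibitionLevel.LOW) -> dict:
    """Parameter sets for the four synapse classes, keyed by (pre, post) type."""
    return {
        ("E", "E"): SynapseParams.e_to_e(),
        ("E", "I"): SynapseParams.e_to_i(),
        ("I", "E"): SynapseParams.inhibitory(level),
        ("I", "I"): SynapseParams.inhibitory(level),
    }


@dataclass
class NoiseParams:
    """Gaussian per-step per-neuron noise current (uA/cm2)."""

    mu: float = 7.55
    sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SimulationConfig:
    """Euler-integration settings.

    ``spike_threshold`` defines an action potential as an upward crossing
    of V (default 10 mV) with a ``refractory`` lockout; the warm-up
    interval is simulated but its spikes are discarded so that burst
    statistics do not depend on the synchronized initial condition.
    """

    dt: float = 0.1           # ms
    duration: float = 300_000.0  # ms
    spike_threshold: float = 10.0  # mV
    refractory: float = 2.0   # ms
    warmup: float = 5_000.0   # ms, discarded
    v_bound: float = 200.0    # |V| divergence guard, mV
    max_mean_rate_hz: float = 200.0  # spike-buffer sizing guard
    record_states: bool = False
    record_stride: int = 100  # state-trace sampling stride in steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")

    def to_dict(self) -> dict:
        return asdict(self)
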