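import numpy as np
import pytest

from modgate import (compute_ai, make_schedule, preset_geometry,
                     render_voltage)


@pytest.fixture(scope="session")
def pair_data():
    """A two-cluster surrogate recording with ground truth.

    Cluster 0 initiates bursts that propagate to cluster 1 with a 30 ms
    hop delay (80% of bursts); the rest stay local to cluster 1.
    """
    geom = preset_geometry("pair")
    patterns = [(0, (0, 1)), (1, (1,))]
    schedule = make_schedule(geom, patterns, [0.8, 0.2], hop_delay_mean=30.0,
                             duration_ms=120_000.0, seed=11)
    rec = render_voltage(schedule, seed=12)
    ai = compute_ai(rec)
    return schedule, rec, ai


@pytest.fixture(scope="session")
def model_sweep():
    """Seed-averaged modularity sweep of the two-cluster model.

    Low-inhibition proportional scheme, 60 s simulated per run, two
    network realizations per modularity value.
    """
    from modgate.sweep import sweep_modularity
    return sweep_modularity([0.0, 0.02, 0.05, 0.1, 0.15], n_seeds=2,
                            duration_ms=60_000.0, base_seed=1)
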