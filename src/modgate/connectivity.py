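"""Modular two-cluster connectivity generation.

Networks consist of two clusters of ``n_per_cluster`` neurons.  Within
cluster 1 (respectively 2) directed connections exist independently with
probability 0.25 (0.2); inter-cluster connections start at zero.  Each
intra-cluster edge is then independently *replaced* by an inter-cluster
edge with probability ``lam`` (the modularity), so the expected
inter/intra edge-count ratio is lam/(1-lam).  One in five neurons per
cluster is inhibitory.

Three wiring schemes control which postsynaptic types inter-cluster
edges hit:

``proportional``
    rewired edges pick a uniformly random target in the other cluster,
    so the type mix of inter-cluster edges matches the intra-cluster mix.
``feedforward``
    after proportional rewiring, the realized number of inter-cluster
    E->I edges is adjusted (edges added or removed, never both) to equal
    the realized number of inter-cluster E->E edges, per direction.
``targeting``
    after proportional rewiring, every inhibitory neuron that receives
    at least one excitatory input from the other cluster has its outputs
    onto same-cluster inhibitory neurons redirected to randomly chosen
    excitatory neurons of its own cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import Condition, InhibitionLevel, Scheme, synapse_table

__all__ = ["ConnectivityMatrix", "build_modular_connectivity", "sample_strengths"]


@dataclass
class ConnectivityMatrix:
    """Directed binary synapse matrix with neuron metadata.

    ``a[i, j] == 1`` means a synapse from presynaptic neuron ``i`` to
    postsynaptic neuron ``j``.  ``strengths`` (mV, negative for
    inhibitory presynaptic neurons) is dense with zeros where no synapse
    exists; it is ``None`` until :func:`sample_strengths` runs.
    """

    a: np.ndarray                 # (N, N) uint8
    cluster_of: np.ndarray        # (N,) int, values {1, 2}
    type_of: np.ndarray           # (N,) '<U1', values {'E', 'I'}
    lambda_used: float
    scheme: Scheme
    condition: Condition = Condition.CONTROL
    seed: Optional[int] = None
    strengths: Optional[np.ndarray] = None
    inhibition_level: InhibitionLevel = InhibitionLevel.LOW

    @property
    def n_neurons(self) -> int:
        return self.a.shape[0]

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(pre, post) index arrays of existing synapses, row-major order."""
        return np.nonzero(self.a)

    def is_inter(self) -> np.ndarray:
        """Boolean matrix marking inter-cluster ordered pairs."""
        return self.cluster_of[:, None] != self.cluster_of[None, :]

    def n_inter_edges(self) -> int:
        return int((self.a * self.is_inter()).sum())

    def n_intra_edges(self) -> int:
        return int(self.a.sum()) - self.n_inter_edges()

    def validate(self) -> None:
        a = self.a
        if np.any(np.diag(a)):
            raise ValueError("self-connections present")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if self.strengths is not None:
            inhib_pre = self.type_of == "I"
            if np.any(self.strengths[inhib_pre] > 0):
                raise ValueError("inhibitory presynaptic strengths must be <= 0")


def _rewire_proportional(a: np.ndarray, cluster_of: np.ndarray, lam: float,
                         rng: np.random.Generator) -> None:
    """Replace each intra edge with prob lam by an inter edge (in place).

    The presynaptic neuron is kept; the new postsynaptic target is drawn
    uniformly among other-cluster neurons not already targeted by that
    presynaptic neuron, so edge count is conserved exactly.  In the
    (densities-permitting, never observed) case that a presynaptic
    neuron already targets the whole other cluster, its edge is kept.
    """
    pre_idx, post_idx = np.nonzero(a)
    intra = cluster_of[pre_idx] == cluster_of[post_idx]
    pre_idx, post_idx = pre_idx[intra], post_idx[intra]
    rewire = rng.random(pre_idx.size) < lam
    for i, j in zip(pre_idx[rewire], post_idx[rewire]):
        other = np.nonzero((cluster_of != cluster_of[i]) & (a[i] == 0))[0]
        if other.size == 0:
            continue
        target = rng.choice(other)
        a[i, j] = 0
        a[i, target] = 1


def _match_feedforward(a: np.ndarray, cluster_of: np.ndarray, type_of: np.ndarray,
                       rng: np.random.Generator) -> None:
    """Force realized inter E->I count to equal inter E->E count, per direction."""
    for v, w in ((1, 2), (2, 1)):
        pre_e = (cluster_of == v) & (type_of == "E")
        post_e = (cluster_of == w) & (type_of == "E")
        post_i = (cluster_of == w) & (type_of == "I")
        n_ee = int(a[np.ix_(pre_e, post_e)].sum())
        sub = np.ix_(pre_e, post_i)
        n_ei = int(a[sub].sum())
        pre_ids = np.nonzero(pre_e)[0]
        post_ids = np.nonzero(post_i)[0]
        if n_ei < n_ee:
            absent = np.nonzero(a[sub] == 0)
            k = n_ee - n_ei
            if k > absent[0].size:
                raise ValueError("feedforward scheme cannot add enough E->I edges")
            pick = rng.choice(absent[0].size, size=k, replace=False)
            a[pre_ids[absent[0][pick]], post_ids[absent[1][pick]]] = 1
        elif n_ei > n_ee:
            present = np.nonzero(a[sub] == 1)
            pick = rng.choice(present[0].size, size=n_ei - n_ee, replace=False)
            a[pre_ids[present[0][pick]], post_ids[present[1][pick]]] = 0


def _retarget_inhibitory(a: np.ndarray, cluster_of: np.ndarray, type_of: np.ndarray,
                         rng: np.random.Generator) -> None:
    """Inhibitory neurons with inter-cluster excitatory input lose their
    I->I outputs: each such synapse is redirected to a random excitatory
    neuron of the same cluster (avoiding duplicates)."""
    n = a.shape[0]
    for i in range(n):
        if type_of[i] != "I":
            continue
        inter_e_in = (type_of == "E") & (cluster_of != cluster_of[i]) & (a[:, i] == 1)
        if not inter_e_in.any():
            continue
        same = cluster_of == cluster_of[i]
        ii_targets = np.nonzero(same & (type_of == "I") & (a[i] == 1))[0]
        for j in ii_targets:
            free_e = np.nonzero(same & (type_of == "E") & (a[i] == 0))[0]
            a[i, j] = 0
            if free_e.size:
                a[i, rng.choice(free_e)] = 1


def build_modular_connectivity(
    n_per_cluster: int = 50,
    p_intra: tuple[float, float] = (0.25, 0.2),
    lam: float = 0.0,
    scheme: Scheme | str = Scheme.PROPORTIONAL,
    condition: Condition | str = Condition.CONTROL,
    seed: Optional[int] = None,
) -> ConnectivityMatrix:
    """Generate a two-cluster modular connectivity matrix.

    Parameters
    ----------
    n_per_cluster : neurons per cluster (floor(n/5) of them inhibitory).
    p_intra : intra-cluster connection probabilities (cluster 1, cluster 2).
    lam : modularity, the probability of replacing an intra-cluster edge
        with an inter-cluster one; must lie in [0, 0.5].
    scheme, condition, seed : see module docstring / :class:`ConnectivityMatrix`.
    """
    if not 0.0 <= lam <= 0.5:
        raise ValueError(f"lam must be in [0, 0.5], got {lam}")
    if n_per_cluster < 5:
        raise ValueError("n_per_cluster must be >= 5 (one in five inhibitory)")
    scheme = Scheme(scheme)
    condition = Condition(condition)
    rng = np.random.default_rng(seed)

    n = n_per_cluster
    N = 2 * n
    cluster_of = np.repeat([1, 2], n)
    type_of = np.full(N, "E", dtype="<U1")
    n_inhib = n // 5
    for c in (0, 1):
        picks = rng.choice(n, size=n_inhib, replace=False) + c * n
        type_of[picks] = "I"

    a = np.zeros((N, N), dtype=np.uint8)
    for c, p in ((1, p_intra[0]), (2, p_intra[1])):
        idx = np.nonzero(cluster_of == c)[0]
        block = (rng.random((n, n)) < p).astype(np.uint8)
        np.fill_diagonal(block, 0)
        a[np.ix_(idx, idx)] = block

    if lam > 0:
        _rewire_proportional(a, cluster_of, lam, rng)
        if scheme is Scheme.FEEDFORWARD:
            _match_feedforward(a, cluster_of, type_of, rng)
        elif scheme is Scheme.TARGETING:
            _retarget_inhibitory(a, cluster_of, type_of, rng)

    conn = ConnectivityMatrix(
        a=a, cluster_of=cluster_of, type_of=type_of, lambda_used=lam,
        scheme=scheme, condition=condition, seed=seed,
    )
    conn.validate()
    return conn


def _truncated_gaussian(a_nom: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw N(a_nom, a_nom/2) magnitudes, redrawing until within
    [0.8 a_nom, 1.2 a_nom].  ``a_nom`` is a positive magnitude here."""
    out = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        draws = rng.normal(a_nom, a_nom / 2.0, size=pending.size)
        ok = (draws >= 0.8 * a_nom) & (draws <= 1.2 * a_nom)
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
    return out


def sample_strengths(
    conn: ConnectivityMatrix,
    inhibition_level: InhibitionLevel | str = InhibitionLevel.LOW,
    seed: Optional[int] = None,
) -> ConnectivityMatrix:
    """Draw per-synapse strengths and apply the condition's inhibition mask.

    Each synapse strength magnitude is drawn from a Gaussian with mean
    A_nom and SD A_nom/2, redrawn until it falls within 20% of A_nom;
    inhibitory presynaptic strengths get a negative sign.  Under
    ``inhibition_block`` every inhibitory strength is set to 0; under
    ``local_inhibition`` only inter-cluster inhibitory strengths are.
    """
    if conn.strengths is not None:
        raise ValueError("strengths already sampled")
    level = InhibitionLevel(inhibition_level)
    table = synapse_table(level)
    rng = np.random.default_rng(seed)
    N = conn.n_neurons
    strengths = np.zeros((N, N))
    pre_idx, post_idx = conn.edges()
    for klass, params in table.items():
        mask = (conn.type_of[pre_idx] == klass[0]) & (conn.type_of[post_idx] == klass[1])
        k = int(mask.sum())
        if k == 0 or params.A_nom == 0:
            continue
        mags = _truncated_gaussian(abs(params.A_nom), k, rng)
        sign = -1.0 if params.A_nom < 0 else 1.0
        strengths[pre_idx[mask], post_idx[mask]] = sign * mags

    inhib_pre = conn.type_of == "I"
    if conn.condition is Condition.INHIBITION_BLOCK:
        strengths[inhib_pre, :] = 0.0
    elif conn.condition is Condition.LOCAL_INHIBITION:
        inter = conn.is_inter()
        strengths[inhib_pre[:, None] & inter] = 0.0

    conn.strengths = strengths
    conn.inhibition_level = level
    conn.validate()
    return conn
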