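"""Spiking-network core: neuron dynamics, topology construction, simulation step.

The neuron model is the two-variable quadratic integrate-and-fire (Izhikevich)
model,

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I,      du/dt = a (b v - u),

with a spike emitted (and v reset to c, u incremented by d) when v crosses the
peak ``v_peak``.  Regular-spiking parameters are used for excitatory neurons
and fast-spiking parameters for inhibitory neurons.  Synapses deliver their
efficacy as an instantaneous current increment one conduction delay after the
presynaptic spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from . import _kernels

__all__ = [
    "Role",
    "NeuronParams",
    "Topology",
    "NetworkState",
    "SpikeRecord",
    "build_minimal_circuit",
    "build_random_network",
    "init_state",
    "step",
    "sync_weights",
    "background_noise",
    "GaussianNoise",
    "DEFAULT_NOISE_SIGMA",
    "DEFAULT_W_MAX",
]

#: Default weight bound (efficacy units = instantaneous current increment).
DEFAULT_W_MAX = 10.0

#: Gaussian per-step current s.d. calibrated so an isolated regular-spiking
#: neuron fires at ~2 Hz baseline (see docs/methods.md).
DEFAULT_NOISE_SIGMA = 3.9


class Role(IntEnum):
    """Functional role of a neuron in the embodied network."""

    SENSORY = 0   # sensory-input: receives external stimulation
    MOTOR = 1     # motor-output: its spikes drive the environment
    HIDDEN = 2
    INHIBITORY = 3


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich membrane coefficients plus the spike cutoff.

    ``a`` recovery timescale (1/ms), ``b`` recovery sensitivity, ``c`` reset
    potential (mV), ``d`` post-spike recovery increment, ``v_peak`` spike
    threshold/cutoff (mV).
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0
    kind: str = "excitatory"

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d, self.v_peak)
        if not all(np.isfinite(vals)):
            raise ValueError("neuron coefficients must be finite")
        if self.v_peak <= self.c:
            raise ValueError("spike threshold must exceed the reset potential")
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown neuron kind {self.kind!r}")

    @classmethod
    def regular_spiking(cls) -> "NeuronParams":
        return cls(0.02, 0.2, -65.0, 8.0, 30.0, "excitatory")

    @classmethod
    def fast_spiking(cls) -> "NeuronParams":
        return cls(0.1, 0.2, -65.0, 2.0, 30.0, "inhibitory")

    @property
    def v_rest(self) -> float:
        """Stable fixed point of the (v, u) system (mV)."""
        disc = (5.0 - self.b) ** 2 - 4 * 0.04 * 140.0
        if disc < 0:
            return self.c
        return (-(5.0 - self.b) - np.sqrt(disc)) / (2 * 0.04)


@dataclass
class Topology:
    """Directed weighted network with conduction delays and a plastic mask.

    ``weights[i, j]`` is the efficacy of the synapse from neuron ``i`` to
    neuron ``j`` (signed: inhibitory presynaptic neurons have non-positive
    rows).  ``connected`` marks which synapses exist (a plastic weight may
    decay to exactly 0 without the synapse disappearing).
    """

    n: int
    roles: np.ndarray            # int8, Role values
    weights: np.ndarray          # float64 (n, n)
    delays: np.ndarray           # float64 (n, n), ms
    connected: np.ndarray        # bool (n, n)
    plastic: np.ndarray          # bool (n, n)
    w_max: float = DEFAULT_W_MAX
    params: dict = field(default_factory=dict)   # Role-independent overrides

    def __post_init__(self):
        self.roles = np.asarray(self.roles, dtype=np.int8)
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def input_ids(self) -> np.ndarray:
        return np.flatnonzero(self.roles == Role.SENSORY)

    @property
    def output_ids(self) -> np.ndarray:
        return np.flatnonzero(self.roles == Role.MOTOR)

    @property
    def inhibitory_mask(self) -> np.ndarray:
        return self.roles == Role.INHIBITORY

    def neuron_params(self) -> list[NeuronParams]:
        rs = self.params.get("excitatory", NeuronParams.regular_spiking())
        fs = self.params.get("inhibitory", NeuronParams.fast_spiking())
        return [fs if self.roles[i] == Role.INHIBITORY else rs
                for i in range(self.n)]

    def validate(self) -> None:
        if self.weights.shape != (self.n, self.n):
            raise ValueError("weight matrix shape mismatch")
        if np.any(np.diag(self.connected)):
            raise ValueError("self-connections are not allowed")
        if np.any(np.abs(self.weights) > self.w_max + 1e-12):
            raise ValueError("|w| exceeds w_max")
        inh = self.inhibitory_mask
        if np.any(self.weights[inh, :] > 1e-12):
            raise ValueError("inhibitory presynaptic weights must be <= 0")
        if np.any(self.weights[~inh, :] < -1e-12):
            raise ValueError("excitatory presynaptic weights must be >= 0")
        if np.any(self.delays[self.connected] <= 0):
            raise ValueError("delays must be >= the simulation step")
        if np.any(self.weights[~self.connected] != 0):
            raise ValueError("weights on absent synapses must be 0")

    # -- plain-text serialization ---------------------------------------
    def save_edge_list(self, path) -> None:
        """Edge list: header line, then `src dst weight delay_ms plastic`."""
        with open(path, "w") as fh:
            roles = ",".join(str(int(r)) for r in self.roles)
            fh.write(f"# lsasim-topology n={self.n} w_max={self.w_max!r} "
                     f"roles={roles}\n")
            src, dst = np.nonzero(self.connected)
            for i, j in zip(src, dst):
                fh.write(f"{i} {j} {float(self.weights[i, j])!r} "
                         f"{float(self.delays[i, j])!r} "
                         f"{int(self.plastic[i, j])}\n")

    @classmethod
    def load_edge_list(cls, path) -> "Topology":
        with open(path) as fh:
            header = fh.readline().strip()
            fields = dict(tok.split("=", 1) for tok in header.split()[2:])
            n = int(fields["n"])
            w_max = float(fields["w_max"])
            roles = np.array([int(r) for r in fields["roles"].split(",")],
                             dtype=np.int8)
            w = np.zeros((n, n))
            d = np.zeros((n, n))
            conn = np.zeros((n, n), dtype=bool)
            plas = np.zeros((n, n), dtype=bool)
            for line in fh:
                if not line.strip():
                    continue
                i, j, wij, dij, p = line.split()
                i, j = int(i), int(j)
                w[i, j] = float(wij)
                d[i, j] = float(dij)
                conn[i, j] = True
                plas[i, j] = bool(int(p))
        return cls(n=n, roles=roles, weights=w, delays=d,
                   connected=conn, plastic=plas, w_max=w_max)


class SpikeRecord:
    """Append-only time-sorted record of (time ms, neuron id)."""

    def __init__(self):
        self._t_chunks: list[np.ndarray] = []
        self._id_chunks: list[np.ndarray] = []
        self._last_t = -np.inf

    def append(self, t: float, ids: np.ndarray) -> None:
        if len(ids) == 0:
            return
        if t < self._last_t:
            raise ValueError("spike times must be nondecreasing")
        self._last_t = t
        self._t_chunks.append(np.full(len(ids), t))
        self._id_chunks.append(np.asarray(ids, dtype=np.int32).copy())

    @property
    def times(self) -> np.ndarray:
        return (np.concatenate(self._t_chunks) if self._t_chunks
                else np.empty(0))

    @property
    def ids(self) -> np.ndarray:
        return (np.concatenate(self._id_chunks) if self._id_chunks
                else np.empty(0, dtype=np.int32))

    def __len__(self) -> int:
        return sum(len(c) for c in self._id_chunks)

    def train(self, neuron_id: int) -> np.ndarray:
        """Spike times of one neuron."""
        t, i = self.times, self.ids
        return t[i == neuron_id]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.times, "neuron_id": self.ids})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_minimal_circuit(kind: str, initial_weight: float = 3.0,
                          w_max: float = DEFAULT_W_MAX, delay_ms: float = 1.0,
                          inhibitory_weight: float = 1.0) -> Topology:
    """Minimal stimulation-avoidance / prediction circuits.

    ``lsa2``        input -> output.
    ``lsa3``        input -> {output, hidden}, equal weights; the hidden
                    neuron has no outgoing synapses (it fires only from
                    background noise and cannot affect anything).
    ``predictive3`` anticipatory input -> inhibitory -> target input chain;
                    the inhibitory neuron's outgoing weight is negative
                    (magnitude ``inhibitory_weight``).
    """
    if initial_weight > w_max:
        raise ValueError("initial weight exceeds w_max")
    if kind == "lsa2":
        n = 2
        roles = np.array([Role.SENSORY, Role.MOTOR], dtype=np.int8)
        edges = [(0, 1, initial_weight, True)]
    elif kind == "lsa3":
        n = 3
        roles = np.array([Role.SENSORY, Role.MOTOR, Role.HIDDEN],
                         dtype=np.int8)
        edges = [(0, 1, initial_weight, True), (0, 2, initial_weight, True)]
    elif kind == "predictive3":
        if inhibitory_weight > w_max:
            raise ValueError("initial weight exceeds w_max")
        n = 3
        roles = np.array([Role.SENSORY, Role.INHIBITORY, Role.SENSORY],
                         dtype=np.int8)
        edges = [(0, 1, initial_weight, True),
                 (1, 2, -inhibitory_weight, True)]
    else:
        raise ValueError(f"unknown circuit kind {kind!r}")

    w = np.zeros((n, n))
    d = np.zeros((n, n))
    conn = np.zeros((n, n), dtype=bool)
    plas = np.zeros((n, n), dtype=bool)
    for i, j, wij, p in edges:
        w[i, j] = wij
        d[i, j] = delay_ms
        conn[i, j] = True
        plas[i, j] = p
    return Topology(n=n, roles=roles, weights=w, delays=d, connected=conn,
                    plastic=plas, w_max=w_max)


def build_feedforward(n_input: int = 4, n_output: int = 4,
                      initial_weight: float = 2.0,
                      w_max: float = DEFAULT_W_MAX,
                      delay_ms: float = 1.0) -> Topology:
    """All-to-all plastic sensory -> motor layer (wall-task controller)."""
    if initial_weight > w_max:
        raise ValueError("initial weight exceeds w_max")
    n = n_input + n_output
    roles = np.array([Role.SENSORY] * n_input + [Role.MOTOR] * n_output,
                     dtype=np.int8)
    conn = np.zeros((n, n), dtype=bool)
    conn[:n_input, n_input:] = True
    w = np.where(conn, initial_weight, 0.0)
    d = np.where(conn, delay_ms, 0.0)
    return Topology(n=n, roles=roles, weights=w, delays=d, connected=conn,
                    plastic=conn.copy(), w_max=w_max)


def build_random_network(n: int, p_connect: float, frac_inhibitory: float = 0.2,
                         n_input: int = 10, n_output: int = 10, seed: int = 0,
                         w_max: float = DEFAULT_W_MAX,
                         exc_weight_range: tuple[float, float] = (0.0, 5.0),
                         inh_weight: float = 5.0,
                         delay_range_ms: tuple[float, float] = (1.0, 10.0),
                         plastic: str = "excitatory") -> Topology:
    """Directed Erdős–Rényi network with disjoint sensory/motor sets.

    Inhibitory neurons are drawn uniformly among non-input neurons.  Delays
    are uniform over ``delay_range_ms``; excitatory weights uniform over
    ``exc_weight_range``, inhibitory weights fixed at ``-inh_weight``.
    ``plastic`` is one of 'excitatory' (all synapses from excitatory
    neurons), 'all', or 'none'.
    """
    if n_input + n_output > n:
        raise ValueError("n_input + n_output exceeds network size")
    if not 0.0 <= p_connect <= 1.0:
        raise ValueError("p_connect must be a probability")
    rng = np.random.default_rng(seed)

    roles = np.full(n, Role.HIDDEN, dtype=np.int8)
    perm = rng.permutation(n)
    inputs = perm[:n_input]
    outputs = perm[n_input:n_input + n_output]
    roles[inputs] = Role.SENSORY
    roles[outputs] = Role.MOTOR
    non_input = perm[n_input:]
    n_inh = int(round(frac_inhibitory * n))
    if n_inh > len(non_input):
        raise ValueError("too many inhibitory neurons requested")
    inh = rng.choice(non_input, size=n_inh, replace=False)
    roles[inh] = Role.INHIBITORY

    conn = rng.random((n, n)) < p_connect
    np.fill_diagonal(conn, False)
    w = np.where(conn, rng.uniform(*exc_weight_range, size=(n, n)), 0.0)
    is_inh = roles == Role.INHIBITORY
    w[is_inh, :] = np.where(conn[is_inh, :], -inh_weight, 0.0)
    d = np.where(conn, rng.uniform(*delay_range_ms, size=(n, n)), 0.0)
    if plastic == "excitatory":
        plas = conn & ~is_inh[:, None]
    elif plastic == "all":
        plas = conn.copy()
    elif plastic == "none":
        plas = np.zeros_like(conn)
    else:
        raise ValueError(f"unknown plastic spec {plastic!r}")
    return Topology(n=n, roles=roles, weights=w, delays=d, connected=conn,
                    plastic=plas, w_max=w_max)


# ---------------------------------------------------------------------------
# simulation state and step
# ---------------------------------------------------------------------------

class NetworkState:
    """Mutable simulation state bound to a compiled view of one Topology.

    Holds membrane/recovery variables, the delayed-current ring buffer, and
    per-neuron spike history (depth >= the STDP memory window at physiological
    rates).  Created via :func:`init_state`.
    """

    HIST_DEPTH = 64

    def __init__(self, topo: Topology, dt: float = 1.0, n_sub: int = 4):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.topo = topo
        self.dt = float(dt)
        self.n_sub = int(n_sub)
        n = topo.n
        prm = topo.neuron_params()
        self.pa = np.array([p.a for p in prm])
        self.pb = np.array([p.b for p in prm])
        self.pc = np.array([p.c for p in prm])
        self.pd = np.array([p.d for p in prm])
        self.vpeak = np.array([p.v_peak for p in prm])
        self.v = np.array([p.v_rest for p in prm])
        self.u = self.pb * self.v
        self.t = 0.0

        # outgoing CSR
        src, dst = np.nonzero(topo.connected)
        order = np.lexsort((dst, src))
        src, dst = src[order], dst[order]
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.indptr, src + 1, 1)
        self.indptr = np.cumsum(self.indptr)
        self.indices = dst.astype(np.int64)
        self.wflat = topo.weights[src, dst].copy()
        self.sflat = np.where(topo.inhibitory_mask[src], -1.0, 1.0)
        dsteps = np.round(topo.delays[src, dst] / self.dt).astype(np.int64)
        if np.any(dsteps < 1):
            raise ValueError("conduction delays must be >= dt")
        self.dsteps = dsteps
        self.pflat = topo.plastic[src, dst].copy()
        self._src = src
        self._dst = dst

        # incoming CSR referencing flat synapse indices
        iorder = np.lexsort((src, dst))
        self.iindptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.iindptr, dst[iorder] + 1, 1)
        self.iindptr = np.cumsum(self.iindptr)
        self.ipre = src[iorder].astype(np.int64)
        self.iflat = np.arange(len(src), dtype=np.int64)[iorder]

        n_slots = (int(dsteps.max()) if len(dsteps) else 1) + 1
        self.n_slots = n_slots
        self.buf = np.zeros((n_slots, n))
        self.pos = 0
        self.last_spike = np.full(n, -np.inf)
        self.hist = np.full((n, self.HIST_DEPTH), -np.inf)
        self.hist_n = np.zeros(n, dtype=np.int64)
        self._spike_scratch = np.empty(n, dtype=np.int64)

    def weight(self, i: int, j: int) -> float:
        """Current weight of synapse i -> j."""
        lo, hi = self.indptr[i], self.indptr[i + 1]
        k = np.searchsorted(self.indices[lo:hi], j)
        if k == hi - lo or self.indices[lo + k] != j:
            raise KeyError(f"no synapse {i}->{j}")
        return float(self.wflat[lo + k])

    def weights_dense(self) -> np.ndarray:
        w = np.zeros((self.topo.n, self.topo.n))
        w[self._src, self._dst] = self.wflat
        return w


def init_state(topo: Topology, dt: float = 1.0) -> NetworkState:
    return NetworkState(topo, dt=dt)


def step(state: NetworkState, topo: Topology, external_current: np.ndarray,
         dt: float | None = None) -> np.ndarray:
    """Advance the network one step; returns the ids of neurons that spiked.

    Spikes are stamped with the time at the *end* of the step; a presynaptic
    spike stamped T depolarizes its target starting at T + delay.  Raises on
    non-finite state (integration instability).
    """
    if topo is not state.topo:
        raise ValueError("state was initialized for a different topology")
    if dt is not None and dt != state.dt:
        raise ValueError("dt is fixed at state initialization")
    ns = _kernels.advance(state.v, state.u, state.pa, state.pb, state.pc,
                          state.pd, state.vpeak, external_current,
                          state.buf, state.pos, state.n_slots,
                          state.indptr, state.indices, state.wflat,
                          state.dsteps, state._spike_scratch, state.dt,
                          state.n_sub)
    state.pos += 1
    if state.pos == state.n_slots:
        state.pos = 0
    state.t += state.dt
    if not np.isfinite(state.v).all():
        raise FloatingPointError(
            f"non-finite membrane potential at t={state.t} ms")
    return state._spike_scratch[:ns].copy()


def sync_weights(state: NetworkState, topo: Topology | None = None) -> None:
    """Write the current (possibly plastically-updated) weights back into
    ``topo.weights``."""
    topo = topo or state.topo
    topo.weights[state._src, state._dst] = state.wflat


# ---------------------------------------------------------------------------
# background noise
# ---------------------------------------------------------------------------

class GaussianNoise:
    """Independent per-neuron, per-step Gaussian current; chunked generation.

    The default amplitude makes an isolated regular-spiking neuron fire at
    roughly 2 Hz, giving unconnected (hidden) neurons their baseline random
    firing.
    """

    def __init__(self, n: int, sigma: float = DEFAULT_NOISE_SIGMA,
                 seed=0, chunk: int = 1024):
        if sigma < 0:
            raise ValueError("noise level must be >= 0")
        self.n = n
        self.sigma = float(sigma)
        self._rng = np.random.default_rng(seed)
        self._chunk = chunk
        self._buf = np.empty((0, n))
        self._row = 0

    def next(self) -> np.ndarray:
        """Current vector for one step. The returned row may be mutated by
        the caller (each row is handed out exactly once)."""
        if self._row >= len(self._buf):
            if self.sigma == 0.0:
                self._buf = np.zeros((self._chunk, self.n))
            else:
                self._buf = self._rng.standard_normal(
                    (self._chunk, self.n)) * self.sigma
            self._row = 0
        out = self._buf[self._row]
        self._row += 1
        return out


def background_noise(n: int, sigma: float = DEFAULT_NOISE_SIGMA,
                     seed=0) -> GaussianNoise:
    """Per-neuron background current generator, reproducible from ``seed``."""
    return GaussianNoise(n, sigma=sigma, seed=seed)
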