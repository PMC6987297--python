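"""Symmetric rectangular STDP: fixed-step potentiation/depression windows.

The rule acts on the signed lag between a postsynaptic and a presynaptic
spike (``lag = t_post - t_pre``):

    +dw   if 0 < lag < dt_p_max      (LTP: pre just before post)
    -dw   if 0 < -lag < dt_d_max     (LTD: pre just after post)
     0    otherwise (including exactly simultaneous spikes)

Both windows default to 20 ms and the step magnitude is constant inside the
window (rectangular kernel, equal LTP/LTD magnitudes by default).  Weight
magnitudes are clipped to [0, w_max]; the synapse sign, fixed by the
presynaptic neuron's type, is never flipped.  The memory window tau is the
larger of the two windows: it is the horizon over which the network can
associate an action with its consequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .neural_core import DEFAULT_W_MAX, NetworkState

__all__ = ["STDPConfig", "stdp_delta", "apply_stdp_on_spike",
           "oracle_pair_sum"]


@dataclass(frozen=True)
class STDPConfig:
    """Windows (ms), step magnitude, bounds, and pairing scheme.

    ``pairing`` is 'nearest' (each spike pairs with the partner's most recent
    earlier spike; default — bounds the drift under dense firing) or 'all'
    (every spike pair inside the window counts).
    """

    dt_p_max: float = 20.0
    dt_d_max: float = 20.0
    dw: float = 0.01 * DEFAULT_W_MAX
    dw_depression: float | None = None   # None -> same as dw
    w_max: float = DEFAULT_W_MAX
    pairing: str = "nearest"

    def __post_init__(self):
        if self.dt_p_max <= 0 or self.dt_d_max <= 0:
            raise ValueError("STDP windows must be positive")
        if self.dw <= 0 or self.w_max <= 0:
            raise ValueError("dw and w_max must be positive")
        if self.pairing not in ("nearest", "all"):
            raise ValueError(f"unknown pairing scheme {self.pairing!r}")

    @property
    def dw_d(self) -> float:
        return self.dw if self.dw_depression is None else self.dw_depression

    @property
    def tau(self) -> float:
        """Memory window: the larger of the two STDP windows (ms)."""
        return max(self.dt_p_max, self.dt_d_max)


def stdp_delta(lag: float, config: STDPConfig) -> float:
    """Signed efficacy change for one pre/post pair with the given lag (ms).

    ``lag`` is the post-spike time minus the pre-spike time.
    """
    if 0.0 < lag < config.dt_p_max:
        return config.dw
    if 0.0 < -lag < config.dt_d_max:
        return -config.dw_d
    return 0.0


def apply_stdp_on_spike(state: NetworkState, spiked: np.ndarray, t: float,
                        config: STDPConfig) -> None:
    """Event-wise update for the neurons that spiked at time ``t``.

    For each new spike, every plastic synapse touching that neuron is paired
    with partner spikes per the pairing scheme and moved by the summed rule,
    clipping the magnitude to [0, w_max] after each pairing.  Non-plastic
    synapses are untouched.  ``state`` carries the spike history buffers
    (depth covering at least tau of history at physiological rates).
    """
    spiked = np.asarray(spiked, dtype=np.int64)
    if spiked.size == 0:
        return
    _kernels.stdp_update(spiked, spiked.size, t, state.last_spike,
                         state.hist, state.hist_n, state.HIST_DEPTH,
                         state.wflat, state.sflat, state.pflat,
                         state.indptr, state.indices,
                         state.iindptr, state.ipre, state.iflat,
                         config.dw, config.dw_d,
                         config.dt_p_max, config.dt_d_max, config.w_max,
                         config.pairing == "all")


def oracle_pair_sum(pre: np.ndarray, post: np.ndarray, config: STDPConfig,
                    w0: float = 0.0, bounded: bool = False) -> float:
    """Total signed change from exhaustive pair enumeration (test oracle).

    Replays the two sorted spike trains event by event in time order.  At a
    post spike, potentiation pairings with earlier pre spikes are applied; at
    a pre spike, depression pairings with earlier post spikes.  Simultaneous
    pre/post spikes never pair (the rule's sign is undefined at lag 0).  With
    ``bounded=True`` the running magnitude ``w0 + change`` is clipped to
    [0, w_max] after every pairing, in time order, and the bounded net change
    is returned; otherwise pairings are summed freely.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(np.diff(pre) < 0) or np.any(np.diff(post) < 0):
        raise ValueError("spike trains must be sorted")
    nearest = config.pairing == "nearest"
    events = ([(t, 0) for t in pre] + [(t, 1) for t in post])
    # post events first at equal times: irrelevant for the total (lag-0 pairs
    # are skipped) but fixed for determinism
    events.sort(key=lambda e: (e[0], e[1]))
    w = w0
    total = 0.0

    def _apply(delta: float) -> None:
        nonlocal w, total
        if bounded:
            new = min(config.w_max, max(0.0, w + delta))
            total += new - w
            w = new
        else:
            total += delta

    for t, which in events:
        if which == 1:  # post spike: potentiation with earlier pre spikes
            earlier = pre[pre < t]
            if nearest:
                earlier = earlier[-1:]
            for tp in earlier[::-1]:
                lag = t - tp
                if lag >= config.dt_p_max:
                    break
                _apply(config.dw)
        else:           # pre spike: depression with earlier post spikes
            earlier = post[post < t]
            if nearest:
                earlier = earlier[-1:]
            for tq in earlier[::-1]:
                if t - tq >= config.dt_d_max:
                    break
                _apply(-config.dw_d)
    return total
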