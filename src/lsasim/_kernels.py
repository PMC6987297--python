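"""Compiled inner loops: membrane integration, delayed synaptic delivery, STDP.

All kernels operate on flat CSR-style arrays owned by ``neural_core.NetworkState``.
Times are in ms, currents in the dimensionless efficacy/current units of the
Izhikevich model (numerically mV per ms of membrane drive).
"""

import numpy as np
from numba import njit

__all__ = ["advance", "stdp_update"]


@njit(cache=True)
def advance(v, u, pa, pb, pc, pd, vpeak, i_ext, buf, pos, n_slots,
            indptr, indices, wflat, dsteps, spiked, dt, n_sub):
    """One network step of ``dt`` ms.

    Consumes the current ring-buffer slot ``pos``, integrates the two-variable
    quadratic model with ``n_sub`` membrane substeps, resets neurons crossing
    ``vpeak``, and schedules their synaptic charge ``dsteps`` slots ahead.
    Returns the number of spikes; their ids are written into ``spiked``.
    """
    n = v.size
    ns = 0
    h = dt / n_sub
    for i in range(n):
        cur = i_ext[i] + buf[pos, i]
        buf[pos, i] = 0.0
        vi = v[i]
        ui = u[i]
        for _ in range(n_sub):
            vi += h * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + cur)
            if vi >= vpeak[i]:
                vi = vpeak[i]   # clamp the upswing at the spike cutoff
                break
        ui += dt * pa[i] * (pb[i] * vi - ui)
        if vi >= vpeak[i]:
            spiked[ns] = i
            ns += 1
            vi = pc[i]
            ui += pd[i]
        v[i] = vi
        u[i] = ui
    for k in range(ns):
        i = spiked[k]
        for e in range(indptr[i], indptr[i + 1]):
            slot = pos + dsteps[e]
            if slot >= n_slots:
                slot -= n_slots
            buf[slot, indices[e]] += wflat[e]
    return ns


@njit(cache=True)
def stdp_update(spiked, ns, t, last_spike, hist, hist_n, hist_depth,
                wflat, sflat, pflat, indptr, indices, iindptr, ipre, iflat,
                dw_p, dw_d, win_p, win_d, wmax, all_pairs):
    """Event-wise STDP for the spikes of the current step (spike time ``t``).

    Rectangular rule on the signed lag (post minus pre spike time):
    +dw_p for 0 < lag < win_p, -dw_d for 0 < lag < win_d, nothing at lag 0.
    Updates act on the weight *magnitude*, clipped to [0, wmax]; the sign
    (presynaptic type) is never flipped.  Nearest-neighbor pairing uses the
    partner's most recent earlier spike; all-pairs walks the spike history.
    Within one step, depression pairings (spiking neuron as presynaptic
    partner) are applied before potentiation pairings, a fixed tie-break the
    pair-enumeration oracle replays.
    """
    for k in range(ns):
        j = spiked[k]
        # j as presynaptic partner: depress outgoing synapses
        for e in range(indptr[j], indptr[j + 1]):
            if not pflat[e]:
                continue
            jj = indices[e]
            if all_pairs:
                m = hist_n[jj]
                if m > hist_depth:
                    m = hist_depth
                for h in range(m):
                    tq = hist[jj, (hist_n[jj] - 1 - h) % hist_depth]
                    lag = t - tq
                    if lag <= 0.0:
                        continue
                    if lag >= win_d:
                        break
                    mag = wflat[e] * sflat[e] - dw_d
                    if mag < 0.0:
                        mag = 0.0
                    wflat[e] = mag * sflat[e]
            else:
                lag = t - last_spike[jj]
                if 0.0 < lag < win_d:
                    mag = wflat[e] * sflat[e] - dw_d
                    if mag < 0.0:
                        mag = 0.0
                    wflat[e] = mag * sflat[e]
    for k in range(ns):
        j = spiked[k]
        # j as postsynaptic partner: potentiate incoming synapses
        for e in range(iindptr[j], iindptr[j + 1]):
            f = iflat[e]
            if not pflat[f]:
                continue
            i = ipre[e]
            if all_pairs:
                m = hist_n[i]
                if m > hist_depth:
                    m = hist_depth
                for h in range(m):
                    tp = hist[i, (hist_n[i] - 1 - h) % hist_depth]
                    lag = t - tp
                    if lag <= 0.0:
                        continue
                    if lag >= win_p:
                        break
                    mag = wflat[f] * sflat[f] + dw_p
                    if mag > wmax:
                        mag = wmax
                    wflat[f] = mag * sflat[f]
            else:
                lag = t - last_spike[i]
                if 0.0 < lag < win_p:
                    mag = wflat[f] * sflat[f] + dw_p
                    if mag > wmax:
                        mag = wmax
                    wflat[f] = mag * sflat[f]
    for k in range(ns):
        j = spiked[k]
        last_spike[j] = t
        hist[j, hist_n[j] % hist_depth] = t
        hist_n[j] += 1
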