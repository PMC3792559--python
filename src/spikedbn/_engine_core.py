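"""Numba-compiled inner loop of the event-driven simulator.

Semantics are identical to the scalar reference (`engine.process_event`)
and the clock-driven oracle; the test suite holds all three together.
Layers are flattened into contiguous neuron arrays; connection groups are
packed into one weight buffer with an index table.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_events"]

LONG_AGO = -(2**62)

# queue entry kinds
_EXTERNAL = 0
_INTERNAL = 1
_BIAS = 2


@njit(cache=True)
def _grow_i64(arr, cap):  # pragma: no cover
    out = np.empty(cap, np.int64)
    out[:arr.shape[0]] = arr
    return out


@njit(cache=True)
def _grow_i32(arr, cap):  # pragma: no cover
    out = np.empty(cap, np.int32)
    out[:arr.shape[0]] = arr
    return out


@njit(cache=True)
def simulate_events(
    ev_t, ev_layer, ev_unit,          # merged external + bias events (sorted)
    sizes, is_lif,                    # per-layer unit count / has-dynamics flag
    n_groups, g_src, g_tgt, g_wofs,   # routing table
    w_flat,                           # all group weights, row-major per group
    bias_w_flat, bias_ofs,            # per-layer bias event weights
    v, last_t, ref_until, last_spike,  # flattened per-neuron state
    layer_ofs,
    inv_tau_us, v_th, v_reset, t_ref_us,
    g_stdp_amp, stdp_inv_tau_us,
):  # pragma: no cover - exercised through engine.run
    """Process the event queue; returns recorded (t, layer, unit) arrays.

    ev_layer = -1 marks a bias tick.  Entries with equal timestamps are
    processed in order: the pre-sorted externals and bias ticks first, then
    internally generated spikes in creation order -- the same
    (timestamp, stream, creation) contract as the scalar reference.
    """
    cap = 1024
    rec_t = np.empty(cap, np.int64)
    rec_l = np.empty(cap, np.int32)
    rec_u = np.empty(cap, np.int64)
    n_rec = 0

    qcap = 1024
    q_kind = np.empty(qcap, np.int32)
    q_l = np.empty(qcap, np.int32)
    q_u = np.empty(qcap, np.int64)

    n_ev = ev_t.shape[0]
    i = 0
    while i < n_ev:
        t = ev_t[i]
        q_head = 0
        q_tail = 0
        while i < n_ev and ev_t[i] == t:
            if q_tail == qcap:
                qcap *= 2
                q_kind = _grow_i32(q_kind, qcap)
                q_l = _grow_i32(q_l, qcap)
                q_u = _grow_i64(q_u, qcap)
            if ev_layer[i] < 0:
                q_kind[q_tail] = _BIAS
                q_l[q_tail] = -1
                q_u[q_tail] = -1
            else:
                q_kind[q_tail] = _EXTERNAL
                q_l[q_tail] = ev_layer[i]
                q_u[q_tail] = ev_unit[i]
            q_tail += 1
            i += 1

        while q_head < q_tail:
            kind = q_kind[q_head]
            src = q_l[q_head]
            unit = q_u[q_head]
            q_head += 1

            if kind == _BIAS:
                for l in range(sizes.shape[0]):
                    if not is_lif[l]:
                        continue
                    ofs = layer_ofs[l]
                    bofs = bias_ofs[l]
                    for j in range(sizes[l]):
                        w = bias_w_flat[bofs + j]
                        if w == 0.0:
                            continue
                        idx = ofs + j
                        if t < ref_until[idx]:
                            continue
                        dt = t - last_t[idx]
                        v[idx] = v[idx] * np.exp(-dt * inv_tau_us) + w
                        last_t[idx] = t
                        if v[idx] >= v_th:
                            v[idx] = v_reset
                            ref_until[idx] = t + t_ref_us
                            last_spike[idx] = t
                            if n_rec == cap:
                                cap *= 2
                                rec_t = _grow_i64(rec_t, cap)
                                rec_l = _grow_i32(rec_l, cap)
                                rec_u = _grow_i64(rec_u, cap)
                            rec_t[n_rec] = t
                            rec_l[n_rec] = l
                            rec_u[n_rec] = j
                            n_rec += 1
                            if q_tail == qcap:
                                qcap *= 2
                                q_kind = _grow_i32(q_kind, qcap)
                                q_l = _grow_i32(q_l, qcap)
                                q_u = _grow_i64(q_u, qcap)
                            q_kind[q_tail] = _INTERNAL
                            q_l[q_tail] = l
                            q_u[q_tail] = j
                            q_tail += 1
                continue

            if kind == _EXTERNAL:
                # an external event is a spike of this layer's own unit
                if n_rec == cap:
                    cap *= 2
                    rec_t = _grow_i64(rec_t, cap)
                    rec_l = _grow_i32(rec_l, cap)
                    rec_u = _grow_i64(rec_u, cap)
                rec_t[n_rec] = t
                rec_l[n_rec] = src
                rec_u[n_rec] = unit
                n_rec += 1
                idx = layer_ofs[src] + unit
                last_spike[idx] = t
                if is_lif[src]:  # forced firing: reset + refractory
                    v[idx] = v_reset
                    last_t[idx] = t
                    ref_until[idx] = t + t_ref_us

            # route the spike along all enabled outgoing groups
            for g in range(n_groups):
                if g_src[g] != src:
                    continue
                tgt = g_tgt[g]
                nt = sizes[tgt]
                wofs = g_wofs[g] + unit * nt
                tofs = layer_ofs[tgt]
                amp = g_stdp_amp[g]
                for j in range(nt):
                    idx = tofs + j
                    if t < ref_until[idx]:
                        continue
                    w = w_flat[wofs + j]
                    if amp > 0.0:
                        dpair = t - last_spike[idx]
                        w -= amp * np.exp(-dpair * stdp_inv_tau_us)
                    dt = t - last_t[idx]
                    v[idx] = v[idx] * np.exp(-dt * inv_tau_us) + w
                    last_t[idx] = t
                    if v[idx] >= v_th:
                        v[idx] = v_reset
                        ref_until[idx] = t + t_ref_us
                        last_spike[idx] = t
                        if n_rec == cap:
                            cap *= 2
                            rec_t = _grow_i64(rec_t, cap)
                            rec_l = _grow_i32(rec_l, cap)
                            rec_u = _grow_i64(rec_u, cap)
                        rec_t[n_rec] = t
                        rec_l[n_rec] = tgt
                        rec_u[n_rec] = j
                        n_rec += 1
                        if q_tail == qcap:
                            qcap *= 2
                            q_kind = _grow_i32(q_kind, qcap)
                            q_l = _grow_i32(q_l, qcap)
                            q_u = _grow_i64(q_u, qcap)
                        q_kind[q_tail] = _INTERNAL
                        q_l[q_tail] = tgt
                        q_u[q_tail] = j
                        q_tail += 1

    return rec_t[:n_rec], rec_l[:n_rec], rec_u[:n_rec]
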