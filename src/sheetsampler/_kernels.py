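"""Discrete-time simulation kernel (JIT compiled).

One shared RNG stream drives a run; it is consumed in a fixed documented
order per time step so that a seed fully determines the trace:

1. input spike draws, by input index (skipped entirely when the input is
   clamped),
2. the network-neuron visit order (Fisher–Yates, K−1 integer draws),
3. one uniform per *eligible* network neuron, in visit order,
4. if wake–sleep learning is active: the companion prior-sampler's visit
   order, then one uniform per eligible sleep neuron.

``simulate_reference`` in :mod:`sheetsampler.simulator` replays the identical
stream in pure Python and must agree bit-for-bit with this kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RULE_NONE = 0
RULE_HEURISTIC = 1
RULE_WAKESLEEP = 2


@njit(cache=True)
def run_core(seed, n_steps, tau_steps,
             seg_ends, seg_p, clamp_y,
             use_y_trace, y_trace,
             V, V0, b, Wexc, Winh, aff_idx,
             z, cnt_z, y, cnt_y,
             plast_rule, aff_on, eta_V, eta_b, eta_W, dt,
             m, Wmax, gamma, clip_nonneg,
             b_sleep, z_sleep, cnt_sleep, exc_pairs,
             record_z, record_y,
             measure_start, zsum, zzsum, accumulate_zz,
             spike_count, input_spike_count,
             wsum_start, wsum,
             ckpt_every, ckpt_V, ckpt_b, ckpt_W,
             record_events, events, ev_count):
    np.random.seed(seed)
    K = V.shape[0]
    N = V0.shape[0]
    F = aff_idx.shape[1]
    log_tau = np.log(float(tau_steps))
    order = np.empty(K, dtype=np.int64)
    order_s = np.empty(K, dtype=np.int64)
    seg = 0
    n_ev = ev_count[0]
    max_ev = events.shape[0]
    wake_sleep = plast_rule == RULE_WAKESLEEP
    cap = Wmax * (1.0 - 1e-6)
    lo = 0.0 if clip_nonneg else -cap

    for t in range(n_steps):
        # --- input update ---------------------------------------------------
        if use_y_trace:
            # prescribed spike-identical input states; no RNG consumed
            for i in range(N):
                y[i] = y_trace[t, i]
        elif not clamp_y:
            while t >= seg_ends[seg]:
                seg += 1
            for i in range(N):
                if cnt_y[i] > 0:
                    cnt_y[i] -= 1
                u = np.random.random()
                if u < seg_p[seg, i]:
                    cnt_y[i] = tau_steps
                    input_spike_count[i] += 1
                    if record_events and n_ev < max_ev:
                        events[n_ev, 0] = t
                        events[n_ev, 1] = K + i
                        n_ev += 1
                y[i] = 1 if cnt_y[i] > 0 else 0

        # --- network neurons, fresh random visit order ---------------------
        for k in range(K):
            order[k] = k
        for k in range(K - 1, 0, -1):
            j = np.random.randint(0, k + 1)
            tmp = order[k]
            order[k] = order[j]
            order[j] = tmp

        for idx in range(K):
            k = order[idx]
            if cnt_z[k] <= 1:
                # eligible: inactive, or in the last step of its active phase
                u = b[k]
                for j in range(K):
                    if z[j] == 1:
                        u += Wexc[k, j] + Winh[k, j]
                # j == k contributes nothing (zero diagonal)
                for f in range(F):
                    i = aff_idx[k, f]
                    if y[i] == 1:
                        u += V[k, i]
                p = 1.0 / (1.0 + np.exp(-(u - log_tau)))
                if np.random.random() < p:
                    cnt_z[k] = tau_steps
                    z[k] = 1
                    spike_count[k] += 1
                    if record_events and n_ev < max_ev:
                        events[n_ev, 0] = t
                        events[n_ev, 1] = k
                        n_ev += 1
                else:
                    cnt_z[k] = 0
                    z[k] = 0
            else:
                cnt_z[k] -= 1

        # --- companion prior sampler (sleep phase), no input ---------------
        if wake_sleep:
            for k in range(K):
                order_s[k] = k
            for k in range(K - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = order_s[k]
                order_s[k] = order_s[j]
                order_s[j] = tmp
            for idx in range(K):
                k = order_s[idx]
                if cnt_sleep[k] <= 1:
                    u = b_sleep[k]
                    for j in range(K):
                        if z_sleep[j] == 1:
                            u += Wexc[k, j] + Winh[k, j]
                    p = 1.0 / (1.0 + np.exp(-(u - log_tau)))
                    if np.random.random() < p:
                        cnt_sleep[k] = tau_steps
                        z_sleep[k] = 1
                    else:
                        cnt_sleep[k] = 0
                        z_sleep[k] = 0
                else:
                    cnt_sleep[k] -= 1

        # --- plasticity (Euler step on the current states) ------------------
        if aff_on and eta_V > 0.0:
            for k in range(K):
                if z[k] == 1:
                    for f in range(F):
                        i = aff_idx[k, f]
                        s = 1.0 / (1.0 + np.exp(-(V[k, i] + V0[i])))
                        V[k, i] += dt * eta_V * (y[i] - s)
                        if clip_nonneg and V[k, i] < 0.0:
                            V[k, i] = 0.0
        if eta_b > 0.0:
            for k in range(K):
                b[k] += dt * eta_b * (m[k] - z[k])
        if plast_rule == RULE_HEURISTIC and eta_W > 0.0:
            for pidx in range(exc_pairs.shape[0]):
                k = exc_pairs[pidx, 0]
                j = exc_pairs[pidx, 1]
                w = Wexc[k, j]
                ltd = m[k] * m[j] + np.tan(0.5 * np.pi * w / Wmax) / gamma
                w += dt * eta_W * (z[k] * z[j] - ltd)
                if w < lo:
                    w = lo
                elif w > cap:
                    w = cap
                Wexc[k, j] = w
                Wexc[j, k] = w
        elif wake_sleep and eta_W > 0.0:
            for pidx in range(exc_pairs.shape[0]):
                k = exc_pairs[pidx, 0]
                j = exc_pairs[pidx, 1]
                w = Wexc[k, j] + dt * eta_W * (z[k] * z[j] -
                                               z_sleep[k] * z_sleep[j])
                if clip_nonneg and w < 0.0:
                    w = 0.0
                Wexc[k, j] = w
                Wexc[j, k] = w
            for k in range(K):
                b_sleep[k] += dt * eta_b * (z[k] - z_sleep[k])

        # --- recording and accumulation -------------------------------------
        if record_z.shape[0] > 0:
            for k in range(K):
                record_z[t, k] = z[k]
        if record_y.shape[0] > 0:
            for i in range(N):
                record_y[t, i] = y[i]
        if t >= measure_start:
            for k in range(K):
                if z[k] == 1:
                    zsum[k] += 1.0
            if accumulate_zz:
                for k in range(K):
                    if z[k] == 1:
                        for j in range(K):
                            if z[j] == 1:
                                zzsum[k, j] += 1.0
        if t >= wsum_start:
            for k in range(K):
                for j in range(K):
                    wsum[k, j] += Wexc[k, j]
        if ckpt_every > 0 and (t + 1) % ckpt_every == 0:
            c = (t + 1) // ckpt_every - 1
            if c < ckpt_b.shape[0]:
                for k in range(K):
                    ckpt_b[c, k] = b[k]
                    for j in range(K):
                        ckpt_W[c, k, j] = Wexc[k, j]
                    for i in range(N):
                        ckpt_V[c, k, i] = V[k, i]

    ev_count[0] = n_ev
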