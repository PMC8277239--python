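"""Numba time-stepping kernels for the IF and QIF spiking networks.

All-to-all blocks with identical weights admit an exact optimization: the
summed double-exponential drive onto every target neuron is a single pair
of filtered population spike trains (A1, A2) per block, updated exactly
between events (``A <- A*exp(-dt/tau) + arriving jumps``).  Delayed jumps
are held in per-block ring buffers indexed by arrival step; each jump is
pre-decayed from its interpolated arrival time to the next step boundary,
so the exponential states remain exact despite the fixed step.

The IF voltage is integrated with exponential Euler (the synaptic
conductances are frozen over one step, making the voltage equation linear
with known exact solution); the QIF voltage with explicit Euler.  Spike
times are located by linear interpolation within the crossing step.

Error codes returned by the kernels: 0 ok, 1 spike-buffer overflow,
2 non-finite voltage, 3 per-step voltage change exceeded ``max_dv``.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["if_step_loop", "qif_step_loop"]


@numba.njit(cache=True)
def if_step_loop(
    n_steps,
    dt,
    t0,
    pop_off,
    p_tau,
    p_vrest,
    p_vpeak,
    p_vreset,
    bias_mv,
    V,
    b_src,
    b_tgt,
    b_tau1,
    b_tau2,
    b_vrev,
    b_norm,
    b_jump,
    b_taud,
    A1,
    A2,
    L,
    buf1,
    buf2,
    onsets_flat,
    onset_off,
    onset_ptr,
    sq_tgt,
    sq_t0,
    sq_t1,
    sq_dv,
    kick_tgt,
    kick_t,
    kick_dv,
    kick_ptr,
    rec_every,
    lfp_out,
    syn_out,
    spike_id,
    spike_t,
    max_dv,
):  # pragma: no cover - exercised via network.simulate
    npop = pop_off.shape[0] - 1
    nb = b_src.shape[0]
    ns = sq_tgt.shape[0]
    nk = kick_tgt.shape[0]
    max_spikes = spike_id.shape[0]
    n_sp = 0

    sum_s = np.zeros(npop)
    sum_sv = np.zeros(npop)
    sq_add = np.zeros(npop)

    d1 = np.empty(nb)
    d2 = np.empty(nb)
    for b in range(nb):
        d1[b] = np.exp(-dt / b_tau1[b])
        d2[b] = np.exp(-dt / b_tau2[b])

    for k in range(n_steps):
        t = t0 + k * dt
        # synaptic drive at start of step
        for p in range(npop):
            sum_s[p] = 0.0
            sum_sv[p] = 0.0
            sq_add[p] = 0.0
        for b in range(nb):
            s = b_norm[b] * (A2[b] - A1[b])
            tgt = b_tgt[b]
            sum_s[tgt] += s
            sum_sv[tgt] += s * b_vrev[b]
        for j in range(ns):
            if sq_t0[j] <= t < sq_t1[j]:
                sq_add[sq_tgt[j]] += sq_dv[j]

        # record start-of-step state
        if k % rec_every == 0:
            r = k // rec_every
            for p in range(npop):
                acc = 0.0
                for i in range(pop_off[p], pop_off[p + 1]):
                    acc += V[i]
                lfp_out[p, r] = acc / (pop_off[p + 1] - pop_off[p])
            for b in range(nb):
                syn_out[b, r] = b_norm[b] * (A2[b] - A1[b])

        # integrate membrane, detect crossings
        for p in range(npop):
            G = 1.0 + sum_s[p]
            e = np.exp(-G * dt / p_tau[p])
            base = p_vrest[p] + sum_sv[p] + sq_add[p]
            vpk = p_vpeak[p]
            vrs = p_vreset[p]
            for i in range(pop_off[p], pop_off[p + 1]):
                a = (base + bias_mv[i]) / G
                v_old = V[i]
                v_new = a + (v_old - a) * e
                if abs(v_new - v_old) > max_dv:
                    return n_sp, 3
                if v_new >= vpk:
                    frac = (vpk - v_old) / (v_new - v_old)
                    t_cross = t + frac * dt
                    if n_sp >= max_spikes:
                        return n_sp, 1
                    spike_id[n_sp] = i
                    spike_t[n_sp] = t_cross
                    n_sp += 1
                    # schedule delayed jumps on outgoing blocks
                    for b in range(nb):
                        if b_src[b] == p:
                            arr = t_cross + b_taud[b] - t0
                            ka = int(np.ceil(arr / dt - 1e-9))
                            if ka <= k:
                                ka = k + 1
                            lag = ka * dt - arr
                            slot = ka % L
                            buf1[b, slot] += b_jump[b] * np.exp(-lag / b_tau1[b])
                            buf2[b, slot] += b_jump[b] * np.exp(-lag / b_tau2[b])
                    v_new = vrs
                if not np.isfinite(v_new):
                    return n_sp, 2
                V[i] = v_new

        # externally driven blocks: arrivals in (t, t+dt]
        for b in range(nb):
            if b_src[b] == -1:
                o0 = onset_off[b]
                o1 = onset_off[b + 1]
                while onset_ptr[b] < o1 - o0:
                    arr = onsets_flat[o0 + onset_ptr[b]] + b_taud[b] - t0
                    ka = int(np.ceil(arr / dt - 1e-9))
                    if ka <= k:
                        ka = k + 1  # late (pre-start) arrivals land now
                    if ka > k + 1:
                        break
                    lag = ka * dt - arr
                    if lag < 0.0:
                        lag = 0.0
                    slot = ka % L
                    buf1[b, slot] += b_jump[b] * np.exp(-lag / b_tau1[b])
                    buf2[b, slot] += b_jump[b] * np.exp(-lag / b_tau2[b])
                    onset_ptr[b] += 1

        # advance synaptic states to the end-of-step boundary
        slot = (k + 1) % L
        for b in range(nb):
            A1[b] = A1[b] * d1[b] + buf1[b, slot]
            A2[b] = A2[b] * d2[b] + buf2[b, slot]
            buf1[b, slot] = 0.0
            buf2[b, slot] = 0.0

        # delta kicks due at the end-of-step boundary
        tb = t0 + (k + 1) * dt
        while kick_ptr[0] < nk and kick_t[kick_ptr[0]] <= tb + 1e-12:
            p = kick_tgt[kick_ptr[0]]
            dv = kick_dv[kick_ptr[0]]
            for i in range(pop_off[p], pop_off[p + 1]):
                V[i] += dv
            kick_ptr[0] += 1

    return n_sp, 0


@numba.njit(cache=True)
def qif_step_loop(
    n_steps,
    dt,
    t0,
    pop_off,
    p_tau,
    p_vpeak,
    p_vreset,
    eta,
    V,
    b_src,
    b_tgt,
    b_tau1,
    b_tau2,
    b_sign,
    b_jump,
    b_taud,
    A1,
    A2,
    L,
    buf1,
    buf2,
    sq_tgt,
    sq_t0,
    sq_t1,
    sq_amp,
    kick_tgt,
    kick_t,
    kick_dv,
    kick_ptr,
    rec_every,
    lfp_out,
    rate_out,
    syn_out,
    spike_id,
    spike_t,
):  # pragma: no cover - exercised via network.simulate
    npop = pop_off.shape[0] - 1
    nb = b_src.shape[0]
    ns = sq_tgt.shape[0]
    nk = kick_tgt.shape[0]
    max_spikes = spike_id.shape[0]
    n_sp = 0

    cur = np.zeros(npop)
    spk_count = np.zeros(npop)

    d1 = np.empty(nb)
    d2 = np.empty(nb)
    for b in range(nb):
        d1[b] = np.exp(-dt / b_tau1[b])
        d2[b] = np.exp(-dt / b_tau2[b])

    for k in range(n_steps):
        t = t0 + k * dt
        for p in range(npop):
            cur[p] = 0.0
            spk_count[p] = 0.0
        for b in range(nb):
            s = A2[b] - A1[b]
            cur[b_tgt[b]] += b_sign[b] * p_tau[b_tgt[b]] * s
        for j in range(ns):
            if sq_t0[j] <= t < sq_t1[j]:
                cur[sq_tgt[j]] += sq_amp[j]

        if k % rec_every == 0:
            r = k // rec_every
            for p in range(npop):
                acc = 0.0
                for i in range(pop_off[p], pop_off[p + 1]):
                    acc += V[i]
                lfp_out[p, r] = acc / (pop_off[p + 1] - pop_off[p])
            for b in range(nb):
                syn_out[b, r] = A2[b] - A1[b]

        for p in range(npop):
            inv_tau = 1.0 / p_tau[p]
            vpk = p_vpeak[p]
            vrs = p_vreset[p]
            Ip = cur[p]
            for i in range(pop_off[p], pop_off[p + 1]):
                v_old = V[i]
                v_new = v_old + dt * inv_tau * (eta[i] + v_old * v_old + Ip)
                if v_new >= vpk:
                    frac = (vpk - v_old) / (v_new - v_old)
                    t_cross = t + frac * dt
                    if n_sp >= max_spikes:
                        return n_sp, 1
                    spike_id[n_sp] = i
                    spike_t[n_sp] = t_cross
                    n_sp += 1
                    spk_count[p] += 1.0
                    for b in range(nb):
                        if b_src[b] == p:
                            arr = t_cross + b_taud[b] - t0
                            ka = int(np.ceil(arr / dt - 1e-9))
                            if ka <= k:
                                ka = k + 1
                            lag = ka * dt - arr
                            slot = ka % L
                            buf1[b, slot] += b_jump[b] * np.exp(-lag / b_tau1[b])
                            buf2[b, slot] += b_jump[b] * np.exp(-lag / b_tau2[b])
                    v_new = vrs
                if not np.isfinite(v_new):
                    return n_sp, 2
                V[i] = v_new

        if k % rec_every == 0:
            r = k // rec_every
            for p in range(npop):
                npops = pop_off[p + 1] - pop_off[p]
                rate_out[p, r] = spk_count[p] / (npops * dt)

        slot = (k + 1) % L
        for b in range(nb):
            A1[b] = A1[b] * d1[b] + buf1[b, slot]
            A2[b] = A2[b] * d2[b] + buf2[b, slot]
            buf1[b, slot] = 0.0
            buf2[b, slot] = 0.0

        tb = t0 + (k + 1) * dt
        while kick_ptr[0] < nk and kick_t[kick_ptr[0]] <= tb + 1e-12:
            p = kick_tgt[kick_ptr[0]]
            dv = kick_dv[kick_ptr[0]]
            for i in range(pop_off[p], pop_off[p + 1]):
                V[i] += dv
            kick_ptr[0] += 1

    return n_sp, 0
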