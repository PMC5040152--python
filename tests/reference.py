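"""Independent fixed-step reference integrators used as test oracles.

These deliberately share no code with the event-driven engines: a plain
time-stepped grid integration (kicks applied at bin boundaries, threshold
checked once per step) that converges to the same hybrid dynamics as the
step size goes to zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lif_grid_sim(out_indptr, out_targets, out_weights, V0, mu, duration, dt,
                 tau, theta, Vr, trp, delay, discard_refractory=True):
    """Time-stepped LIF network; returns (spike_steps, spike_ids).

    Per step: (1) apply kicks scheduled for this step to non-refractory
    neurons (discarded otherwise when discard_refractory), (2) exact
    exponential decay toward mu over dt, (3) threshold check; spikes reset V
    and schedule deliveries delay (rounded up to a whole step, min 1 for the
    zero-delay case) later.
    """
    N = V0.size
    n_steps = int(round(duration / dt))
    d_steps = max(1, int(round(delay / dt)))
    r_steps = int(round(trp / dt))
    V = V0.copy()
    ref = np.zeros(N, dtype=np.int64)  # remaining refractory steps
    decay = np.exp(-dt / tau)
    # pending kicks ring buffer: (d_steps+1) x N accumulated weights
    pend = np.zeros((d_steps + 1, N))
    sp_t = []
    sp_i = []
    for step in range(n_steps):
        slot = step % (d_steps + 1)
        for i in range(N):
            if ref[i] == 0:
                V[i] += pend[slot, i]
            pend[slot, i] = 0.0
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
            else:
                V[i] = mu[i] + (V[i] - mu[i]) * decay
        for i in range(N):
            if ref[i] == 0 and V[i] >= theta:
                sp_t.append(step)
                sp_i.append(i)
                V[i] = Vr
                ref[i] = r_steps
                tgt_slot = (step + d_steps) % (d_steps + 1)
                for k in range(out_indptr[i], out_indptr[i + 1]):
                    pend[tgt_slot, out_targets[k]] += out_weights[k]
    return np.array(sp_t, dtype=np.int64), np.array(sp_i, dtype=np.int64)


@njit(cache=True)
def qif_grid_sim(out_indptr, out_targets, out_weights, V0, mu, duration, dt,
                 tau, theta, Vq, dVq, trp, delay, V_peak, V_reset):
    """Time-stepped QIF network (forward Euler on the quadratic flow)."""
    N = V0.size
    n_steps = int(round(duration / dt))
    d_steps = max(1, int(round(delay / dt)))
    r_steps = int(round(trp / dt))
    V = V0.copy()
    ref = np.zeros(N, dtype=np.int64)
    pend = np.zeros((d_steps + 1, N))
    sp_t = []
    sp_i = []
    for step in range(n_steps):
        slot = step % (d_steps + 1)
        for i in range(N):
            if ref[i] == 0:
                V[i] += pend[slot, i]
            pend[slot, i] = 0.0
        for i in range(N):
            if ref[i] > 0:
                ref[i] -= 1
            else:
                V[i] += dt * ((V[i] - Vq) ** 2 / dVq + mu[i] - theta) / tau
        for i in range(N):
            if ref[i] == 0 and V[i] >= V_peak:
                sp_t.append(step)
                sp_i.append(i)
                V[i] = V_reset
                ref[i] = r_steps
                tgt_slot = (step + d_steps) % (d_steps + 1)
                for k in range(out_indptr[i], out_indptr[i + 1]):
                    pend[tgt_slot, out_targets[k]] += out_weights[k]
    return np.array(sp_t, dtype=np.int64), np.array(sp_i, dtype=np.int64)


def grid_raster(spike_steps, spike_ids, dt):
    """Spike times in ms from grid output."""
    return spike_steps * dt, spike_ids
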