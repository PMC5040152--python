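"""Numerically exact event-driven simulation of the delta-synapse LIF network.

The network is a hybrid dynamical system: between synaptic deliveries every
membrane potential follows the closed-form leaky-integrator solution
V(t0+dt) = mu + (V0 - mu) e^(-dt/tau_m); a spike of presynaptic neuron j at
time t makes V of each of its targets jump by w at t + delta.  A neuron
fires when V reaches theta, resets to V_r and is clamped for the absolute
refractory period tau_rp; deliveries that arrive while a neuron is
refractory are discarded (they have no effect — this semantic choice is the
mechanism behind the delay-dependence of the strong-coupling regime, so it
is implemented literally).

The simulation is event-driven and exact to floating point: predicted
threshold crossings are kept in an indexed binary min-heap keyed by
(time, neuron id), and spike deliveries in a FIFO ring buffer (all synapses
share one delay, so deliveries are generated already time-ordered).

Events carrying the exact same timestamp need a defined semantics; this
matters only when the delay is zero (or shorter than the refractory
period), where a spike's deliveries land at the instant of the spike and
can trigger further crossings at the same instant.  The default is the
synchronous-batch rule — the dt -> 0 limit of a time-stepped integration:

* all deliveries carrying the current timestamp are applied (summed, FIFO
  order) before any triggered crossing fires;
* then all neurons at or above threshold fire together (recorded in
  ascending id order); their deliveries form the next same-time batch;
* repeat until the timestamp is exhausted.

This keeps the net sign of simultaneous recurrent input intact.  Two serial
tie orderings ("resets-first": crossings before equal-time deliveries;
"deliveries-first": the reverse) are available for comparison; under
"resets-first" a same-instant excitatory cascade outruns its own
inhibition, which at zero delay collapses the strong-coupling network into
a fully synchronized locked state.

A quadratic integrate-and-fire (QIF) variant shares the event semantics but
advances the subthreshold flow tau dV/dt = (V-V_q)^2/dV_q + mu - theta by
its closed-form (tangent-type) solution, spiking at V_peak with reset to
V_reset.
"""

from __future__ import annotations

import dataclasses
import math

import h5py
import numpy as np
from numba import njit

from .params import ModelParams, QIFParams
from .topology import NetworkTopology

__all__ = [
    "SpikeRaster",
    "VoltageTrace",
    "DivergenceError",
    "lif_free_evolution",
    "next_threshold_crossing",
    "evolve_lif",
    "evolve_qif",
    "initial_voltages",
    "stationary_voltages",
]

_INF = np.inf
_DQ_CAP = 1 << 20  # pending-delivery ring buffer capacity (spikes in flight)


class DivergenceError(RuntimeError):
    """Raised when the event queue overflows (rate blow-up); names the time reached."""


@dataclasses.dataclass
class SpikeRaster:
    """Ordered spike events from a spiking (or Poisson-sampled) simulation."""

    times: np.ndarray   # ms, non-decreasing
    ids: np.ndarray     # int32 in [0, N)
    duration: float     # ms
    N: int
    t_start: float = 0.0
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def rate_hz(self) -> float:
        """Population-averaged firing rate in Hz."""
        span = self.duration - self.t_start
        return self.n_spikes / self.N / span * 1000.0

    def spike_counts(self) -> np.ndarray:
        return np.bincount(self.ids, minlength=self.N)

    def spikes_of(self, i: int) -> np.ndarray:
        return self.times[self.ids == i]

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        k = np.searchsorted(self.times, [t0, t1])
        return SpikeRaster(
            self.times[k[0]:k[1]], self.ids[k[0]:k[1]], t1, self.N, t0, dict(self.provenance)
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("ids", data=self.ids)
            f.attrs["duration"] = self.duration
            f.attrs["t_start"] = self.t_start
            f.attrs["N"] = self.N
            for k, v in self.provenance.items():
                f.attrs[f"prov_{k}"] = v

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as f:
            prov = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("prov_")}
            return cls(
                f["times"][:], f["ids"][:], float(f.attrs["duration"]),
                int(f.attrs["N"]), float(f.attrs["t_start"]), prov,
            )


@dataclasses.dataclass
class VoltageTrace:
    """Uniformly sampled membrane potentials of selected neurons."""

    ids: np.ndarray       # (M,)
    times: np.ndarray     # (T,) ms
    V: np.ndarray         # (T, M) mV
    refractory: np.ndarray  # (T, M) bool, sample taken inside refractory window


def lif_free_evolution(V0, mu, dt, tau_m):
    """Closed-form inter-event propagation: mu + (V0 - mu) exp(-dt/tau_m)."""
    return mu + (V0 - mu) * np.exp(-np.asarray(dt, float) / tau_m)


def next_threshold_crossing(V0, mu, theta, tau_m):
    """Time for the free LIF to reach theta from V0 (< theta), or None.

    Crossing requires suprathreshold drive mu > theta; otherwise V relaxes
    toward mu without ever reaching threshold.
    """
    if V0 >= theta:
        raise ValueError("V0 must be below threshold")
    if mu <= theta:
        return None
    return tau_m * math.log((mu - V0) / (mu - theta))


# ----------------------------------------------------------------------------
# indexed min-heap over neurons keyed by (t_pred, id)
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hless(t1, i1, t2, i2):
    return t1 < t2 or (t1 == t2 and i1 < i2)


@njit(cache=True)
def _sift_up(heap, pos, tp, k):
    i = heap[k]
    ti = tp[i]
    while k > 0:
        p = (k - 1) >> 1
        j = heap[p]
        if _hless(ti, i, tp[j], j):
            heap[k] = j
            pos[j] = k
            k = p
        else:
            break
    heap[k] = i
    pos[i] = k


@njit(cache=True)
def _sift_down(heap, pos, tp, k, n):
    i = heap[k]
    ti = tp[i]
    while True:
        c = 2 * k + 1
        if c >= n:
            break
        j = heap[c]
        if c + 1 < n:
            j2 = heap[c + 1]
            if _hless(tp[j2], j2, tp[j], j):
                c += 1
                j = j2
        if _hless(tp[j], j, ti, i):
            heap[k] = j
            pos[j] = k
            k = c
        else:
            break
    heap[k] = i
    pos[i] = k


@njit(cache=True, inline="always")
def _heap_update(heap, pos, tp, i, n):
    k = pos[i]
    _sift_up(heap, pos, tp, k)
    if pos[i] == k:
        _sift_down(heap, pos, tp, k, n)


@njit(cache=True)
def _heapify(heap, pos, tp, n):
    for i in range(n):
        heap[i] = i
        pos[i] = i
    for k in range(n // 2 - 1, -1, -1):
        _sift_down(heap, pos, tp, k, n)


# ----------------------------------------------------------------------------
# LIF kernel
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _lif_pred(V, t, mu, theta, tau):
    """Absolute predicted crossing time for a free LIF at (V, t)."""
    if mu > theta and V < theta:
        return t + tau * math.log((mu - V) / (mu - theta))
    if V >= theta:
        return t
    return _INF


@njit(cache=True)
def _run_lif(out_indptr, out_targets, out_weights,
             V, tlast, ref_until, mu, tp, heap, pos,
             dq_t, dq_j, dq_head, dq_tail,
             t_end, tau, theta, Vr, trp, delta, ref_mode, order_mode,
             sp_t, sp_i, rec_ids, rec_t0, rec_dt, rec_idx, rec_V, rec_ref):
    """Advance the network to t_end.  Returns
    (status, t_reached, n_spikes, dq_head, dq_tail, rec_idx); status 0 = done,
    1 = spike buffer full (resumable), 2 = delivery queue overflow."""
    N = V.size
    cap = sp_t.size
    n_sp = 0
    n_rec = rec_ids.size
    rec_cap = rec_V.shape[0]
    mask = _DQ_CAP - 1
    dirty = np.empty(N, dtype=np.int64)
    is_dirty = np.zeros(N, dtype=np.bool_)
    n_dirty = 0
    t_guard = -1.0
    n_at_t = 0
    guard = 3 * N + 100
    while True:
        i_cr = heap[0]
        t_cr = tp[i_cr]
        if dq_head < dq_tail:
            t_del = dq_t[dq_head & mask]
        else:
            t_del = _INF
        cross_now = t_cr < t_del or (t_cr == t_del and order_mode == 0)
        t_next = t_cr if cross_now else t_del

        # voltage samples strictly up to the next event (pre-event values)
        if n_rec > 0:
            lim = t_next if t_next < t_end else t_end
            while rec_idx < rec_cap:
                ts = rec_t0 + rec_idx * rec_dt
                if ts > lim:
                    break
                for m in range(n_rec):
                    i = rec_ids[m]
                    if ts < ref_until[i]:
                        rec_V[rec_idx, m] = Vr
                        rec_ref[rec_idx, m] = True
                    else:
                        dt = ts - tlast[i]
                        rec_V[rec_idx, m] = mu[i] + (V[i] - mu[i]) * math.exp(-dt / tau)
                        rec_ref[rec_idx, m] = False
                rec_idx += 1

        if t_next > t_end:
            return 0, t_end, n_sp, dq_head, dq_tail, rec_idx

        if order_mode == 2:
            # synchronous-batch semantics: all deliveries at this timestamp are
            # summed before any triggered crossing fires; all crossers of a
            # generation fire together, their deliveries form the next
            # generation (the dt->0 limit of a time-stepped integration).
            t = t_next
            while True:
                applied = False
                while dq_head < dq_tail and dq_t[dq_head & mask] == t:
                    j = dq_j[dq_head & mask]
                    dq_head += 1
                    applied = True
                    for k in range(out_indptr[j], out_indptr[j + 1]):
                        i = out_targets[k]
                        if t < ref_until[i]:
                            if ref_mode == 0:
                                continue
                            V[i] += out_weights[k]
                        else:
                            dt = t - tlast[i]
                            V[i] = mu[i] + (V[i] - mu[i]) * math.exp(-dt / tau) \
                                + out_weights[k]
                            tlast[i] = t
                        if not is_dirty[i]:
                            is_dirty[i] = True
                            dirty[n_dirty] = i
                            n_dirty += 1
                for d in range(n_dirty):
                    i = dirty[d]
                    is_dirty[i] = False
                    tp[i] = _lif_pred(V[i], tlast[i], mu[i], theta, tau)
                    _heap_update(heap, pos, tp, i, N)
                n_dirty = 0
                fired = False
                while tp[heap[0]] <= t:
                    if n_sp >= cap:
                        return 1, t, n_sp, dq_head, dq_tail, rec_idx
                    if dq_tail - dq_head >= _DQ_CAP:
                        return 2, t, n_sp, dq_head, dq_tail, rec_idx
                    if t == t_guard:
                        n_at_t += 1
                        if n_at_t > guard:
                            return 2, t, n_sp, dq_head, dq_tail, rec_idx
                    else:
                        t_guard = t
                        n_at_t = 1
                    i = heap[0]
                    sp_t[n_sp] = t
                    sp_i[n_sp] = i
                    n_sp += 1
                    dq_t[dq_tail & mask] = t + delta
                    dq_j[dq_tail & mask] = i
                    dq_tail += 1
                    V[i] = Vr
                    tlast[i] = t + trp
                    ref_until[i] = t + trp
                    tp[i] = _lif_pred(Vr, t + trp, mu[i], theta, tau)
                    _heap_update(heap, pos, tp, i, N)
                    fired = True
                if not applied and not fired:
                    break
        elif cross_now:
            # threshold crossing of neuron i_cr at t_cr
            if n_sp >= cap:
                return 1, t_cr, n_sp, dq_head, dq_tail, rec_idx
            if dq_tail - dq_head >= _DQ_CAP:
                return 2, t_cr, n_sp, dq_head, dq_tail, rec_idx
            if t_cr == t_guard:
                n_at_t += 1
                if n_at_t > guard:
                    return 2, t_cr, n_sp, dq_head, dq_tail, rec_idx
            else:
                t_guard = t_cr
                n_at_t = 1
            i = i_cr
            sp_t[n_sp] = t_cr
            sp_i[n_sp] = i
            n_sp += 1
            dq_t[dq_tail & mask] = t_cr + delta
            dq_j[dq_tail & mask] = i
            dq_tail += 1
            V[i] = Vr
            tlast[i] = t_cr + trp
            ref_until[i] = t_cr + trp
            tp[i] = _lif_pred(Vr, t_cr + trp, mu[i], theta, tau)
            _heap_update(heap, pos, tp, i, N)
        else:
            j = dq_j[dq_head & mask]
            t = t_del
            dq_head += 1
            for k in range(out_indptr[j], out_indptr[j + 1]):
                i = out_targets[k]
                if t < ref_until[i]:
                    if ref_mode == 0:
                        continue  # delivery discarded
                    # accumulate onto the clamped voltage; takes effect at
                    # the end of the refractory period (tlast == ref_until)
                    V[i] += out_weights[k]
                    tp[i] = _lif_pred(V[i], ref_until[i], mu[i], theta, tau)
                    _heap_update(heap, pos, tp, i, N)
                    continue
                dt = t - tlast[i]
                Vi = mu[i] + (V[i] - mu[i]) * math.exp(-dt / tau)
                Vi += out_weights[k]
                V[i] = Vi
                tlast[i] = t
                tp[i] = _lif_pred(Vi, t, mu[i], theta, tau)
                _heap_update(heap, pos, tp, i, N)


# ----------------------------------------------------------------------------
# QIF closed forms and kernel
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _qif_flow_consts(mu, theta, Vq, dVq, tau):
    """alpha (1/(mV ms)) and drive d (mV/ms) of dV/dt = alpha (V-Vq)^2 + d."""
    return 1.0 / (tau * dVq), (mu - theta) / tau


@njit(cache=True)
def _qif_advance(x0, dt, alpha, d):
    """x(t0+dt) for dx/dt = alpha x^2 + d, x = V - Vq (finite for valid dt)."""
    if dt <= 0.0:
        return x0
    if d > 0.0:
        w = math.sqrt(alpha * d)
        L = math.sqrt(d / alpha)
        return L * math.tan(w * dt + math.atan(x0 / L))
    elif d < 0.0:
        k = math.sqrt(-d / alpha)
        if abs(x0 + k) < 1e-300:
            return x0
        r = (x0 - k) / (x0 + k) * math.exp(2.0 * k * alpha * dt)
        if abs(1.0 - r) < 1e-300:
            return 1e300
        return k * (1.0 + r) / (1.0 - r)
    else:
        den = 1.0 - x0 * alpha * dt
        if den <= 0.0:
            return 1e300
        return x0 / den


@njit(cache=True)
def _qif_crossing_dt(x0, xp, alpha, d):
    """Time for dx/dt = alpha x^2 + d to go from x0 (< xp) to xp, or inf."""
    if x0 >= xp:
        return 0.0
    if d > 0.0:
        w = math.sqrt(alpha * d)
        L = math.sqrt(d / alpha)
        return (math.atan(xp / L) - math.atan(x0 / L)) / w
    elif d < 0.0:
        k = math.sqrt(-d / alpha)
        if x0 <= k:
            return _INF
        r0 = (x0 - k) / (x0 + k)
        rp = (xp - k) / (xp + k)
        return math.log(rp / r0) / (2.0 * k * alpha)
    else:
        if x0 <= 0.0:
            return _INF
        return (1.0 / x0 - 1.0 / xp) / alpha


@njit(cache=True, inline="always")
def _qif_pred(V, t, mu, theta, Vq, dVq, Vpk, tau):
    alpha, d = _qif_flow_consts(mu, theta, Vq, dVq, tau)
    if V >= Vpk:
        return t
    dt = _qif_crossing_dt(V - Vq, Vpk - Vq, alpha, d)
    return t + dt


@njit(cache=True)
def _run_qif(out_indptr, out_targets, out_weights,
             V, tlast, ref_until, mu, tp, heap, pos,
             dq_t, dq_j, dq_head, dq_tail,
             t_end, tau, theta, Vq, dVq, Vpk, Vrst, trp, delta, ref_mode, order_mode,
             sp_t, sp_i, rec_ids, rec_t0, rec_dt, rec_idx, rec_V, rec_ref):
    N = V.size
    cap = sp_t.size
    n_sp = 0
    n_rec = rec_ids.size
    rec_cap = rec_V.shape[0]
    mask = _DQ_CAP - 1
    dirty = np.empty(N, dtype=np.int64)
    is_dirty = np.zeros(N, dtype=np.bool_)
    n_dirty = 0
    t_guard = -1.0
    n_at_t = 0
    guard = 3 * N + 100
    while True:
        i_cr = heap[0]
        t_cr = tp[i_cr]
        if dq_head < dq_tail:
            t_del = dq_t[dq_head & mask]
        else:
            t_del = _INF
        cross_now = t_cr < t_del or (t_cr == t_del and order_mode == 0)
        t_next = t_cr if cross_now else t_del

        if n_rec > 0:
            lim = t_next if t_next < t_end else t_end
            while rec_idx < rec_cap:
                ts = rec_t0 + rec_idx * rec_dt
                if ts > lim:
                    break
                for m in range(n_rec):
                    i = rec_ids[m]
                    if ts < ref_until[i]:
                        rec_V[rec_idx, m] = Vrst
                        rec_ref[rec_idx, m] = True
                    else:
                        alpha, d = _qif_flow_consts(mu[i], theta, Vq, dVq, tau)
                        rec_V[rec_idx, m] = Vq + _qif_advance(
                            V[i] - Vq, ts - tlast[i], alpha, d
                        )
                        rec_ref[rec_idx, m] = False
                rec_idx += 1

        if t_next > t_end:
            return 0, t_end, n_sp, dq_head, dq_tail, rec_idx

        if order_mode == 2:
            # synchronous-batch semantics (see the LIF kernel)
            t = t_next
            while True:
                applied = False
                while dq_head < dq_tail and dq_t[dq_head & mask] == t:
                    j = dq_j[dq_head & mask]
                    dq_head += 1
                    applied = True
                    for k in range(out_indptr[j], out_indptr[j + 1]):
                        i = out_targets[k]
                        if t < ref_until[i]:
                            if ref_mode == 0:
                                continue
                            V[i] += out_weights[k]
                        else:
                            alpha, d = _qif_flow_consts(mu[i], theta, Vq, dVq, tau)
                            V[i] = Vq + _qif_advance(V[i] - Vq, t - tlast[i], alpha, d) \
                                + out_weights[k]
                            tlast[i] = t
                        if not is_dirty[i]:
                            is_dirty[i] = True
                            dirty[n_dirty] = i
                            n_dirty += 1
                for dd in range(n_dirty):
                    i = dirty[dd]
                    is_dirty[i] = False
                    tp[i] = _qif_pred(V[i], tlast[i], mu[i], theta, Vq, dVq, Vpk, tau)
                    _heap_update(heap, pos, tp, i, N)
                n_dirty = 0
                fired = False
                while tp[heap[0]] <= t:
                    if n_sp >= cap:
                        return 1, t, n_sp, dq_head, dq_tail, rec_idx
                    if dq_tail - dq_head >= _DQ_CAP:
                        return 2, t, n_sp, dq_head, dq_tail, rec_idx
                    if t == t_guard:
                        n_at_t += 1
                        if n_at_t > guard:
                            return 2, t, n_sp, dq_head, dq_tail, rec_idx
                    else:
                        t_guard = t
                        n_at_t = 1
                    i = heap[0]
                    sp_t[n_sp] = t
                    sp_i[n_sp] = i
                    n_sp += 1
                    dq_t[dq_tail & mask] = t + delta
                    dq_j[dq_tail & mask] = i
                    dq_tail += 1
                    V[i] = Vrst
                    tlast[i] = t + trp
                    ref_until[i] = t + trp
                    tp[i] = _qif_pred(Vrst, t + trp, mu[i], theta, Vq, dVq, Vpk, tau)
                    _heap_update(heap, pos, tp, i, N)
                    fired = True
                if not applied and not fired:
                    break
        elif cross_now:
            if n_sp >= cap:
                return 1, t_cr, n_sp, dq_head, dq_tail, rec_idx
            if dq_tail - dq_head >= _DQ_CAP:
                return 2, t_cr, n_sp, dq_head, dq_tail, rec_idx
            if t_cr == t_guard:
                n_at_t += 1
                if n_at_t > guard:
                    return 2, t_cr, n_sp, dq_head, dq_tail, rec_idx
            else:
                t_guard = t_cr
                n_at_t = 1
            i = i_cr
            sp_t[n_sp] = t_cr
            sp_i[n_sp] = i
            n_sp += 1
            dq_t[dq_tail & mask] = t_cr + delta
            dq_j[dq_tail & mask] = i
            dq_tail += 1
            V[i] = Vrst
            tlast[i] = t_cr + trp
            ref_until[i] = t_cr + trp
            tp[i] = _qif_pred(Vrst, t_cr + trp, mu[i], theta, Vq, dVq, Vpk, tau)
            _heap_update(heap, pos, tp, i, N)
        else:
            j = dq_j[dq_head & mask]
            t = t_del
            dq_head += 1
            for k in range(out_indptr[j], out_indptr[j + 1]):
                i = out_targets[k]
                if t < ref_until[i]:
                    if ref_mode == 0:
                        continue
                    V[i] += out_weights[k]
                    tp[i] = _qif_pred(V[i], ref_until[i], mu[i], theta, Vq, dVq,
                                      Vpk, tau)
                    _heap_update(heap, pos, tp, i, N)
                    continue
                alpha, d = _qif_flow_consts(mu[i], theta, Vq, dVq, tau)
                Vi = Vq + _qif_advance(V[i] - Vq, t - tlast[i], alpha, d)
                Vi += out_weights[k]
                V[i] = Vi
                tlast[i] = t
                tp[i] = _qif_pred(Vi, t, mu[i], theta, Vq, dVq, Vpk, tau)
                _heap_update(heap, pos, tp, i, N)


@njit(cache=True)
def _lif_all_preds(V, tlast, ref_until, mu, tp, theta, tau):
    for i in range(V.size):
        t0 = max(tlast[i], ref_until[i])
        tp[i] = _lif_pred(V[i], t0, mu[i], theta, tau)


@njit(cache=True)
def _qif_all_preds(V, tlast, ref_until, mu, tp, theta, Vq, dVq, Vpk, tau):
    for i in range(V.size):
        t0 = max(tlast[i], ref_until[i])
        tp[i] = _qif_pred(V[i], t0, mu[i], theta, Vq, dVq, Vpk, tau)


# ----------------------------------------------------------------------------
# Python-level engine state and drivers
# ----------------------------------------------------------------------------

class EngineState:
    """Persistent engine state, so simulations can run in segments (used by
    the perturbation protocol: continue, fork, or change the feed-forward
    drive between segments)."""

    def __init__(self, topology: NetworkTopology, params: ModelParams,
                 init_V: np.ndarray, model: str = "lif",
                 qif_params: QIFParams | None = None,
                 refractory_deliveries: str = "discard",
                 tie_break: str = "batched"):
        N = topology.N
        init_V = np.asarray(init_V, dtype=np.float64)
        if init_V.shape != (N,):
            raise ValueError("init_V must have shape (N,)")
        self.topology = topology
        self.params = params
        self.model = model
        self.qif = qif_params or QIFParams()
        if refractory_deliveries not in ("discard", "accumulate"):
            raise ValueError("refractory_deliveries must be 'discard' or 'accumulate'")
        self.refractory_deliveries = refractory_deliveries
        if tie_break not in ("resets-first", "deliveries-first", "batched"):
            raise ValueError(
                "tie_break must be 'resets-first', 'deliveries-first' or 'batched'"
            )
        self.tie_break = tie_break
        if model == "lif" and np.any(init_V >= params.theta):
            raise ValueError("initial voltages must lie below threshold")
        self.out_indptr, self.out_targets, self.out_weights = topology.to_outgoing_csr()
        self.V = init_V.copy()
        self.t = 0.0
        self.tlast = np.zeros(N)
        self.ref_until = np.full(N, -np.inf)
        self.mu = np.full(N, params.mu0, dtype=np.float64)
        self.tp = np.empty(N)
        self.heap = np.empty(N, dtype=np.int64)
        self.pos = np.empty(N, dtype=np.int64)
        self.dq_t = np.empty(_DQ_CAP)
        self.dq_j = np.empty(_DQ_CAP, dtype=np.int32)
        self.dq_head = 0
        self.dq_tail = 0
        self.refresh_predictions()

    def copy(self) -> "EngineState":
        new = object.__new__(EngineState)
        new.topology, new.params, new.model, new.qif = (
            self.topology, self.params, self.model, self.qif
        )
        new.refractory_deliveries = self.refractory_deliveries
        new.tie_break = self.tie_break
        new.out_indptr, new.out_targets, new.out_weights = (
            self.out_indptr, self.out_targets, self.out_weights
        )
        for name in ("V", "tlast", "ref_until", "mu", "tp", "heap", "pos", "dq_t", "dq_j"):
            setattr(new, name, getattr(self, name).copy())
        new.t = self.t
        new.dq_head = self.dq_head
        new.dq_tail = self.dq_tail
        return new

    def set_drive(self, mu: np.ndarray | float) -> None:
        """Change the per-neuron feed-forward input; re-predicts crossings."""
        self.mu[:] = mu
        self.refresh_predictions()

    def refresh_predictions(self) -> None:
        p, q = self.params, self.qif
        if self.model == "lif":
            _lif_all_preds(self.V, self.tlast, self.ref_until, self.mu, self.tp,
                           p.theta, p.tau_m)
        else:
            _qif_all_preds(self.V, self.tlast, self.ref_until, self.mu, self.tp,
                           p.theta, q.V_q, q.dV_q, q.V_peak, p.tau_m)
        _heapify(self.heap, self.pos, self.tp, self.topology.N)

    def run(self, duration: float, record_ids=None, record_dt: float = 1.0,
            spike_buffer: int = 1 << 22):
        """Advance by ``duration`` ms; returns (SpikeRaster, VoltageTrace|None)."""
        p, q = self.params, self.qif
        t_end = self.t + duration
        rec_ids = (np.asarray(record_ids, dtype=np.int64)
                   if record_ids is not None else np.empty(0, dtype=np.int64))
        if rec_ids.size:
            rec_t0 = self.t
            rec_cap = int(math.floor(duration / record_dt)) + 1
        else:
            rec_t0, rec_cap = 0.0, 0
        rec_V = np.empty((rec_cap, rec_ids.size))
        rec_ref = np.zeros((rec_cap, rec_ids.size), dtype=np.bool_)
        rec_idx = 0
        sp_t = np.empty(spike_buffer)
        sp_i = np.empty(spike_buffer, dtype=np.int32)
        all_t, all_i = [], []
        while True:
            args_common = (
                self.out_indptr, self.out_targets, self.out_weights,
                self.V, self.tlast, self.ref_until, self.mu,
                self.tp, self.heap, self.pos,
                self.dq_t, self.dq_j, self.dq_head, self.dq_tail, t_end,
            )
            ref_mode = 0 if self.refractory_deliveries == "discard" else 1
            order_mode = {"resets-first": 0, "deliveries-first": 1, "batched": 2}[
                self.tie_break
            ]
            if self.model == "lif":
                status, t_reached, n_sp, self.dq_head, self.dq_tail, rec_idx = _run_lif(
                    *args_common, p.tau_m, p.theta, p.V_r, p.tau_rp, p.delta, ref_mode, order_mode,
                    sp_t, sp_i, rec_ids, rec_t0, record_dt, rec_idx, rec_V, rec_ref,
                )
            else:
                status, t_reached, n_sp, self.dq_head, self.dq_tail, rec_idx = _run_qif(
                    *args_common, p.tau_m, p.theta, q.V_q, q.dV_q,
                    q.V_peak, q.V_reset, p.tau_rp, p.delta, ref_mode, order_mode,
                    sp_t, sp_i, rec_ids, rec_t0, record_dt, rec_idx, rec_V, rec_ref,
                )
            all_t.append(sp_t[:n_sp].copy())
            all_i.append(sp_i[:n_sp].copy())
            if status == 2:
                raise DivergenceError(
                    f"delivery queue overflow at t={t_reached:.3f} ms (rate blow-up)"
                )
            if status == 0:
                break
        t_start = self.t
        self.t = t_end
        times = np.concatenate(all_t) if all_t else np.empty(0)
        ids = np.concatenate(all_i) if all_i else np.empty(0, np.int32)
        raster = SpikeRaster(times, ids, t_end, self.topology.N, t_start,
                             {"engine": self.model})
        trace = None
        if rec_ids.size:
            times_grid = rec_t0 + record_dt * np.arange(rec_idx)
            trace = VoltageTrace(rec_ids, times_grid, rec_V[:rec_idx], rec_ref[:rec_idx])
        return raster, trace


@njit(cache=True)
def _ou_reset_sample(mu, sigma, theta, Vr, trp, tau, n, seed, burn_ms, space_ms):
    """Sample voltages from the stationary density of a single LIF driven by
    white noise (Euler-Maruyama, dt = 0.01 ms), skipping refractory instants."""
    np.random.seed(seed)
    dt = 0.01
    sq = sigma * math.sqrt(dt / tau)
    V = Vr
    t_ref = 0.0
    out = np.empty(n)
    k = 0
    t = 0.0
    next_s = burn_ms
    while k < n:
        if t_ref > 0.0:
            t_ref -= dt
        else:
            V += dt * (mu - V) / tau + sq * np.random.normal()
            if V >= theta:
                V = Vr
                t_ref = trp
        t += dt
        if t >= next_s:
            if t_ref <= 0.0 and V < theta:
                out[k] = V
                k += 1
            next_s = t + space_ms
    return out


def stationary_voltages(params: ModelParams, seed: int, mu: float | None = None,
                        sigma: float | None = None) -> np.ndarray:
    """Initial voltages drawn i.i.d. from the stationary membrane-potential
    distribution of the mean-field theory at the self-consistent rate.

    A uniform draw on [V_r, theta) puts every neuron simultaneously on a
    coherent upward sweep and ignites a giant population volley at t=0+,
    which can drop the network into a synchronized attractor (an artifact
    of the initial condition, most severe for delays shorter than the
    refractory period).  Sampling from the stationary single-neuron density
    of the asynchronous state avoids that transient.
    """
    if mu is None or sigma is None:
        from .meanfield import solve_selfconsistent

        sol = solve_selfconsistent(params)
        mu = sol.mu if mu is None else mu
        sigma = sol.sigma if sigma is None else sigma
    if sigma < 1e-9:
        return initial_voltages(params, seed)
    return _ou_reset_sample(mu, sigma, params.theta, params.V_r, params.tau_rp,
                            params.tau_m, params.N, seed % (2**31 - 1), 500.0, 37.0)


def initial_voltages(params: ModelParams, seed: int, low=None, high=None) -> np.ndarray:
    """Uniform initial voltages on [V_r, theta) with a dedicated seed."""
    rng = np.random.default_rng(seed)
    lo = params.V_r if low is None else low
    hi = params.theta if high is None else high
    return lo + (hi - lo) * rng.random(params.N) * (1.0 - 1e-12)


def evolve_lif(topology: NetworkTopology, params: ModelParams, init_V, duration: float,
               record_ids=None, record_dt: float = 1.0,
               refractory_deliveries: str = "discard"):
    """Run the LIF network from t=0 for ``duration`` ms.

    Deterministic given (topology, params, init_V).  Returns
    (SpikeRaster, VoltageTrace or None).
    """
    state = EngineState(topology, params, np.asarray(init_V, float), model="lif",
                        refractory_deliveries=refractory_deliveries)
    raster, trace = state.run(duration, record_ids, record_dt)
    raster.provenance.update({"J": params.J, "delta": params.delta, "seed": params.seed})
    return raster, trace


def evolve_qif(topology: NetworkTopology, params: ModelParams, init_V, duration: float,
               qif_params: QIFParams | None = None, record_ids=None, record_dt: float = 1.0,
               refractory_deliveries: str = "discard"):
    """Run the QIF variant (same event semantics, quadratic subthreshold flow)."""
    state = EngineState(topology, params, np.asarray(init_V, float), model="qif",
                        qif_params=qif_params,
                        refractory_deliveries=refractory_deliveries)
    raster, trace = state.run(duration, record_ids, record_dt)
    raster.provenance.update({"J": params.J, "delta": params.delta, "seed": params.seed,
                              "model": "qif"})
    return raster, trace
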