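import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratechaos.lif import (EngineState, evolve_lif, evolve_qif, initial_voltages,
                           lif_free_evolution, next_threshold_crossing,
                           stationary_voltages)
from ratechaos.params import ModelParams, QIFParams
from ratechaos.topology import NetworkTopology, build_topology

from reference import lif_grid_sim, qif_grid_sim


def _grid_times(topology, params, V0, duration, dt=1e-4):
    """Spike times/ids from the independent fixed-step reference."""
    oi, ot, ow = topology.to_outgoing_csr()
    mu = np.full(topology.N, params.mu0)
    steps, ids = lif_grid_sim(oi, ot, ow, V0, mu, duration, dt, params.tau_m,
                              params.theta, params.V_r, params.tau_rp, params.delta)
    return steps * dt, ids


# ---------------------------------------------------------------- closed forms

def test_free_evolution_fixed_point_and_identity():
    assert lif_free_evolution(10.0, 10.0, 57.3, 20.0) == 10.0
    assert lif_free_evolution(3.0, 24.0, 0.0, 20.0) == 3.0


def test_free_evolution_closed_form_matches_fine_euler():
    V0, mu, tau, dt = 0.0, 10.0, 20.0, 20.0
    exact = lif_free_evolution(V0, mu, dt, tau)
    assert math.isclose(exact, 10.0 * (1 - math.exp(-1.0)), rel_tol=1e-12)
    V, h = V0, 0.001
    for _ in range(int(dt / h)):
        V += h * (mu - V) / tau
    assert abs(V - exact) < 1e-3


@given(st.floats(-50, 19.9), st.floats(-10, 19.99))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_no_crossing_for_subthreshold_drive(V0, mu):
    assert next_threshold_crossing(V0, mu, 20.0, 20.0) is None


def test_crossing_time_closed_form():
    # deterministic oscillator: V_r -> theta under mu > theta
    p = ModelParams()
    t = next_threshold_crossing(p.V_r, p.mu0, p.theta, p.tau_m)
    assert math.isclose(t, p.tau_m * math.log((p.mu0 - p.V_r) / (p.mu0 - p.theta)),
                        rel_tol=1e-14)
    # crossing time vanishes for diverging drive
    assert next_threshold_crossing(10.0, 1e9, 20.0, 20.0) < 1e-6
    with pytest.raises(ValueError):
        next_threshold_crossing(21.0, 30.0, 20.0, 20.0)


# ---------------------------------------------------------- uncoupled networks

def test_uncoupled_isis_match_deterministic_period():
    p = ModelParams(N=30, C=0, J=0.0, seed=1)
    top = build_topology(p)
    V0 = initial_voltages(p, 2)
    raster, _ = evolve_lif(top, p, V0, 300.0)
    T = p.tau_rp + p.tau_m * math.log((p.mu0 - p.V_r) / (p.mu0 - p.theta))
    for i in range(p.N):
        isis = np.diff(raster.spikes_of(i))
        assert np.all(np.abs(isis - T) < 1e-9)
        n_expected = math.floor(300.0 / T)
        assert abs(raster.spikes_of(i).size - n_expected) <= 1


# ------------------------------------------------------------ oracle equivalence

@pytest.mark.parametrize("delta,J,dt", [(0.55, 0.5, 1e-4), (0.0, 0.5, 1e-4),
                                        (1.2, 2.0, 2e-5)])
def test_event_engine_matches_fixed_step_reference(delta, J, dt):
    """Spike-for-spike agreement with an independent fixed-step grid
    integrator on small networks over 200 ms (step 1e-4 ms; the
    strong-coupling case uses a finer step since its spike-time chains
    accumulate the grid quantization)."""
    p = ModelParams(N=20, C=8, f_E=0.8, J=J, g=5.0, delta=delta, seed=21)
    top = build_topology(p)
    V0 = initial_voltages(p, 22)
    raster, _ = evolve_lif(top, p, V0, 200.0)
    gt, gi = _grid_times(top, p, V0, 200.0, dt)
    assert raster.n_spikes == gt.size
    for i in range(p.N):
        te = raster.spikes_of(i)
        tg = gt[gi == i]
        assert te.size == tg.size
        if te.size:
            assert np.max(np.abs(te - tg)) < 1e-3


def test_two_neuron_mutual_inhibition_matches_reference():
    """Hand-built two-neuron inhibitory loop against the grid oracle."""
    p = ModelParams(N=2, C=1, f_E=0.5, J=0.0, delta=0.8, seed=0)
    indptr = np.array([0, 1, 2], dtype=np.int64)
    pre = np.array([1, 0], dtype=np.int32)
    w = np.array([-3.0, -3.0])
    top = NetworkTopology(2, indptr, pre, w, np.array([True, False]), p)
    V0 = np.array([12.0, 17.0])
    raster, _ = evolve_lif(top, p, V0, 500.0)
    gt, gi = _grid_times(top, p, V0, 500.0)
    assert raster.n_spikes == gt.size > 10
    assert np.max(np.abs(np.sort(raster.times) - np.sort(gt))) < 1e-3


# ----------------------------------------------------------- invariant checks

def test_determinism_bitwise():
    p = ModelParams(N=100, C=20, J=0.8, seed=5)
    top = build_topology(p)
    V0 = initial_voltages(p, 6)
    r1, _ = evolve_lif(top, p, V0, 500.0)
    r2, _ = evolve_lif(top, p, V0, 500.0)
    assert np.array_equal(r1.times, r2.times)
    assert np.array_equal(r1.ids, r2.ids)


def test_refractoriness_and_ordering_on_every_raster(reduced_params, reduced_topology):
    p = reduced_params
    raster, _ = evolve_lif(reduced_topology, p, initial_voltages(p, 7), 1000.0)
    assert np.all(np.diff(raster.times) >= 0)
    assert raster.ids.min() >= 0 and raster.ids.max() < p.N
    for i in range(0, p.N, 7):
        ts = raster.spikes_of(i)
        if ts.size >= 2:
            assert np.min(np.diff(ts)) >= p.tau_rp - 1e-12


def test_segmented_run_equals_single_run(reduced_params, reduced_topology):
    """Engine state persists exactly across run() segments (deliveries in
    flight included)."""
    p = reduced_params
    V0 = initial_voltages(p, 8)
    whole, _ = evolve_lif(reduced_topology, p, V0, 400.0)
    st = EngineState(reduced_topology, p, V0)
    parts = [st.run(130.0)[0], st.run(170.0)[0], st.run(100.0)[0]]
    times = np.concatenate([r.times for r in parts])
    ids = np.concatenate([r.ids for r in parts])
    assert np.array_equal(times, whole.times)
    assert np.array_equal(ids, whole.ids)


def test_voltage_recording_between_spikes(reduced_params, reduced_topology):
    p = reduced_params
    st = EngineState(reduced_topology, p, initial_voltages(p, 9))
    raster, trace = st.run(200.0, record_ids=[0, 5, 10], record_dt=0.5)
    assert trace.V.shape == (trace.times.size, 3)
    assert np.all(np.isfinite(trace.V))
    assert np.all(trace.V <= p.theta + 1e-9)
    # refractory samples are clamped at the reset potential
    assert np.all(trace.V[trace.refractory] == p.V_r)


def test_divergence_error_names_time():
    from ratechaos.lif import DivergenceError, _DQ_CAP

    # all-excitatory tight loop with huge kicks blows up immediately
    p = ModelParams(N=50, C=10, f_E=0.98, J=50.0, g=0.0, delta=0.0, tau_rp=0.0,
                    seed=1)
    top = build_topology(p)
    with pytest.raises(DivergenceError, match="t="):
        evolve_lif(top, p, initial_voltages(p, 2), 1000.0)


def test_stationary_voltages_deterministic_and_subthreshold():
    p = ModelParams(N=500, C=100, J=0.5, seed=3)
    a = stationary_voltages(p, 42)
    b = stationary_voltages(p, 42)
    assert np.array_equal(a, b)
    assert np.all(a < p.theta)
    assert a.std() > 1.0  # spread over the operating range


# ----------------------------------------------------------------- QIF variant

def test_qif_uncoupled_matches_reference():
    p = ModelParams(N=3, C=0, J=0.0, seed=1)
    top = build_topology(p)
    q = QIFParams()
    V0 = np.array([-100.0, 10.0, 60.0])
    raster, _ = evolve_qif(top, p, V0, 2500.0, qif_params=q)
    oi, ot, ow = top.to_outgoing_csr()
    steps, ids = qif_grid_sim(oi, ot, ow, V0, np.full(3, p.mu0), 2500.0, 1e-4,
                              p.tau_m, p.theta, q.V_q, q.dV_q, p.tau_rp, p.delta,
                              q.V_peak, q.V_reset)
    gt = steps * 1e-4
    assert raster.n_spikes == gt.size >= 3
    for i in range(3):
        te, tg = raster.spikes_of(i), gt[ids == i]
        assert te.size == tg.size
        if te.size:
            assert np.max(np.abs(te - tg)) < 2e-3


def test_qif_subthreshold_drive_at_stable_fixed_point_is_silent():
    q = QIFParams()
    p = ModelParams(N=2, C=0, J=0.0, mu0=10.0, seed=1)  # mu < rheobase theta
    top = build_topology(p)
    k = math.sqrt((p.theta - p.mu0) * q.dV_q)
    V0 = np.array([q.V_q - k, q.V_q - k - 30.0])  # at/below the stable point
    raster, _ = evolve_qif(top, p, V0, 500.0, qif_params=q)
    assert raster.n_spikes == 0


def test_qif_coupled_small_network_matches_reference():
    p = ModelParams(N=20, C=8, f_E=0.8, J=20.0, g=5.0, delta=0.55, seed=13)
    top = build_topology(p)
    q = QIFParams()
    V0 = initial_voltages(p, 14, low=-50.0, high=60.0)
    raster, _ = evolve_qif(top, p, V0, 1000.0, qif_params=q)
    oi, ot, ow = top.to_outgoing_csr()
    steps, ids = qif_grid_sim(oi, ot, ow, V0, np.full(p.N, p.mu0), 1000.0, 1e-4,
                              p.tau_m, p.theta, q.V_q, q.dV_q, p.tau_rp, p.delta,
                              q.V_peak, q.V_reset)
    gt = steps * 1e-4
    assert raster.n_spikes == gt.size
    for i in range(p.N):
        te, tg = raster.spikes_of(i), gt[ids == i]
        assert te.size == tg.size
        if te.size:
            assert np.max(np.abs(te - tg)) < 2e-3


def test_strong_coupling_voltage_tail_below_reset():
    """At strong coupling the LIF voltage distribution develops a long tail
    far below the reset potential (deep hyperpolarized excursions between
    bursts), the mechanism behind the super-Poissonian irregularity."""
    p = ModelParams(N=2000, C=200, J=0.8, g=5.0, delta=0.55, seed=31)
    top = build_topology(p)
    st = EngineState(top, p, stationary_voltages(p, 32))
    st.run(1000.0)
    _, trace = st.run(4000.0, record_ids=np.arange(0, p.N, 20), record_dt=1.0)
    V = trace.V[~trace.refractory]
    deep = p.V_r - 3 * (p.theta - p.V_r)  # 3 operating ranges below reset
    assert np.mean(V < deep) > 0.05
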