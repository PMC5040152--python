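import numpy as np
import pytest

from ratechaos.diagnostics import (CorrelationFunction, decorrelation_time,
                                   filtered_rate, isi_cv, phase_signals,
                                   rate_autocorrelation, scaling_fit,
                                   spike_autocorrelation, synchrony_chi,
                                   voltage_distribution)
from ratechaos.lif import SpikeRaster, VoltageTrace
from ratechaos.rate import RateTrajectory


def _raster(times, ids, duration, N, t0=0.0):
    order = np.argsort(times, kind="stable")
    return SpikeRaster(np.asarray(times, float)[order],
                       np.asarray(ids, np.int32)[order], duration, N, t0)


# ------------------------------------------------------- spike autocorrelation

def test_periodic_raster_ac_peaks_at_period_multiples():
    T, period = 20000.0, 25.0
    times = np.arange(0.5, T, period)
    r = _raster(times, np.zeros(times.size), T, 1)
    ac = spike_autocorrelation(r, n_sample=1, max_lag=120.0, seed=0)
    raw = ac.values * ac.raw_norm
    off_peak = [raw[k] for k in range(2, 120) if k % 25 not in (0, 24, 1)]
    for k in (25, 50, 75, 100):
        assert raw[k] > 10 * np.max(np.abs(off_peak))


def test_spike_ac_symmetrizable_and_normalized():
    rng = np.random.default_rng(0)
    times = np.sort(rng.uniform(0, 50000, 5000))
    r = _raster(times, rng.integers(0, 10, 5000), 50000.0, 10)
    ac = spike_autocorrelation(r, n_sample=10, max_lag=50.0, seed=1)
    assert ac.values[1] == 1.0  # declared normalization lag
    lags, vals = ac.symmetric()
    assert np.allclose(vals, vals[::-1])  # even in lag


def test_spike_ac_excludes_sparse_neurons():
    r = _raster([10.0, 20.0, 30.0, 500.0], [0, 0, 0, 1], 5000.0, 2)
    ac = spike_autocorrelation(r, n_sample=5, min_spikes=2, max_lag=50.0, seed=0)
    assert ac.n_excluded == 1


# --------------------------------------------------------------- filtered rate

def test_filtered_rate_conserves_spike_count_and_is_smooth():
    rng = np.random.default_rng(1)
    # keep spikes > 5 filter widths away from the edges: the unit-area
    # kernel then conserves the total count exactly
    times = np.sort(rng.uniform(600, 9400, 2000))
    r = _raster(times, rng.integers(0, 5, 2000), 10000.0, 5)
    traj = filtered_rate(r, filter_sd=10.0)
    got = traj.rates.sum() / 1000.0  # Hz*ms bins -> counts
    assert np.isclose(got, r.n_spikes, rtol=1e-9)
    assert np.all(traj.rates >= 0)


def test_empty_raster_filters_to_zero():
    r = _raster([], [], 1000.0, 3)
    traj = filtered_rate(r, filter_sd=10.0)
    assert np.allclose(traj.rates, 0.0)


def test_filter_width_confound_monotone():
    """Wider Gaussian filters produce longer apparent rate-correlation
    times on the same raster."""
    rng = np.random.default_rng(2)
    N, T = 40, 60000.0
    n = rng.poisson(10.0 / 1000.0 * T * N)
    r = _raster(rng.uniform(0, T, n), rng.integers(0, N, n), T, N)
    widths = []
    for sd in (10.0, 50.0, 100.0):
        traj = filtered_rate(r, filter_sd=sd)
        ac = rate_autocorrelation(traj, max_lag=800.0)
        t_dec, _ = decorrelation_time(ac)
        widths.append(t_dec)
    assert widths[0] < widths[1] < widths[2]


# --------------------------------------------------------- rate autocorrelation

def test_constant_trajectory_rejected():
    traj = RateTrajectory(np.full((500, 4), 3.0), np.arange(4), 1.0)
    with pytest.raises(ValueError):
        rate_autocorrelation(traj)


def test_white_noise_trajectory_delta_ac():
    rng = np.random.default_rng(3)
    traj = RateTrajectory(rng.standard_normal((20000, 20)) + 10.0, np.arange(20), 1.0)
    ac = rate_autocorrelation(traj, max_lag=30.0)
    assert ac.values[0] == 1.0
    assert np.all(np.abs(ac.values[1:]) < 0.05)


# -------------------------------------------------------------------- ISI CV

def test_cv_periodic_zero_poisson_one():
    times = np.arange(0.0, 200000.0, 40.0)
    r = _raster(times, np.zeros(times.size), 200000.0, 1)
    cvs, mean_cv = isi_cv(r, min_spikes=10)
    assert mean_cv < 1e-12

    rng = np.random.default_rng(4)
    isis = rng.exponential(200.0, size=1000)  # 5 Hz Poisson, 200 s
    times = np.cumsum(isis)
    r = _raster(times, np.zeros(times.size), float(times[-1] + 1), 1)
    _, mean_cv = isi_cv(r, min_spikes=10)
    assert abs(mean_cv - 1.0) < 4.0 / np.sqrt(1000)  # ~4 sigma


def test_cv_requires_enough_spikes():
    r = _raster([1.0, 2.0], [0, 0], 100.0, 1)
    with pytest.raises(ValueError):
        isi_cv(r, min_spikes=10)
    with pytest.raises(ValueError):
        isi_cv(r, min_spikes=2)


# ------------------------------------------------------------------ synchrony

def test_chi_identical_signals_is_one_and_independent_scales_as_sqrt_n():
    rng = np.random.default_rng(5)
    base = rng.standard_normal(2000)
    X = np.tile(base, (20, 1))
    assert np.isclose(synchrony_chi(X), 1.0)
    for N, bound in [(25, 0.35), (400, 0.09)]:
        X = rng.standard_normal((N, 4000))
        chi = synchrony_chi(X)
        assert chi < bound  # ~1/sqrt(N) with sampling slack


def test_phase_signals_interpolate_isi_fraction():
    r = _raster([0.0, 10.0, 30.0], [0, 0, 0], 40.0, 1)
    ph = phase_signals(r, dt=1.0)
    assert np.isclose(ph[0, 5], 0.5)          # halfway through first ISI
    assert np.isclose(ph[0, 20], 0.5)         # halfway through second ISI
    assert np.isnan(ph[0, 35])                # after the last spike


# ------------------------------------------------------- voltage distribution

def test_voltage_distribution_constant_and_refractory_exclusion():
    V = np.full((100, 2), -3.5)
    ref = np.zeros_like(V, dtype=bool)
    ref[:50, 0] = True
    trace = VoltageTrace(np.array([0, 1]), np.arange(100.0), V, ref)
    d = voltage_distribution(trace, bins=10, exclude_refractory=True)
    assert d.n_samples == 150
    assert np.isclose(d.masses.sum(), 1.0)
    assert np.isclose(d.mean, -3.5)
    assert d.var == 0.0


# ------------------------------------------------------- decorrelation time

def test_decorrelation_time_of_exact_exponential():
    lags = np.arange(0.0, 200.0)
    vals = np.exp(-lags / 20.0)
    ac = CorrelationFunction(lags, vals, "zero-lag", 1.0, 1)
    t_cross, t_fit = decorrelation_time(ac)
    assert abs(t_cross - 20.0) < 0.5
    assert abs(t_fit - 20.0) < 0.5


def test_decorrelation_time_none_when_no_decay():
    lags = np.arange(0.0, 50.0)
    ac = CorrelationFunction(lags, np.full(50, 0.9), "zero-lag", 1.0, 1)
    assert decorrelation_time(ac) == (None, None)


# ------------------------------------------------------------- scaling fits

def test_scaling_fit_recovers_constructed_exponents():
    J_c = 0.5
    J = J_c + np.array([0.02, 0.05, 0.1, 0.2, 0.4])
    amp = 3.0 * (J - J_c)
    tim = 7.0 * (J - J_c) ** -0.5
    fit = scaling_fit(J, J_c, amp, tim, n_boot=200, seed=0)
    assert abs(fit["amplitude_slope"] - 1.0) < 1e-9
    assert abs(fit["time_slope"] + 0.5) < 1e-9
    with pytest.raises(ValueError):
        scaling_fit(J[:3], J_c, amp[:3], tim[:3])
    with pytest.raises(ValueError):
        scaling_fit(J - 1.0, J_c, amp, tim)
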