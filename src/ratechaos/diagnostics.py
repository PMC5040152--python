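"""Summary statistics distinguishing the two dynamical regimes.

Spike and rate autocorrelations, Gaussian-filtered rate functions,
decorrelation times, interspike-interval CV, the synchrony measure chi,
membrane-potential distributions, and the near-critical scaling fits
(fluctuation amplitude ~ (J - J_c), decorrelation time ~ (J - J_c)^(-1/2)).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal, stats

from .lif import SpikeRaster, VoltageTrace
from .rate import RateTrajectory

__all__ = [
    "CorrelationFunction",
    "DistributionSummary",
    "binned_counts",
    "spike_autocorrelation",
    "filtered_rate",
    "rate_autocorrelation",
    "isi_cv",
    "synchrony_chi",
    "phase_signals",
    "voltage_distribution",
    "decorrelation_time",
    "scaling_fit",
]


@dataclasses.dataclass
class CorrelationFunction:
    """Averaged autocorrelation on a symmetric lag grid.

    ``normalization`` records the convention: "first-nonzero-lag" (spike ACs,
    where the zero-lag bin is dominated by the self-count delta) or "zero-lag"
    (rate ACs).  The stored values satisfy AC(lag) = AC(-lag); only lags >= 0
    are kept.
    """

    lags: np.ndarray          # ms, from 0
    values: np.ndarray        # normalized
    normalization: str
    raw_norm: float           # the (pre-normalization) value divided out
    n_averaged: int
    n_excluded: int = 0
    bin: float = 1.0

    def symmetric(self):
        lags = np.concatenate([-self.lags[:0:-1], self.lags])
        vals = np.concatenate([self.values[:0:-1], self.values])
        return lags, vals


@dataclasses.dataclass
class DistributionSummary:
    edges: np.ndarray
    masses: np.ndarray
    mean: float
    var: float
    skewness: float
    n_samples: int


def binned_counts(raster: SpikeRaster, bin: float = 1.0, ids=None):
    """(n_units, n_bins) spike-count matrix on a uniform grid."""
    t0, t1 = raster.t_start, raster.duration
    n_bins = int(np.floor((t1 - t0) / bin))
    if ids is None:
        ids = np.arange(raster.N)
    ids = np.asarray(ids)
    id_map = -np.ones(raster.N, dtype=np.int64)
    id_map[ids] = np.arange(ids.size)
    rows = id_map[raster.ids]
    cols = ((raster.times - t0) / bin).astype(np.int64)
    keep = (rows >= 0) & (cols >= 0) & (cols < n_bins)
    counts = np.zeros((ids.size, n_bins))
    np.add.at(counts, (rows[keep], cols[keep]), 1.0)
    return counts


def _mean_autocovariance(X: np.ndarray, max_lag_bins: int) -> np.ndarray:
    """Row-averaged autocovariance of X (rows = units, columns = time bins),
    stationary means removed, via FFT; lags 0..max_lag_bins."""
    T = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    F = np.fft.rfft(Xc, nfft, axis=1)
    ac = np.fft.irfft((F * F.conj()).real.mean(axis=0), nfft)[: max_lag_bins + 1]
    return ac / (T - np.arange(max_lag_bins + 1))


def spike_autocorrelation(raster: SpikeRaster, bin: float = 1.0,
                          max_lag: float = 200.0, n_sample: int = 3000,
                          seed: int = 0, min_spikes: int = 2) -> CorrelationFunction:
    """Population-averaged spike-train autocorrelation.

    Per sampled neuron, the autocovariance of its binned spike-count train
    (stationary mean removed), averaged over neurons, then normalized to the
    value at the first nonzero lag — the "second peak"; the zero-lag bin
    carries the self-count delta and is reported on the same scale.
    Neurons with fewer than ``min_spikes`` spikes are excluded and counted.
    """
    span = raster.duration - raster.t_start
    if span <= 2 * max_lag:
        raise ValueError("raster duration must exceed twice max_lag")
    counts_per = raster.spike_counts()
    eligible = np.flatnonzero(counts_per >= min_spikes)
    n_excluded = raster.N - eligible.size
    if eligible.size == 0:
        raise ValueError("no neuron has enough spikes")
    rng = np.random.default_rng(seed)
    if eligible.size > n_sample:
        eligible = rng.choice(eligible, size=n_sample, replace=False)
    X = binned_counts(raster, bin, ids=np.sort(eligible))
    L = int(round(max_lag / bin))
    ac = _mean_autocovariance(X, L)
    norm = ac[1]
    if norm == 0:
        raise ValueError("autocorrelation vanishes at the first nonzero lag")
    return CorrelationFunction(
        lags=bin * np.arange(L + 1), values=ac / norm,
        normalization="first-nonzero-lag", raw_norm=float(norm),
        n_averaged=int(eligible.size), n_excluded=int(n_excluded), bin=bin,
    )


def filtered_rate(raster: SpikeRaster, bin: float = 1.0, filter_sd: float = 50.0,
                  ids=None) -> RateTrajectory:
    """Per-neuron rate functions: binned spike counts convolved with a
    unit-area Gaussian kernel (truncated at +-5 sd), in Hz."""
    if filter_sd <= 0:
        raise ValueError("filter_sd must be positive")
    if ids is None:
        ids = np.arange(raster.N)
    ids = np.asarray(ids)
    X = binned_counts(raster, bin, ids=ids)
    half = int(np.ceil(5 * filter_sd / bin))
    t = np.arange(-half, half + 1) * bin
    kern = np.exp(-0.5 * (t / filter_sd) ** 2)
    kern /= kern.sum()
    sm = signal.fftconvolve(X, kern[None, :], mode="same")
    sm = np.maximum(sm, 0.0)  # FFT roundoff can leave ~1e-14 negatives
    return RateTrajectory(
        rates=(sm / bin * 1000.0).T, unit_ids=ids, dt=bin, t_start=raster.t_start,
        provenance={"filter_sd": filter_sd, "bin": bin},
    )


def rate_autocorrelation(traj: RateTrajectory, max_lag: float = 500.0) -> CorrelationFunction:
    """Unit-averaged autocorrelation of the rate functions, normalized to
    its zero-lag value.  Zero-variance units are excluded."""
    X = traj.rates.T  # units x time
    var = X.var(axis=1)
    keep = var > 0
    n_excluded = int(np.count_nonzero(~keep))
    if not np.any(keep):
        raise ValueError("all units have zero rate variance")
    L = int(round(max_lag / traj.dt))
    L = min(L, X.shape[1] - 2)
    ac = _mean_autocovariance(X[keep], L)
    return CorrelationFunction(
        lags=traj.dt * np.arange(L + 1), values=ac / ac[0],
        normalization="zero-lag", raw_norm=float(ac[0]),
        n_averaged=int(np.count_nonzero(keep)), n_excluded=n_excluded, bin=traj.dt,
    )


def _per_neuron_spikes(raster: SpikeRaster):
    order = np.argsort(raster.ids, kind="stable")
    ids = raster.ids[order]
    times = raster.times[order]
    bounds = np.searchsorted(ids, np.arange(raster.N + 1))
    for i in range(raster.N):
        yield i, times[bounds[i]:bounds[i + 1]]


def isi_cv(raster: SpikeRaster, min_spikes: int = 10):
    """Per-neuron coefficient of variation of interspike intervals.

    Returns (cv array over included neurons, mean CV).  Neurons with fewer
    than ``min_spikes`` spikes are excluded; raises if none qualifies.
    """
    if min_spikes < 3:
        raise ValueError("min_spikes must be at least 3")
    cvs = []
    for _, ts in _per_neuron_spikes(raster):
        if ts.size >= min_spikes:
            isi = np.diff(ts)
            m = isi.mean()
            if m > 0:
                cvs.append(isi.std() / m)
    if not cvs:
        raise ValueError("no neuron reaches min_spikes")
    cvs = np.asarray(cvs)
    return cvs, float(cvs.mean())


def phase_signals(raster: SpikeRaster, dt: float = 1.0) -> np.ndarray:
    """Per-neuron phase time series: elapsed fraction of the current ISI,
    sampled every dt ms.  Samples before a neuron's first or after its last
    spike are NaN; units with fewer than two spikes are all-NaN."""
    t0, t1 = raster.t_start, raster.duration
    grid = np.arange(t0, t1, dt)
    out = np.full((raster.N, grid.size), np.nan)
    for i, ts in _per_neuron_spikes(raster):
        if ts.size < 2:
            continue
        k = np.searchsorted(ts, grid, side="right")
        valid = (k >= 1) & (k < ts.size)
        kk = k[valid]
        t_prev = ts[kk - 1]
        t_next = ts[kk]
        out[i, valid] = (grid[valid] - t_prev) / (t_next - t_prev)
    return out


def synchrony_chi(signals: np.ndarray) -> float:
    """Synchrony measure chi in [0, 1]:

        chi^2 = Var_t( population mean signal ) / mean_i Var_t( signal_i ).

    Rows are units; NaN entries (undefined phases) are ignored columnwise;
    zero-variance rows are excluded.  chi = 1 for identical signals and
    ~ 1/sqrt(N) for independent ones.
    """
    X = np.asarray(signals, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two signals")
    col_ok = ~np.any(np.isnan(X), axis=0)
    X = X[:, col_ok]
    if X.shape[1] < 2:
        raise ValueError("no common valid time samples")
    v = X.var(axis=1)
    keep = v > 0
    if not np.any(keep):
        raise ValueError("all signals have zero variance")
    X = X[keep]
    chi2 = X.mean(axis=0).var() / X.var(axis=1).mean()
    return float(np.sqrt(chi2))


def voltage_distribution(trace: VoltageTrace, bins=100,
                         exclude_refractory: bool = True) -> DistributionSummary:
    """Pooled membrane-potential histogram over neurons and times."""
    V = trace.V
    if exclude_refractory:
        V = V[~trace.refractory]
    V = np.asarray(V, float).ravel()
    masses, edges = np.histogram(V, bins=bins, density=False)
    masses = masses / V.size
    return DistributionSummary(
        edges=edges, masses=masses, mean=float(V.mean()), var=float(V.var()),
        skewness=float(stats.skew(V)), n_samples=int(V.size),
    )


def decorrelation_time(ac: CorrelationFunction, threshold: float = np.exp(-1.0),
                       skip_zero_lag: bool = None):
    """Smallest lag at which the normalized AC first falls below 1/e,
    linearly interpolated between bins.

    For spike ACs (normalized at the first nonzero lag) the zero-lag
    self-count bin is skipped.  Returns (t_1e, t_expfit); both are None when
    the AC never decays below the threshold within the available lags.
    t_expfit refits log AC over the decaying stretch as a robustness check.
    """
    vals = ac.values
    lags = ac.lags
    if skip_zero_lag is None:
        skip_zero_lag = ac.normalization == "first-nonzero-lag"
    k0 = 1 if skip_zero_lag else 0
    v = vals[k0:]
    lg = lags[k0:]
    below = np.flatnonzero(v < threshold)
    if below.size == 0:
        return None, None
    k = below[0]
    if k == 0:
        t_cross = float(lg[0])
    else:
        f = (v[k - 1] - threshold) / (v[k - 1] - v[k])
        t_cross = float(lg[k - 1] + f * (lg[k] - lg[k - 1]))
    # exponential fit over the positive decaying stretch up to the crossing
    sel = (lg <= lg[k]) & (v > 0)
    t_fit = None
    if np.count_nonzero(sel) >= 3:
        slope, _, _, _, _ = stats.linregress(lg[sel], np.log(v[sel]))
        if slope < 0:
            t_fit = float(-1.0 / slope)
    return t_cross, t_fit


def scaling_fit(J_values, J_c, amplitudes, times, n_boot: int = 2000, seed: int = 0):
    """Log-log slopes of fluctuation amplitude and decorrelation time against
    (J - J_c), with bootstrap 95% confidence intervals.

    Near the rate-chaos transition the fluctuation amplitude vanishes
    linearly in J - J_c (slope +1) and the decorrelation time diverges as
    (J - J_c)^(-1/2) (slope -1/2).  Requires at least 4 supercritical points.
    """
    J = np.asarray(J_values, float)
    A = np.asarray(amplitudes, float)
    T = np.asarray(times, float)
    if np.any(J <= J_c):
        raise ValueError("all J values must exceed J_c")
    if J.size < 4:
        raise ValueError("need at least 4 points")
    x = np.log(J - J_c)

    def slope(xx, yy):
        return stats.linregress(xx, np.log(yy)).slope

    s_amp = slope(x, A)
    s_tim = slope(x, T)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    n = J.size
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        while np.unique(x[idx]).size < 2:
            idx = rng.integers(0, n, n)
        boots[b, 0] = slope(x[idx], A[idx])
        boots[b, 1] = slope(x[idx], T[idx])
    ci = np.percentile(boots, [2.5, 97.5], axis=0)
    return {
        "amplitude_slope": float(s_amp),
        "amplitude_ci": (float(ci[0, 0]), float(ci[1, 0])),
        "time_slope": float(s_tim),
        "time_ci": (float(ci[0, 1]), float(ci[1, 1])),
    }
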