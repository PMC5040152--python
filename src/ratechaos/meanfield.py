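r"""Ricciardi mean-field theory of the balanced LIF network.

The stationary firing rate of an LIF neuron driven by Gaussian white noise
with mean ``mu`` and amplitude ``sigma`` is

    1/phi = tau_rp + tau_m * sqrt(pi) * \int_{(V_r-mu)/sigma}^{(theta-mu)/sigma}
            e^{u^2} (1 + erf u) du,

evaluated with the numerically stable identity e^{u^2}(1+erf u) = erfcx(-u).
The population rate solves the self-consistency nu = phi(mu(nu), sigma(nu))
with input moments

    mu(nu)     = mu0 + tau_m J nu (C_E - g C_I),
    sigma^2(nu)=       tau_m J^2 nu (C_E + g^2 C_I),

(nu in spikes/ms).  The matched rate network loses stability when the bulk
spectral radius of the linearized rate dynamics' Jacobian exceeds one; by the
circular law the bulk radius of D_ij = tau_m (a w_ij + b w_ij^2), with
a = dphi/dmu and b = dphi/dsigma^2 at the fixed point, is

    r(J) = tau_m * sqrt( C_E (aJ + bJ^2)^2 + C_I (-agJ + b g^2 J^2)^2 ).

The critical coupling J_c is the root of r(J) = 1.  Note r(J) does not
involve the transmission delay: the predicted transition is delay-independent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize
from scipy.special import erfcx, roots_legendre

from .params import ModelParams

__all__ = [
    "transfer_rate",
    "transfer_slopes",
    "input_moments_homogeneous",
    "MeanFieldSolution",
    "solve_selfconsistent",
    "find_Jstar",
    "rate_jacobian",
    "StabilityResult",
    "critical_coupling",
    "network_spectral_radius",
    "network_critical_coupling",
    "least_stable_direction",
]

# 200-point Gauss-Legendre rule: the integrand is smooth and the integration
# range in practice spans a few units, so this is accurate to ~1e-13 relative.
_GL_X, _GL_W = roots_legendre(200)

# Upper integration limit beyond which phi underflows to 0 Hz for all
# practical purposes (the integrand grows like e^{u^2}).
_YMAX = 25.0


def _ricciardi_integral(a, b):
    """sqrt(pi) * int_a^b erfcx(-u) du, vectorized over equal-shape a, b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    u = mid[..., None] + half[..., None] * _GL_X
    vals = erfcx(-u)
    return np.sqrt(np.pi) * half * (vals * _GL_W).sum(axis=-1)


def transfer_rate(mu, sigma, params: ModelParams):
    """Stationary LIF firing rate phi(mu, sigma) in Hz (vectorized).

    sigma = 0 is handled by the deterministic limit: zero below rheobase,
    the deterministic-oscillator rate 1/(tau_rp + tau_m ln((mu-V_r)/(mu-theta)))
    above it.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    scalar = mu.ndim == 0 and sigma.ndim == 0
    mu, sigma = np.atleast_1d(mu), np.atleast_1d(sigma)
    mu, sigma = np.broadcast_arrays(mu, sigma)
    out = np.zeros(mu.shape, dtype=np.float64)

    det = sigma < 1e-12
    sup = det & (mu > params.theta)
    if np.any(sup):
        out[sup] = 1.0 / (
            params.tau_rp
            + params.tau_m * np.log((mu[sup] - params.V_r) / (mu[sup] - params.theta))
        )

    sto = ~det
    if np.any(sto):
        yr = (params.V_r - mu[sto]) / sigma[sto]
        yt = (params.theta - mu[sto]) / sigma[sto]
        # beyond _YMAX the rate underflows; clip both limits consistently
        yt_c = np.clip(yt, -np.inf, _YMAX)
        yr_c = np.clip(yr, -np.inf, yt_c)
        integral = _ricciardi_integral(yr_c, yt_c)
        rate = 1.0 / (params.tau_rp + params.tau_m * integral)
        rate[yt > _YMAX] = 0.0
        out[sto] = rate

    out *= 1000.0  # spikes/ms -> Hz
    return float(out[0]) if scalar else out


def input_moments_homogeneous(nu_hz, J, params: ModelParams):
    """Mean and sd (mV) of the summed synaptic input at homogeneous rate nu."""
    nu = np.asarray(nu_hz, dtype=float) / 1000.0  # spikes/ms
    mu = params.mu0 + params.tau_m * J * nu * (params.C_E - params.g * params.C_I)
    s2 = params.tau_m * J * J * nu * (params.C_E + params.g**2 * params.C_I)
    return mu, np.sqrt(np.maximum(s2, 0.0))


def transfer_slopes(mu, sigma, params: ModelParams, rel_step: float = 1e-5):
    """(a, b) = (dphi/dmu, dphi/dsigma^2) at (mu, sigma), in (ms mV)^-1 and
    (ms mV^2)^-1 — i.e. on the spikes/ms scale used by the rate dynamics.

    Central finite differences with relative step ``rel_step``.
    """
    dmu = max(abs(mu) * rel_step, 1e-7)
    a = (transfer_rate(mu + dmu, sigma, params) - transfer_rate(mu - dmu, sigma, params)) / (
        2 * dmu
    )
    s2 = sigma * sigma
    ds2 = max(s2 * rel_step, 1e-9)
    lo = max(s2 - ds2, 0.0)
    b = (
        transfer_rate(mu, np.sqrt(s2 + ds2), params)
        - transfer_rate(mu, np.sqrt(lo), params)
    ) / (s2 + ds2 - lo)
    return a / 1000.0, b / 1000.0


@dataclasses.dataclass(frozen=True)
class MeanFieldSolution:
    nu0: float       # Hz
    mu: float        # mV
    sigma: float     # mV
    J: float         # mV
    converged: bool
    residual: float  # |nu - phi| in spikes/ms


def solve_selfconsistent(params: ModelParams, J: float | None = None) -> MeanFieldSolution:
    """Self-consistent population rate nu0 = phi(mu(nu0), sigma(nu0)).

    Solved by bracketed root finding on [0, 1/tau_rp] (the transfer-function
    ceiling); raises if no root exists in that interval.
    """
    if J is None:
        J = params.J

    def resid(nu_ms):
        mu, sigma = input_moments_homogeneous(nu_ms * 1000.0, J, params)
        return transfer_rate(mu, sigma, params) / 1000.0 - nu_ms

    hi = 1.0 / params.tau_rp if params.tau_rp > 0 else 2.0
    r0, r1 = resid(0.0), resid(hi)
    if r0 < 0 or r1 > 0:
        if abs(r0) < 1e-14:
            nu = 0.0
        else:
            raise RuntimeError(f"no self-consistent rate in [0, {hi}] spikes/ms at J={J}")
    else:
        nu = optimize.brentq(resid, 0.0, hi, xtol=1e-14, rtol=1e-15)
    res = abs(resid(nu))
    mu, sigma = input_moments_homogeneous(nu * 1000.0, J, params)
    return MeanFieldSolution(nu * 1000.0, float(mu), float(sigma), J, res < 1e-10, float(res))


def find_Jstar(J_grid, sim_rates, mf_rates, threshold: float = 0.05):
    """Smallest J on the grid where the simulated rate deviates from the
    mean-field prediction by more than ``threshold`` (relative).

    Returns ``(J_exceed, J_interp)``: the first grid point exceeding the
    criterion and a linear interpolation of the crossing between the
    straddling grid points; ``(None, None)`` if never exceeded.  Grid points
    with a zero mean-field rate are excluded.
    """
    J_grid = np.asarray(J_grid, float)
    sim = np.asarray(sim_rates, float)
    mf = np.asarray(mf_rates, float)
    if not (J_grid.shape == sim.shape == mf.shape):
        raise ValueError("grids must be aligned")
    if np.any(np.diff(J_grid) <= 0):
        raise ValueError("J grid must be ascending")
    keep = mf > 0
    J_grid, sim, mf = J_grid[keep], sim[keep], mf[keep]
    dev = np.abs(sim - mf) / mf
    above = np.flatnonzero(dev > threshold)
    if above.size == 0:
        return None, None
    k = above[0]
    if k == 0:
        return float(J_grid[0]), float(J_grid[0])
    # linear interpolation of dev(J) = threshold between k-1 and k
    frac = (threshold - dev[k - 1]) / (dev[k] - dev[k - 1])
    return float(J_grid[k]), float(J_grid[k - 1] + frac * (J_grid[k] - J_grid[k - 1]))


def rate_jacobian(topology, params: ModelParams, fixed_point: MeanFieldSolution,
                  rel_step: float = 1e-5):
    """Jacobian D of the rate map at the homogeneous fixed point (sparse).

    D_ij = tau_m (a w_ij + b w_ij^2) with a, b the transfer slopes at the
    fixed-point input moments.  For the relaxational dynamics the
    linearization is  tau_r dx/dt = -x + D x.
    """
    a, b = transfer_slopes(fixed_point.mu, fixed_point.sigma, params, rel_step)
    W = topology.weight_matrix()
    D = W.copy()
    D.data = params.tau_m * (a * W.data + b * W.data**2)
    return D


@dataclasses.dataclass(frozen=True)
class StabilityResult:
    J_c: float | None                  # mV
    probe_J: np.ndarray                # mV grid probed
    probe_radius: np.ndarray           # r(J) on the grid
    direction: np.ndarray | None = None
    eigenvalue: complex | None = None


def _bulk_radius(J: float, params: ModelParams) -> float:
    sol = solve_selfconsistent(params, J)
    a, b = transfer_slopes(sol.mu, sol.sigma, params)
    eE = a * J + b * J * J
    eI = -a * params.g * J + b * (params.g * J) ** 2
    return params.tau_m * np.sqrt(params.C_E * eE**2 + params.C_I * eI**2)


def critical_coupling(params: ModelParams, J_lo: float = 0.05, J_hi: float = 2.0,
                      tol: float = 1e-4) -> StabilityResult:
    """Critical coupling J_c of the matched rate network: root of r(J) = 1.

    Delay-independent by construction.  Returns J_c = None (with the probed
    radii as diagnostics) if the network is stable over the whole probe range.
    """
    grid = np.linspace(J_lo, J_hi, 14)
    radii = np.array([_bulk_radius(J, params) for J in grid])
    above = np.flatnonzero(radii >= 1.0)
    if above.size == 0:
        return StabilityResult(None, grid, radii)
    k = above[0]
    if k == 0:
        return StabilityResult(float(grid[0]), grid, radii)
    J_c = optimize.brentq(
        lambda J: _bulk_radius(J, params) - 1.0, grid[k - 1], grid[k], xtol=tol
    )
    return StabilityResult(float(J_c), grid, radii)


def network_spectral_radius(topology, params: ModelParams, J: float) -> float:
    """Spectral radius of the sampled rate-dynamics Jacobian at coupling J."""
    from scipy.sparse.linalg import eigs as sparse_eigs

    if params.J <= 0:
        raise ValueError("params.J must be positive (weights are rescaled by J)")
    p = params.replace(J=J)
    sol = solve_selfconsistent(p)
    Wp = topology.weight_matrix().copy()
    Wp.data = Wp.data * (J / params.J)
    a, b = transfer_slopes(sol.mu, sol.sigma, p)
    D = Wp.copy()
    D.data = p.tau_m * (a * Wp.data + b * Wp.data**2)
    if topology.N <= 600:
        w = np.linalg.eigvals(D.toarray())
    else:
        v0 = np.full(topology.N, 1.0 / np.sqrt(topology.N))  # deterministic start
        w = sparse_eigs(D.tocsc(), k=6, which="LM", return_eigenvectors=False,
                        v0=v0, maxiter=10000)
    return float(np.abs(w).max())


def network_critical_coupling(topology, params: ModelParams,
                              J_lo: float, J_hi: float, xtol: float = 2e-3) -> float:
    """Critical coupling of one sampled network realization: the J at which
    the spectral radius of its rate-dynamics Jacobian crosses one.  This is
    the finite-size counterpart of :func:`critical_coupling` and differs
    from it by the sampling fluctuation of the bulk edge."""
    f = lambda J: network_spectral_radius(topology, params, J) - 1.0
    return float(optimize.brentq(f, J_lo, J_hi, xtol=xtol))


def least_stable_direction(jacobian):
    """Leading eigenvector of the Jacobian (largest real part) as a real,
    unit-norm perturbation direction, with its eigenvalue.

    For the relaxational linearization dx/dt = (-x + D x)/tau_r the least
    stable mode of D is the one with the largest real part.  A complex
    leading eigenvector is mapped to a real direction by taking its real
    part and renormalizing.
    """
    from scipy.sparse.linalg import eigs
    from scipy import sparse

    if sparse.issparse(jacobian):
        n = jacobian.shape[0]
        if n < 50:
            w, v = np.linalg.eig(jacobian.toarray())
        else:
            v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic ARPACK start
            w, v = eigs(jacobian.tocsc().astype(np.float64), k=6, which="LR", v0=v0)
    else:
        w, v = np.linalg.eig(np.asarray(jacobian, dtype=float))
    k = int(np.argmax(w.real))
    vec = np.real(v[:, k])
    nrm = np.linalg.norm(vec)
    if nrm < 1e-12:
        vec = np.imag(v[:, k])
        nrm = np.linalg.norm(vec)
    return vec / nrm, complex(w[k])
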