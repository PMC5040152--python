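import numpy as np
import pytest
from numba import njit
from scipy.integrate import quad
from scipy.special import erfcx

from ratechaos.meanfield import (critical_coupling, find_Jstar,
                                 input_moments_homogeneous, least_stable_direction,
                                 rate_jacobian, solve_selfconsistent,
                                 transfer_rate, transfer_slopes)
from ratechaos.params import ModelParams, default_params
from ratechaos.topology import build_topology


# --------------------------------------------------------- transfer function

def test_deterministic_limits():
    p = default_params()
    assert transfer_rate(15.0, 0.0, p) == 0.0
    rate = transfer_rate(24.0, 0.0, p)
    expected = 1000.0 / (p.tau_rp + p.tau_m * np.log((24.0 - p.V_r) / (24.0 - p.theta)))
    assert np.isclose(rate, expected, rtol=1e-12)


def test_quadrature_matches_scipy_quad():
    """The Gauss-Legendre evaluation against adaptive quadrature."""
    p = default_params()
    for mu, sigma in [(24.0, 1.0), (15.0, 4.0), (-20.0, 30.0), (5.0, 10.0),
                      (19.9, 0.3)]:
        a = (p.V_r - mu) / sigma
        b = (p.theta - mu) / sigma
        integral, _ = quad(lambda u: np.sqrt(np.pi) * erfcx(-u), a, b, limit=400)
        expected = 1000.0 / (p.tau_rp + p.tau_m * integral)
        assert np.isclose(transfer_rate(mu, sigma, p), expected, rtol=1e-10)


def test_phi_monotone_in_mu_and_bounded_by_refractory_ceiling():
    p = default_params()
    mu = np.linspace(-60.0, 120.0, 100)
    rates = transfer_rate(mu, 8.0, p)
    assert np.all(np.diff(rates) > 0)
    assert np.all(rates < 1000.0 / p.tau_rp)
    assert np.all(rates >= 0)


def test_transfer_rate_against_single_neuron_monte_carlo():
    """White-noise LIF simulation (Euler-Maruyama, dt = 0.01 ms, 60 s) at
    5 probe points agrees with the quadrature within Monte-Carlo error."""

    @njit(cache=True)
    def mc_rate(mu, sigma, theta, Vr, trp, tau, T_ms, seed):
        np.random.seed(seed)
        dt = 0.01
        sq = sigma * np.sqrt(dt / tau)
        V = Vr
        t = 0.0
        t_ref = 0.0
        n = 0
        while t < T_ms:
            if t_ref > 0:
                t_ref -= dt
            else:
                V += dt * (mu - V) / tau + sq * np.random.normal()
                if V >= theta:
                    V = Vr
                    t_ref = trp
                    n += 1
            t += dt
        return n / T_ms * 1000.0

    p = default_params()
    probes = [(24.0, 2.0), (18.0, 6.0), (10.0, 10.0), (22.0, 8.0), (0.0, 20.0)]
    for k, (mu, sigma) in enumerate(probes):
        pred = transfer_rate(mu, sigma, p)
        est = mc_rate(mu, sigma, p.theta, p.V_r, p.tau_rp, p.tau_m, 60000.0, 100 + k)
        n_expected = max(pred * 60.0, 1.0)
        mc_err = 4.0 * np.sqrt(n_expected) / 60.0  # ~4 sigma Poisson band, Hz
        assert abs(est - pred) < max(mc_err, 1.0)


def test_transfer_slopes_match_quadrature_differentiation():
    """Central finite differences against an independent derivative from
    differentiating the quadrature at much finer step."""
    p = default_params()
    mu, sigma = -10.0, 25.0
    a, b = transfer_slopes(mu, sigma, p)
    h = 1e-3
    a_ref = (transfer_rate(mu + h, sigma, p) - transfer_rate(mu - h, sigma, p)) / (2e-3 * 1000.0)
    s2 = sigma**2
    hb = s2 * 1e-3
    b_ref = (transfer_rate(mu, np.sqrt(s2 + hb), p)
             - transfer_rate(mu, np.sqrt(s2 - hb), p)) / (2 * hb * 1000.0)
    assert np.isclose(a, a_ref, rtol=1e-5)
    assert np.isclose(b, b_ref, rtol=1e-4)


# ----------------------------------------------------------- self-consistency

def test_uncoupled_selfconsistent_rate_is_deterministic_rate():
    p = default_params(J=0.0)
    sol = solve_selfconsistent(p)
    assert np.isclose(sol.nu0, transfer_rate(p.mu0, 0.0, p), rtol=1e-10)
    assert sol.sigma == 0.0


@pytest.mark.parametrize("C,N", [(1000, 10000), (4000, 40000)])
def test_selfconsistency_residual_over_J_grid(C, N):
    p = default_params(N=N, C=C)
    for J in np.arange(0.1, 0.9, 0.1):
        sol = solve_selfconsistent(p, J)
        assert sol.converged
        assert sol.residual < 1e-10
        mu, sigma = input_moments_homogeneous(sol.nu0, J, p)
        assert np.isclose(mu, sol.mu)
        assert np.isclose(transfer_rate(mu, sigma, p), sol.nu0, rtol=1e-8)


def test_homogeneous_moments_summation_identity():
    p = ModelParams(N=100, C=20, J=0.5)
    nu = 10.0  # Hz
    mu, sigma = input_moments_homogeneous(nu, p.J, p)
    nu_ms = nu / 1000.0
    assert np.isclose(mu, p.mu0 + p.tau_m * p.J * nu_ms * (p.C_E - p.g * p.C_I))
    assert np.isclose(sigma**2, p.tau_m * p.J**2 * nu_ms * (p.C_E + p.g**2 * p.C_I))


# ------------------------------------------------------------------ J* finder

def test_find_jstar_constructed_cases():
    J = np.array([0.1, 0.3, 0.5, 0.7])
    mfr = np.array([10.0, 10.0, 10.0, 10.0])
    assert find_Jstar(J, mfr, mfr) == (None, None)
    sim = mfr * np.array([1.0, 1.0, 1.1, 1.1])
    first, interp = find_Jstar(J, sim, mfr)
    assert first == 0.5
    assert 0.3 < interp <= 0.5
    with pytest.raises(ValueError):
        find_Jstar(J[::-1], sim, mfr)


# ------------------------------------------------- stability and directions

def test_jacobian_zero_at_zero_coupling(small_params):
    p = small_params.replace(J=0.0)
    top = build_topology(p)
    sol = solve_selfconsistent(p)
    D = rate_jacobian(top, p, sol)
    assert D.nnz == 0 or np.allclose(D.data, 0.0)


def test_least_stable_direction_known_spectra(fixtures):
    u, lam = least_stable_direction(np.diag([0.1, 0.9]))
    assert np.isclose(abs(u[1]), 1.0)
    assert np.isclose(lam.real, 0.9)
    M, eigs, Q = fixtures["known_spectrum"]
    u, lam = least_stable_direction(M)
    assert np.isclose(lam.real, eigs.max())
    expected = Q[:, np.argmax(eigs)]
    assert min(np.linalg.norm(u - expected), np.linalg.norm(u + expected)) < 1e-8


def test_critical_coupling_delay_independent():
    p = default_params(N=1000, C=100)
    a = critical_coupling(p.replace(delta=0.55), J_lo=0.5, J_hi=3.0)
    b = critical_coupling(p.replace(delta=0.0), J_lo=0.5, J_hi=3.0)
    assert a.J_c == b.J_c
    assert np.all(np.diff(a.probe_radius) > 0)  # radius monotone in J


def test_bulk_radius_matches_sampled_jacobian_spectral_radius():
    """Mean-field circular-law radius vs explicit eigenvalues of a sampled
    network Jacobian (within a few percent at this size)."""
    from scipy.sparse.linalg import eigs as sparse_eigs

    p = default_params(N=4000, C=400, seed=3)
    from ratechaos.meanfield import _bulk_radius

    for J in (0.4, 0.8):
        sol = solve_selfconsistent(p, J)
        D = rate_jacobian(build_topology(p.replace(J=J)), p.replace(J=J), sol)
        v0 = np.full(p.N, 1.0 / np.sqrt(p.N))
        w = sparse_eigs(D.tocsc(), k=8, which="LM", return_eigenvectors=False,
                        v0=v0, maxiter=5000)
        r_net = np.abs(w).max()
        r_mf = _bulk_radius(J, p)
        assert abs(r_net - r_mf) / r_mf < 0.06
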