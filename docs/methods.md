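# Methods

This note documents the models, the numerical choices behind them, and the
places where the design was genuinely open — in enough detail that every
number the package produces can be traced to a decision recorded here.

## Networks

Connectivity is fixed in-degree: every neuron receives exactly
C_E = round(f_E·C) excitatory (+J mV) and C_I = C − C_E inhibitory (−gJ)
synapses, drawn uniformly without replacement within each population, no
self- or duplicate connections.  Fixed in-degree (rather than Erdős–Rényi
with mean C) is the default because the mean-field calculation assumes
identical input statistics for every neuron; with it the homogeneous fixed
point of the rate network is exact.  An `erdos-renyi` mode exists for
sensitivity checks.  Defaults (`src/ratechaos/defaults.yaml`):
N = 10000, C = 1000, f_E = 0.8, g = 5, Δ = 0.55 ms, τ_m = 20 ms,
θ = 20 mV, V_r = 10 mV, τ_rp = 0.5 ms, μ₀ = 24 mV.  The large variant
(N = 40000, C = 4000) keeps the connection probability C/N = 0.1.

## Event-driven LIF engine

Between synaptic deliveries every membrane potential follows the
closed-form leaky-integrator solution, so the only approximations anywhere
are floating-point.  Predicted threshold crossings live in an indexed
binary min-heap keyed by (time, id); deliveries in a FIFO ring buffer
(all synapses share one delay, so deliveries are generated time-ordered).
Spikes reset V to V_r and clamp the neuron for τ_rp; deliveries arriving
during the refractory window are discarded (the documented behavior of the
underlying model; an `accumulate` mode applies them at the end of the
window instead).

**Same-timestamp semantics.**  With Δ = 0 (or Δ < τ_rp) a spike's
deliveries land at the spike's own timestamp and can trigger further
crossings at that instant, so the order of simultaneous events is part of
the model definition.  The default is the synchronous-batch rule — the
dt → 0 limit of a time-stepped integration: all deliveries carrying the
current timestamp are summed before any triggered crossing fires; then all
neurons at or above threshold fire together (recorded in ascending id);
their deliveries form the next same-time batch.  This preserves the net
sign of simultaneous recurrent input.  The two serial alternatives
(`resets-first`, `deliveries-first`) are available as engine options; under
`resets-first` a same-instant excitatory cascade outruns its own
inhibition — all excitatory recruits fire (and become refractory, hence
protected from the cascade's inhibition under discard semantics) before
any inhibitory recruit acts — and the Δ < τ_rp network at J ≳ 0.4 mV
falls into a fully synchronized locked state firing at the uncoupled rate.
We verified with an independent fixed-step oracle that this lock is a
property of that serialization, not an integration error; it contradicts
the zero-delay phenomenology the package is built to examine, which is why
the batch rule is the default.

**Initial conditions.**  `stationary_voltages` samples each V_i i.i.d.
from the stationary membrane-potential density of the mean-field
asynchronous state (a single-neuron Euler–Maruyama run at the
self-consistent (μ, σ), sampled every 37 ms after a 500 ms burn-in).
A uniform draw on [V_r, θ) is also provided but puts the whole population
on one coherent upward sweep, firing a giant volley at t = 0⁺ that can
drop the Δ < τ_rp network into the synchronized attractor; the stationary
sample starts inside the asynchronous state's basin.  A 1 s transient is
discarded before statistics in all standard runs.

**Divergence guards.**  The engine raises a divergence error, naming the
time reached, if the pending-delivery buffer overflows or if more than
3N + 100 spikes occur at one timestamp (only possible with τ_rp = 0).

## QIF variant

Subthreshold flow τ_m dV/dt = (V − V_q)²/dV_q + μ − θ, advanced between
events by its closed-form (tangent/cotangent) solution; spike at V_peak,
reset to V_reset, same delivery and refractory semantics as the LIF.  The
rheobase is μ = θ for any curvature, matching the LIF.  Defaults:
V_q = 15 mV, dV_q = 400 mV, V_peak = 300 mV, V_reset = −270 mV.  dV_q
sets the half-width of the slow subthreshold region,
√((θ−μ)·dV_q) ≈ 90 mV at μ ≈ 0; it is chosen large so that the very
strong jumps of the J = 20 mV control (+20 / −100 mV) remain small
relative to the operating range, as the LIF's jumps are at its couplings.
With the naive narrow choice (V_q = 15, dV_q = θ − V_r = 10) a +20 mV
kick instantly traverses the whole subthreshold range while the quadratic
flow bounds how long inhibition can hold a neuron down, and the network
runs away to a kick-dominated state near 300–600 Hz for every
V_peak/V_reset we tried — not a meaningful comparison.  Under the wide
defaults the J = 20 mV network settles at ~2.4 Hz with mean CV ≈ 0.83.

## Rate ("Poisson") network

Unit rates on an Euler grid (dt = 1 ms), relaxational form
ν ← ν + (dt/τ_r)(−ν + φ(μ_i, σ_i)) with τ_r = τ_m; a pure map mode
(ν ← φ) shares the fixed point and the instability.  The delay enters as
an integer bin shift of presynaptic rates (round(Δ/dt)); the instability
condition never sees it.  φ is evaluated from a precomputed table of the
Ricciardi antiderivative G(x) = ∫₀ˣ √π·erfcx(−u) du (Simpson on a 10⁻³
grid over [−40, 15], logarithmic tail expansion below −40, zero rate
above 15), accurate to ~2·10⁻⁴ relative in the worst corner and ~10⁻⁶
typically; the mean-field module itself always uses 200-point
Gauss–Legendre quadrature (~10⁻¹³).  Poisson spikes are sampled per bin
with probability ν·dt, uniformly jittered within the bin.

## Mean field, stability, critical coupling

`solve_selfconsistent` brackets ν = φ(μ(ν), σ(ν)) on [0, 1/τ_rp] (Brent,
residual < 10⁻¹⁰).  Transfer slopes a = ∂φ/∂μ, b = ∂φ/∂σ² come from
central finite differences with relative step 10⁻⁵ (validated against
finer steps).  The Jacobian is D_ij = τ_m (a w_ij + b w_ij²); both input
channels (mean and variance) are included — dropping the b channel moves
J_c well outside the reported values, which is how the two printed anchors
(0.49 and 0.96 mV) adjudicate the channel question.  `critical_coupling`
bisects the circular-law bulk radius r(J) = 1 to 10⁻⁴ mV.
`network_critical_coupling` does the same with the explicit spectral
radius of one sampled realization's Jacobian (the finite-size bulk edge);
the two agree within a few percent at N ≥ 4000, and the sampled version is
used wherever a specific realization is driven near its own transition.
The least-stable direction is the eigenvector of the largest-real-part
eigenvalue; a complex leading pair is mapped to a real input pattern by
taking the real part and renormalizing.

## Diagnostics

* Spike autocorrelation: per-neuron autocovariance of the 1 ms binned
  spike-count train (stationary mean removed, FFT, bias-corrected by lag),
  averaged over 3000 sampled neurons, normalized to the first nonzero lag
  (the zero-lag bin carries the self-count delta); "second peak"
  normalization absorbs any constant factor.
* Filtered rates: counts convolved with a unit-area Gaussian truncated at
  ±5 sd (widths 10/50/100 ms), reported in Hz.
* CV: sd/mean of ISIs per neuron, neurons with ≥ 10 spikes (≥ 5 in short
  desk runs), averaged.
* Synchrony χ: variance of the population-mean signal over the mean
  single-signal variance, computed on phases defined as elapsed fraction
  of the current ISI sampled at 1 ms (a voltage-based mode exists); NaN
  phases (before first/after last spike) exclude the time sample.
* Voltage distributions pool recorded neurons × 1 ms samples, excluding
  refractory samples by default.
* Decorrelation time: first 1/e crossing of the normalized AC, linearly
  interpolated; an exponential-fit variant is reported alongside.
* Near-critical scaling: log-log least squares of fluctuation amplitude
  (unit-averaged stationary rate variance) and decorrelation time against
  J − J_c, with bootstrap 95% CIs.

## Perturbation experiment

The protocol perturbs μ₀ along the least-stable direction (component sd
1 mV, 2 ms; the 10 ms / 0.1 mV variant reproduces decay times within
20%).  Rate network: deterministic run from the fixed point, deviation
projected on the direction, normalized at the offset.  Spiking network:
trial states every 200 ms along one reference trajectory; perturbed and
unperturbed continuations start from the bit-identical engine state, so
the per-neuron 1 ms count difference isolates the causal response; it is
smoothed with a 2 ms Gaussian (raw count differences are shot-noise
dominated at reduced trial counts), projected, averaged over trials, and
normalized at the offset.  Perturbation direction, strength, duration and
network realization are identical for the two models.  The reported decay
time is the 1/e point of the *envelope* of |p| (forward running maximum):
when the least-stable mode is a complex pair, the projection onto the real
perturbation direction oscillates through zero under a decaying envelope,
and a plain first-crossing would report the first cosine zero rather than
the mode's decay; for monotone responses the two coincide.

## Problem sizes in the shipped runs

The default test suite and the acceptance script run the spiking network
at its native N = 10000 / C = 1000 for the headline quantities (10 s
post-transient, 1 s transient), the mean-field breakdown bracket at
N = 20000 / C = 2000 (2 s), the perturbation dissociation at N = 2000 /
C = 200 with 300 trials per coupling, and the rate-network scaling sweep
at N = 2000 / C = 200 (40 s per coupling).  The analysis scripts accept
`--scale` to move between these and the full sizes.

## What the synthetic conditions do and do not show

All inputs are generated internally; there is no external data.  The
generator reproduces the target architecture exactly (two homogeneous
populations, two synaptic weights, fixed in-degree, constant drive), so
passing tests speak to the mathematical claims about this model class —
not to biological realism (no synaptic filtering, no heterogeneity, no
external spiking noise, no conductances).

Two desk-scale limitations are worth stating plainly.  First, at weak
coupling with the standard delay (J ≈ 0.2 mV, Δ = 0.55 ms, C = 1000) the
simulated rate sits ~8% *below* the white-noise mean field — a real
finite-size/colored-noise effect (delay-driven fast population
oscillation plus sub-Poissonian inputs) confirmed against an independent
fixed-step integrator; the 5% departure criterion is therefore applied to
the upward departure on grids starting at J = 0.3.  Second, the zero-delay network at strong
coupling (Δ = 0, J = 0.8 mV) keeps a residual fast population oscillation
under the synchronous-batch semantics (neurons recruited in one batch fire
at the identical timestamp and tend to be co-recruited again), which
raises its stationary rate ~10% above the white-noise mean field — an
order of magnitude below the +90..120% departure at Δ = 0.55 ms, and
confirmed by the independent fixed-step integrator, but not literally
inside a 5% band.  Third, the clean
near-critical scaling of the supercritical rate network (amplitude ∝
J − J_c, decorrelation time ∝ (J − J_c)^(−1/2)) is a large-N mean-field
property: at the reduced sizes we can afford (N ≤ 4000) the sampled
eigenvalue bulk's discrete edge pins barely-supercritical states at tiny
amplitude and the rectified transfer function bends the strongly
supercritical ones, so the measured amplitude exponent is ≈ 3 and the
decorrelation time is flat — the package reports these fits with
confidence intervals rather than forcing the asymptotic law.
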