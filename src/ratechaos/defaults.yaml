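# Default model parameters for the balanced E/I LIF network and its
# topology-matched rate ("Poisson") network.
#
# The headline network is N=10000 neurons with fixed in-degree C=1000
# (connection probability 0.1); the large variant is N=40000 / C=4000 at the
# same connection probability.  All voltages in mV, times in ms.
model:
  N: 10000          # neurons
  C: 1000           # synapses per neuron (in-degree), split 4:1 E:I
  f_E: 0.8          # excitatory fraction, of neurons and of inputs
  J: 0.5            # excitatory synaptic strength, mV (swept 0.2..0.8 in most runs)
  g: 5.0            # inhibition/excitation ratio; inhibitory weight = -g*J
  delta: 0.55       # synaptic transmission delay, ms
  tau_m: 20.0       # membrane time constant, ms
  theta: 20.0       # spike threshold, mV
  V_r: 10.0         # reset potential, mV
  tau_rp: 0.5       # absolute refractory period, ms
  mu0: 24.0         # constant feed-forward input, mV (suprathreshold drive)
  seed: 0

# Quadratic integrate-and-fire variant.  Subthreshold flow
#   tau_m dV/dt = (V - V_q)^2 / dV_q + mu - theta,
# which matches the LIF's membrane time constant and rheobase (mu = theta)
# for any curvature dV_q.  dV_q sets the width of the slow subthreshold
# region; it is chosen large so that the very strong synaptic jumps of the
# strong-coupling control (J = 20 mV, inhibitory -100 mV) remain small
# relative to the operating range.  Spike at V_peak, reset to V_reset.
qif:
  V_q: 15.0         # mV, center of the slow region
  dV_q: 400.0       # mV, curvature denominator
  V_peak: 300.0     # mV
  V_reset: -270.0   # mV

# Rate-network dynamics (relaxational form; `map` mode available in code).
rate:
  dt: 1.0           # Euler step, ms
  tau_r: 20.0       # rate relaxation time constant, ms (= tau_m)

# Numerics
numerics:
  fd_rel_step: 1.0e-5     # relative step for finite-difference transfer slopes
  selfconsistent_tol: 1.0e-12   # absolute residual tolerance, spikes/ms
  bisect_tol_J: 1.0e-4    # bisection tolerance for the critical coupling, mV
  init_transient: 1000.0  # discarded transient before statistics, ms

# Diagnostics conventions
diagnostics:
  ac_bin: 1.0             # spike-count bin for autocorrelations, ms
  ac_n_sample: 3000       # neurons sampled for the population-averaged spike AC
  filter_sds: [10.0, 50.0, 100.0]   # Gaussian filter widths for rate functions, ms
  chi_phase_dt: 1.0       # sampling step for phase-based synchrony, ms

# Perturbation protocol: structured perturbation of the feed-forward input mu0
# along the least-stable direction of the linearized rate dynamics.
perturbation:
  amplitude_sd: 1.0       # sd of the perturbation vector components, mV
  duration: 2.0           # ms
  smooth_sd: 2.0          # Gaussian smoothing of binned spike-count deviations, ms
  trial_spacing: 200.0    # ms between trial states along the reference trajectory
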