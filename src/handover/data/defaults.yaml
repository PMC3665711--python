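# Default configuration of the handover receiver model and its simulations.
# Every constant that the model's published description leaves open is set
# here, once, and can be overridden by passing an edited copy to the CLI.

model:
  case_prior_natural: 0.8        # P(C=N), the receiver's trust in a natural handover
  decision_threshold: 1.2e-3     # Gamma (m^2), fixed by the shipped calibration routine
  uniform_support: [-0.375, 0.375, -0.25, 0.25]   # workspace rectangle (m)
  prior_mean: [0.0, 0.0]         # natural handover position M (m)
  prior_cov: [0.0016, 0.0016]    # diagonal prior covariance (m^2), SD 4 cm
  learning_rate_mean: 0.5        # pi_mu, fast update of the prior mean
  learning_rate_cov: 0.2         # pi_sigma, slower update of the prior covariance
  observation_noise: 0.005       # per-axis sd (m) of observed delivery samples
  motor_latency: 0.0             # additive constant (s) on reaction times

calibration:
  fractions: {start: 0.05, stop: 1.0, step: 0.05}
  n_mc: 1000
  sigma: 0.005                   # matches model.observation_noise
  duration: 1.0
  rate: 100.0

experiments:
  replicates: 500
  threshold_scale_exp5: 0.5      # "lower level" of Gamma for the industrial robot
  sampling_rate: 100.0
  arm:                           # two-link stand-in for the robot deliverer
    base: [-0.50, -0.35]
    link_lengths: [0.45, 0.45]
  accel_fraction: 0.15
  robot_start: [-0.05, -0.45]    # midair rest pose of the robot hand

synthetic:
  sampling_rate: 240.0
  noise_sigma: 3.0e-6            # tracker-level jitter (m)
  rt_mean: 0.4
  rt_sd: 0.1
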