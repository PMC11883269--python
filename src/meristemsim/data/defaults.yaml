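# Calibrated baseline parameters for the lineage-competition model.
#
# r is set so that an uninhibited, noise-free lineage reaches
# (1 + r*t/2) * exp(r*t/2) ~ 80 total cells at t = 120 h (r*t/2 = 3),
# matching the empirical scale of the dominant lineage.
# sigma / K_hill / m_hill / alpha were calibrated so that a 1000-run
# threshold-version ensemble yields a single clearly dominant lineage
# (rank-1 final total >= 2x rank-2) in >= 95% of runs.
model:
  n_lineages: 5
  r: 0.05
  gamma: 0.5
  sigma: 0.05
  K_hill: 5.0
  m_hill: 4.0
  alpha: 1.0
  t_end: 120.0
  dt: 0.05
  noise_model: multiplicative

# The Hill constants of the two inhibition variants need not coincide;
# the mutual version applies inhibition to the pooled marginal count of
# the other four lineages, so its half-saturation point sits higher.
version_overrides:
  threshold: {}
  mutual:
    K_hill: 12.0
    m_hill: 4.0
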