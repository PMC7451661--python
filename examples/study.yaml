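# Example study configuration for `aboin run` / `aboin oc --config`.
# Omitted design fields take the recommended defaults (phi1 = 0.6*phi,
# phi2 = 1.4*phi, Delta = 0.4*phi, g1 = 0.4, g2 = 0.9, lead-in 6,
# cohorts of 3, maximum 30 patients, elimination cutoff 0.95).
design:
  phi: 0.2
  variant: aboin_prior
  max_n: 36
prior:
  pi0: [0.2, 0.45, 0.7, 0.45, 0.2]   # investigator's MTD confidence per dose
  mtd_guess: 3
scenarios:
  - probs: [0.05, 0.10, 0.20, 0.30, 0.35]
    true_mtd: 3
    label: steep
  - probs: [0.17, 0.18, 0.20, 0.22, 0.23]
    true_mtd: 3
    label: flat
simulation:
  replicates: 1000
  seed: 1
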