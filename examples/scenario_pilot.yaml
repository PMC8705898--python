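# Pilot batch-equivalence study design for a 0.025% w/w capsaicin emulsion.
#
# Arms: three commercial batches of the same reference product plus a
# double-strength (0.05% w/w) negative control. IVRT uses 12 replicate Franz
# cells per batch over a 6 h schedule; IVPT uses 6 skin donors with 2
# replicates each over 24 h. Release constants (true_k, ug h^-1/2 cm^-2) and
# fluxes (true_jss, ng h^-1 cm^-2) scale with strength; donor_cv carries the
# dominant donor-to-donor lognormal variability.
#
# Run:  topeq simulate --scenario examples/scenario_pilot.yaml --out study/
seed: 20211204
arms:
  - label: batch1
    strength_pct: 0.025
    true_k: 28.7
    true_jss: 15.1
    true_lag: 2.0
    donor_cv: 0.55
    replicate_cv: 0.08
    noise_sd: 1.0
  - label: batch2
    strength_pct: 0.025
    true_k: 28.1
    true_jss: 15.0
  - label: batch3
    strength_pct: 0.025
    true_k: 28.0
    true_jss: 13.6
  - label: negative_control
    strength_pct: 0.05
    true_k: 56.0
    true_jss: 22.6
ivrt_times_h: [0.5, 1, 2, 3, 4, 5, 6]
ivpt_times_h: [0, 1.5, 2.5, 3.5, 5.5, 7.5, 9.5, 11.5, 14.5, 17.5, 20.5, 24]
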