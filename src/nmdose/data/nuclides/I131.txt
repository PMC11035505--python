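# I-131 photon emission spectrum (gammas + Xe K x-rays), transcribed from a
# standard decay-data compilation (ICRP-107 style). Beta emissions excluded:
# external photon dose only.
# half_life_s: 693378.0
# columns: energy_keV  intensity_per_decay
29.461   0.0140
29.782   0.0259
33.624   0.00726
34.419   0.00155
80.185   0.0262
177.214  0.00270
284.305  0.0614
318.090  0.00078
325.789  0.00274
364.489  0.815
502.991  0.00360
636.989  0.0717
642.719  0.00217
722.911  0.0177
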