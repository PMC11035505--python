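# F-18 photon emissions: the positron (branching 0.9686) annihilates in situ,
# yielding a pair of 511 keV quanta; intensity below is the pair folded into a
# single table line (2 x 0.9686 photons per decay). Positron transport is not
# modelled (photon-only external dose).
# half_life_s: 6586.2
# columns: energy_keV  intensity_per_decay
511.0    1.9372
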