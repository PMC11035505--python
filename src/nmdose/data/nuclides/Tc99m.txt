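# Tc-99m photon emission spectrum (gamma + K x-rays), transcribed from a
# standard decay-data compilation (ICRP-107 style). Conversion-electron and
# Auger emissions are excluded: only photons matter for external dose.
# half_life_s: 21624.12
# columns: energy_keV  intensity_per_decay
18.251   0.0113
18.367   0.0214
20.619   0.00432
21.005   0.00089
140.511  0.885
142.630  0.000187
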