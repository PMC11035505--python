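# Berger-form point-isotropic dose buildup coefficients for water,
# B(mu*d) = 1 + a * (mu*d) * exp(b * mu*d), interpolated log-linearly in energy.
# Coefficients approximate published water buildup tables; the point-kernel
# backend is a fast deterministic engine cross-checked against the Monte Carlo
# backend, not a precision standard on its own.
energy_keV,a,b
30,0.35,0.005
50,1.00,0.030
100,1.55,0.060
150,1.70,0.065
200,1.65,0.060
300,1.50,0.050
500,1.30,0.040
662,1.20,0.035
1000,1.05,0.030
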