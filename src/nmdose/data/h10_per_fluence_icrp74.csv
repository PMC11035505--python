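# Ambient dose equivalent per unit fluence, H*(10)/Phi, ICRP Publication 74
# (mono-energetic photons, expanded and aligned field).
# columns: energy_keV, h10_pSv_cm2
energy_keV,h10_pSv_cm2
10,0.061
15,0.83
20,1.05
30,0.81
40,0.64
50,0.55
60,0.51
80,0.53
100,0.61
150,0.89
200,1.20
300,1.80
400,2.38
500,2.93
600,3.44
800,4.38
1000,5.20
1500,6.90
2000,8.60
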