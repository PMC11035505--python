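# ICRP Publication 103 tissue weighting factors w_T (sum = 1 exactly).
# "Remainder" is the ICRP-103 remainder-tissue group treated as one entry.
tissue,w_T
Red bone marrow,0.12
Colon,0.12
Lungs,0.12
Stomach,0.12
Breast,0.12
Remainder,0.12
Gonads,0.08
Urinary bladder,0.04
Oesophagus,0.04
Liver,0.04
Thyroid,0.04
Bone surface,0.01
Brain,0.01
Salivary glands,0.01
Skin,0.01
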