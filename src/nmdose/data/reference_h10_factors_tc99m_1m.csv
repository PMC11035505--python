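# Published per-source-region ambient dose equivalent rate factors at 1 m,
# H*(10)_source_region in uSv/h per MBq in the region, for a Tc-99m bone-scan
# (HDP/MDP) patient represented by five adult computational models: four male
# models of ~164 cm height spanning 50.8-85.3 kg, plus the ICRP adult female
# reference voxel phantom. Used as validation input for ratio/RSD arithmetic.
# Note: the kidneys value of model M0B is stored as 8.28E-03; the source table
# prints 8.28E-02, which is inconsistent with its own printed max/min ratio of
# 2.0 and is treated as a transcription error.
region,M0A,M0B,M0C,M0D,ICRP_female
Urinary bladder content,1.82E-02,1.27E-02,1.34E-02,1.15E-02,2.06E-02
Kidneys,1.29E-02,8.28E-03,1.12E-02,8.13E-03,1.61E-02
Remainder,1.41E-02,1.48E-02,1.42E-02,1.37E-02,1.50E-02
Bone surface,1.31E-02,1.11E-02,1.16E-02,9.63E-03,1.09E-02
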