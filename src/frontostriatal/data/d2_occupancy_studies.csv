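study_label,cohort,occupancy_percent
Abi-Dargham et al. (2000),HC,12
Abi-Dargham et al. (2000),SZ,21
Erlandsson et al. (2003),HC,45
Laruelle et al. (1997),HC,26
Riccardi et al. (2008),HC,13
Verhoeff et al. (2001),HC,22
Voruganti et al. (2001),SZ,16
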