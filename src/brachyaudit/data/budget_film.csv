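name,type,dosimetric_pct,spatial_mm,bound,note
Source air kerma strength,B,1.5,,False,source certificate / well-chamber verification
Dose-response calibration,B,3.5,,False,dose-dependent; bounded above 1.5 Gy
OD readout reproducibility,A,0.3,,False,repeat-scan reproducibility
Scanner reproducibility,A,0.25,,False,flatbed scanner repeatability
Scanner homogeneity,B,0.2,,False,flatbed scanner field homogeneity
Catheter reconstruction,B,,0.6,False,one CT slice thickness
Registration,B,,1.5,False,fiducial-based film-to-CT registration
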