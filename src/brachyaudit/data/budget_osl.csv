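name,type,dosimetric_pct,spatial_mm,bound,note
Source air kerma strength,B,1.5,,False,source certificate / well-chamber verification
Dose-response calibration (linac output),B,1.5,,False,overall linac output calibration uncertainty
Session specific ND_w,A,1.4,,False,one standard deviation of the mean response of the nine standards
Reader stability,A,0.8,,False,reference light variation of the OSLD reader
Element sensitivity factor ks_i,B,0.7,,False,batch characterization
Linearity correction factor kL,B,1.7,,False,batch characterization
Angular correction factor ktheta,B,1.4,,False,en-face orientation study
Volume averaging correction factor kvol,A,0.8,,False,statistical uncertainty of the volume-averaging calculation
Beam quality correction factor kQ,B,2.5,,False,combined uncertainty of the beam-quality side study
Catheter reconstruction,B,,0.6,False,one CT slice thickness
Active volume localization,B,,0.5,False,chip localization study
Centroid determination,B,,0.12,False,centroid determination study
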