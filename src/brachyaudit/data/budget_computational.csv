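name,type,dosimetric_pct,spatial_mm,bound,note
MC statistics,A,2.5,,True,upper bound; statistical uncertainty 4 cm from the catheters
Source emission and transport data,B,0.3,,False,systematic transport/cross-section uncertainty
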