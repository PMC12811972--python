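# Radial dose function g(r) for a generic Ir-192 line source (L = 0.35 cm).
# Consensus-style values; editable configuration, not code. g(1 cm) = 1 by definition.
radius_cm,g
0.10,0.988
0.15,0.991
0.25,0.994
0.50,0.997
0.75,0.999
1.00,1.000
1.50,1.001
2.00,1.001
3.00,0.999
4.00,0.993
5.00,0.984
6.00,0.973
8.00,0.942
10.00,0.900
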