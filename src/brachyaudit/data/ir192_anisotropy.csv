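# 2D anisotropy function F(r, theta) for a generic Ir-192 line source.
# Rows: radius (cm); columns: polar angle theta (deg) measured from the source axis.
# F(r, 90) = 1 for every radius. Angles > 90 deg are mirrored: F(r, th) = F(r, 180 - th).
radius_cm,0,10,20,30,40,50,60,70,80,90
0.25,0.620,0.770,0.870,0.920,0.950,0.970,0.985,0.995,0.999,1.000
0.50,0.640,0.780,0.880,0.930,0.955,0.975,0.987,0.995,0.999,1.000
1.00,0.660,0.800,0.890,0.935,0.960,0.978,0.989,0.996,0.999,1.000
2.00,0.680,0.810,0.895,0.940,0.963,0.980,0.990,0.996,0.999,1.000
3.00,0.700,0.820,0.900,0.945,0.965,0.981,0.991,0.997,0.999,1.000
5.00,0.720,0.830,0.905,0.950,0.968,0.982,0.991,0.997,0.999,1.000
10.00,0.740,0.840,0.910,0.952,0.970,0.983,0.992,0.997,0.999,1.000
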