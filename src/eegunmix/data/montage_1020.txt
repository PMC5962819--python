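# 10-20 montage, 19 channels, unit sphere (x=nasion, y=left, z=vertex)
# Ring electrodes at 90 deg inclination, midline/central at 45 deg;
# F3/F4/P3/P4 are spherical midpoints of (Fz,F7)/(Fz,F8)/(Pz,T5)/(Pz,T6).
# label x y z
Fp1 +0.951056516295 +0.309016994375 +0.000000000000
Fp2 +0.951056516295 -0.309016994375 +0.000000000000
F7 +0.587785252292 +0.809016994375 +0.000000000000
F3 +0.769562952291 +0.480804183321 +0.420238265466
Fz +0.707106781187 +0.000000000000 +0.707106781187
F4 +0.769562952291 -0.480804183321 +0.420238265466
F8 +0.587785252292 -0.809016994375 +0.000000000000
T3 +0.000000000000 +1.000000000000 +0.000000000000
C3 +0.000000000000 +0.707106781187 +0.707106781187
Cz +0.000000000000 +0.000000000000 +1.000000000000
C4 +0.000000000000 -0.707106781187 +0.707106781187
T4 +0.000000000000 -1.000000000000 +0.000000000000
T5 -0.587785252292 +0.809016994375 +0.000000000000
P3 -0.769562952291 +0.480804183321 +0.420238265466
Pz -0.707106781187 +0.000000000000 +0.707106781187
P4 -0.769562952291 -0.480804183321 +0.420238265466
T6 -0.587785252292 -0.809016994375 +0.000000000000
O1 -0.951056516295 +0.309016994375 +0.000000000000
O2 -0.951056516295 -0.309016994375 +0.000000000000
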