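sybyl_type,vdw_radius,well_depth
C.3,1.70,0.107
C.2,1.70,0.107
C.1,1.70,0.107
C.ar,1.70,0.107
C.cat,1.70,0.107
N.3,1.55,0.095
N.2,1.55,0.095
N.1,1.55,0.095
N.ar,1.55,0.095
N.am,1.55,0.095
N.pl3,1.55,0.095
N.4,1.55,0.095
O.3,1.52,0.116
O.2,1.52,0.116
O.co2,1.52,0.116
S.3,1.80,0.314
S.2,1.80,0.314
S.o,1.80,0.314
S.o2,1.80,0.314
P.3,1.80,0.314
H,1.20,0.042
F,1.47,0.109
Cl,1.75,0.314
Br,1.85,0.434
I,1.98,0.623
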