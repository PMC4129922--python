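a: 0.431
alpha1: 16.0
alpha2: 1.9
alpha3: 3.6
alpha4: 0.278
b: 1.02e-09
b1: 3121875.0
c1: 3.177e-13
c2: 3.177e-13
c3: 3.42e-10
d: 0.9
d1: 579579.0
dDL: 0.5
dDU: 0.14
dGT: 0.1
dHT: 0.1
dI10: 20.0
dI2: 12.5
dM: 0.9
dN: 0.0125
dS: 14.3
e: 1.2
g1: 1.2
g2: 20000000.0
gamma1: 0.5
gamma2: 0.022
i1: 4909.0
i2: 1200.0
i3: 2250.0
kDU: 0.05
kET: 0.6
kGT: 0.6
kHT: 0.6
kN: 0.6
kT: 0.9
mE: 526800.0
mG: 175900.0
mH: 1053600.0
omega1: 3500000.0
omega2: 0.5
p: 0.1
p1: 0.00036
p2: 0.0022
p3: 4.2e-05
p4: 3.9e-07
pN: 0.0668
qN: 250360.0
s1: 580000.0
s2: 580000.0
s3: 34000.0
s4: 18000.0
vE: 0.0
vM: 0.0
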