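D0 = 1.0
D1 = 1.0
D2 = 0.2
D3 = 0.2
d0 = 5.0
d1 = 64.0
d2 = 1.1
d3 = 0.6
k1 = 6.0
k2 = 50.0
k3 = 0.6
k4 = 100.0
k9 = 4.0
k10 = 0.1
k11 = 1.4
k12 = 1.0
k13 = 2.0
k14 = 100.0
k21 = 1.65
k23 = 0.01
pp = 1.5957062217694487
R0 = 2.5
k7 = 500.0
k77 = 20.0
pdbasic = 0.49154818451941795
aa = 2.0
ab = 0.4
k15 = 0.4
k16 = 5.0
k17 = 1.1

[numerics]
n_r = 200
dt = 0.01
indicator_width = 0.025
slowdown_delta = 0.05
radius_guard = 0.02
ss_tol = 1e-06
cz_threshold = 0.3884448155802292
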