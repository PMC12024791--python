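k1R: 0.008333333333333333
kd1R: 0.008333333333333333
PtaseR: 1.0
k2: 0.03333333333333333
K2: 1.0
kd2: 0.004166666666666667
D2: 0.1
k3F: 0.0004766666666666667
K3: 0.01
K3R: 0.85
kd3: 9.5e-05
D3: 0.5
PtaseNFB: 1.0
k4: 0.03333333333333333
K4: 1.0
kd4: 0.008333333333333333
D4: 1.0
PtaseMEK: 1.0
k5: 0.16666666666666666
K5: 1.0
kd5: 0.0625
D5: 1.0
KNFB: 0.05
PtaseRaf: 1.0
KPFB: 0.01
k6R: 0.6666666666666666
K6: 1.0
kd6: 0.125
D6: 1.0
GAP: 1.0
k7: 0.0016666666666666668
K7: 0.1
kd7: 8.333333333333333e-05
D7: 0.1
PtasePFB: 1.0
duspbasal: 1.0
duspind: 6.0
Kdusp: 0.1
Tdusp: 5400.0
TDUSP: 5400.0
kPFB: 0.0125
ligand_mode: ngf
total_R: 1.0
total_Ras: 1.0
total_Raf: 1.0
total_MEK: 1.0
total_ERK: 1.0
total_NFB: 1.0
total_PFB: 1.0
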