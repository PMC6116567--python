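# Adult population preset (published normal values).
CBF_n: 49.0
CCO_tis: 5.5
CuA_frac_n: 0.8
CMRO2_n: 155.0
P_a_n: 100.0
Hbtot: 9.1
V_blood_n: 0.04
P_ic_n: 9.5
SaO2_n: 0.96
PaCO2_n: 40.0
R_P: 3.0
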