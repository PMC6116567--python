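# Preterm neonatal population preset (published normal values).
# R_P is reduced relative to the adult: at the low preterm operating
# pressure the same tone gain over-compensates, and 2.5 yields a narrow
# but genuine autoregulation plateau around P_a_n.
CBF_n: 19.8
CCO_tis: 2.2
CuA_frac_n: 0.67
CMRO2_n: 40.865
P_a_n: 30.0
Hbtot: 9.75
V_blood_n: 0.0233
P_ic_n: 5.1
SaO2_n: 0.96
PaCO2_n: 40.0
R_P: 2.5
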