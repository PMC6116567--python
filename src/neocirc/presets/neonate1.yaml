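# Preterm subject 1: haemoglobin 17.08 g/dL -> 10.592248062015502 mM haem,
# baseline SpO2 95 %.  All other values from the preterm population preset.
CBF_n: 19.8
CCO_tis: 2.2
CuA_frac_n: 0.67
CMRO2_n: 40.865
P_a_n: 30.0
Hbtot: 10.592248062015502
V_blood_n: 0.0233
P_ic_n: 5.1
SaO2_n: 0.95
PaCO2_n: 40.0
R_P: 2.5
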