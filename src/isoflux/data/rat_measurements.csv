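compartment,N_mmol_per_100g,Delta15N_permil,sd_N,sd_delta
St,0.6,0,0.03,0.1
SIl,1.5,0.3,0.075,0.1
CC,1.6,0.2070707071,0.08,0.1
SIp,1.05,2.3,0.0525,0.1
SIa,0.35,0.3,0.0175,0.1
Lp,12.4,2.45,0.62,0.1
La,1.6,0.35,0.08,0.1
Plp,2.2,3.2,0.11,0.1
Pla,0.85,0.0455732344,0.0425,0.1
Mp,95,3.8,4.75,0.1
Ma,5.5,-1,0.275,0.1
Kp,3.2,1.3,0.16,0.1
Ka,0.45,0.7,0.0225,0.1
Hp,1.9,4.6,0.095,0.1
Ha,0.22,0.5,0.011,0.1
Rp,11.5,3.4,0.575,0.1
Ra,1.1,0.4,0.055,0.1
Skp,52,3.2,2.6,0.1
Ska,2.4,1.2,0.12,0.1
Hair,14,1.2,0.7,0.1
U,2.4,-0.6,0.12,0.1
urine_urea,,0,,0.1
urine_NH4,,-1.5,,0.1
feces,,0.2070707071,,0.1
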