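haplotype,frequency,sd,dprime,chi2
DRB1*03~DQB1*02,0.2125,0.0205,0.93,204.69
DRB1*16~DQB1*05,0.1725,0.0189,0.96,187.82
DRB1*01~DQB1*05,0.0450,0.0104,1.00,44.51
DRB1*04~DQB1*03,0.0875,0.0141,0.82,119.94
DRB1*15~DQB1*06,0.0850,0.0140,0.85,192.21
B*35~C*04,0.1175,0.0161,0.83,238.26
B*14~C*08,0.0450,0.0104,1.00,400.00
B*50~C*06,0.0800,0.0136,0.96,210.04
B*08~DRB1*03,0.0975,0.0148,0.80,117.49
A*02~B*51,0.0750,0.0132,0.21,14.72
A*26~B*08,0.0525,0.0112,0.53,85.26
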