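population,locus,allele,frequency,sd,two_n
Emirati,A,A*02,0.2225,0.0208,400
Emirati,A,A*11,0.0950,0.0147,400
Emirati,A,A*26,0.0900,0.0143,400
Emirati,A,A*01,0.0850,0.0140,400
Emirati,A,A*03,0.0800,0.0136,400
Emirati,A,A*24,0.0775,0.0134,400
Emirati,A,A*32,0.0750,0.0132,400
Emirati,A,A*33,0.0675,0.0126,400
Emirati,A,A*68,0.0675,0.0126,400
Emirati,A,A*30,0.0550,0.0114,400
Emirati,A,A*31,0.0300,0.0085,400
Emirati,A,A*23,0.0250,0.0078,400
Emirati,A,A*74,0.0100,0.0050,400
Emirati,A,A*66,0.0075,0.0043,400
Emirati,A,A*34,0.0050,0.0035,400
Emirati,A,A*29,0.0050,0.0035,400
Emirati,A,A*69,0.0025,0.0025,400
Emirati,C,C*07,0.2000,0.0200,400
Emirati,C,C*04,0.1550,0.0181,400
Emirati,C,C*06,0.1375,0.0172,400
Emirati,C,C*15,0.1300,0.0168,400
Emirati,C,C*12,0.0900,0.0143,400
Emirati,C,C*03,0.0675,0.0126,400
Emirati,C,C*16,0.0675,0.0126,400
Emirati,C,C*08,0.0450,0.0104,400
Emirati,C,C*14,0.0300,0.0085,400
Emirati,C,C*02,0.0300,0.0085,400
Emirati,C,C*17,0.0275,0.0082,400
Emirati,C,C*01,0.0125,0.0056,400
Emirati,C,C*05,0.0050,0.0035,400
Emirati,C,C*18,0.0025,0.0025,400
Emirati,B,B*51,0.1950,0.0198,400
Emirati,B,B*35,0.1375,0.0172,400
Emirati,B,B*08,0.1150,0.0160,400
Emirati,B,B*50,0.0825,0.0138,400
Emirati,B,B*58,0.0575,0.0117,400
Emirati,B,B*40,0.0500,0.0109,400
Emirati,B,B*14,0.0450,0.0104,400
Emirati,B,B*52,0.0350,0.0092,400
Emirati,B,B*18,0.0325,0.0089,400
Emirati,B,B*15,0.0300,0.0085,400
Emirati,B,B*41,0.0250,0.0078,400
Emirati,B,B*53,0.0225,0.0074,400
Emirati,B,B*37,0.0200,0.0070,400
Emirati,B,B*73,0.0175,0.0066,400
Emirati,B,B*57,0.0175,0.0066,400
Emirati,B,B*07,0.0175,0.0066,400
Emirati,B,B*49,0.0175,0.0066,400
Emirati,B,B*44,0.0150,0.0061,400
Emirati,B,B*38,0.0125,0.0056,400
Emirati,B,B*42,0.0125,0.0056,400
Emirati,B,B*27,0.0100,0.0050,400
Emirati,B,B*45,0.0100,0.0050,400
Emirati,B,B*13,0.0075,0.0043,400
Emirati,B,B*39,0.0050,0.0035,400
Emirati,B,B*56,0.0025,0.0025,400
Emirati,B,B*47,0.0025,0.0025,400
Emirati,B,B*81,0.0025,0.0025,400
Emirati,B,B*55,0.0025,0.0025,400
Emirati,DRB1,DRB1*03,0.2225,0.0208,400
Emirati,DRB1,DRB1*16,0.1775,0.0191,400
Emirati,DRB1,DRB1*07,0.1275,0.0167,400
Emirati,DRB1,DRB1*04,0.1025,0.0152,400
Emirati,DRB1,DRB1*15,0.0975,0.0149,400
Emirati,DRB1,DRB1*11,0.0700,0.0128,400
Emirati,DRB1,DRB1*13,0.0550,0.0114,400
Emirati,DRB1,DRB1*01,0.0450,0.0104,400
Emirati,DRB1,DRB1*10,0.0375,0.0095,400
Emirati,DRB1,DRB1*08,0.0225,0.0074,400
Emirati,DRB1,DRB1*14,0.0225,0.0074,400
Emirati,DRB1,DRB1*12,0.0125,0.0056,400
Emirati,DRB1,DRB1*09,0.0075,0.0043,400
Emirati,DQB1,DQB1*02,0.3275,0.0235,400
Emirati,DQB1,DQB1*05,0.2975,0.0229,400
Emirati,DQB1,DQB1*03,0.2025,0.0201,400
Emirati,DQB1,DQB1*06,0.1400,0.0174,400
Emirati,DQB1,DQB1*04,0.0325,0.0089,400
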