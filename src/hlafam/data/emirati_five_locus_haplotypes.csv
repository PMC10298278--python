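haplotype,frequency,sd
A*26~B*08~C*07~DRB1*03~DQB1*02,0.0425,0.0101
A*02~B*50~C*06~DRB1*07~DQB1*02,0.0150,0.0061
A*03~B*52~C*12~DRB1*15~DQB1*06,0.0150,0.0061
A*02~B*08~C*07~DRB1*03~DQB1*02,0.0150,0.0061
A*24~B*08~C*07~DRB1*03~DQB1*02,0.0150,0.0061
A*01~B*51~C*15~DRB1*03~DQB1*02,0.0125,0.0056
A*33~B*14~C*08~DRB1*01~DQB1*05,0.0125,0.0056
A*02~B*51~C*15~DRB1*04~DQB1*03,0.0125,0.0056
A*11~B*40~C*15~DRB1*16~DQB1*05,0.0125,0.0056
A*33~B*58~C*03~DRB1*03~DQB1*02,0.0100,0.0050
A*68~B*14~C*08~DRB1*07~DQB1*02,0.0100,0.0050
A*33~B*58~C*03~DRB1*16~DQB1*05,0.0100,0.0050
A*02~B*35~C*04~DRB1*16~DQB1*05,0.0100,0.0050
A*11~B*51~C*07~DRB1*16~DQB1*05,0.0100,0.0050
A*32~B*08~C*07~DRB1*03~DQB1*02,0.0100,0.0050
A*01~B*37~C*06~DRB1*10~DQB1*05,0.0100,0.0050
A*11~B*41~C*07~DRB1*08~DQB1*03,0.0100,0.0050
A*03~B*50~C*06~DRB1*07~DQB1*02,0.0075,0.0043
A*68~B*35~C*04~DRB1*04~DQB1*03,0.0075,0.0043
A*03~B*50~C*06~DRB1*04~DQB1*04,0.0075,0.0043
A*01~B*58~C*03~DRB1*03~DQB1*02,0.0075,0.0043
A*26~B*51~C*14~DRB1*15~DQB1*06,0.0075,0.0043
A*11~B*40~C*15~DRB1*03~DQB1*02,0.0075,0.0043
A*32~B*18~C*12~DRB1*16~DQB1*05,0.0075,0.0043
A*02~B*51~C*16~DRB1*16~DQB1*05,0.0075,0.0043
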