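population,locus,allele,frequency,two_n
NorthA,A,A*01,0.6000,1000
NorthA,A,A*02,0.3000,1000
NorthA,A,A*03,0.1000,1000
NorthA,DRB1,DRB1*03,0.5500,1000
NorthA,DRB1,DRB1*04,0.3000,1000
NorthA,DRB1,DRB1*07,0.1500,1000
NorthB,A,A*01,0.5800,1000
NorthB,A,A*02,0.3200,1000
NorthB,A,A*03,0.1000,1000
NorthB,DRB1,DRB1*03,0.5700,1000
NorthB,DRB1,DRB1*04,0.2800,1000
NorthB,DRB1,DRB1*07,0.1500,1000
NorthC,A,A*01,0.6200,1000
NorthC,A,A*02,0.2800,1000
NorthC,A,A*03,0.1000,1000
NorthC,DRB1,DRB1*03,0.5300,1000
NorthC,DRB1,DRB1*04,0.3200,1000
NorthC,DRB1,DRB1*07,0.1500,1000
SouthA,A,A*01,0.1000,1000
SouthA,A,A*02,0.3000,1000
SouthA,A,A*03,0.6000,1000
SouthA,DRB1,DRB1*03,0.1500,1000
SouthA,DRB1,DRB1*04,0.3000,1000
SouthA,DRB1,DRB1*07,0.5500,1000
SouthB,A,A*01,0.1200,1000
SouthB,A,A*02,0.2800,1000
SouthB,A,A*03,0.6000,1000
SouthB,DRB1,DRB1*03,0.1500,1000
SouthB,DRB1,DRB1*04,0.2800,1000
SouthB,DRB1,DRB1*07,0.5700,1000
SouthC,A,A*01,0.0800,1000
SouthC,A,A*02,0.3200,1000
SouthC,A,A*03,0.6000,1000
SouthC,DRB1,DRB1*03,0.1500,1000
SouthC,DRB1,DRB1*04,0.3200,1000
SouthC,DRB1,DRB1*07,0.5300,1000
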