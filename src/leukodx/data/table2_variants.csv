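case,gene,dna_vaf,rna_vaf,fpkm,detected
ALL1,SETD2,29.45,33.33,40.51,true
ALL3,PAX5,38.34,29.81,238.84,true
ALL4,NOTCH3,50.33,-,0.4,false
ALL4,TET2,53.55,34.48,10.6,true
ALL4,PAX5,6.37,13.64,78.66,true
AML1,NOTCH3,52.36,-,1.04,true
AML2,NOTCH3,4.62,-,0.79,false
AML2,RUNX1,43.35,52.94,105.24,true
AML2,RUNX1,45.35,44.20,105.24,true
AML3,NF1,65.3,68.57,27.73,true
MPAL2,TET2,53.33,63.64,14.54,true
MPAL2,NF1,45.9,61.54,6.1,true
MPAL4,SH2B3,47.95,42.86,39.96,true
MPAL4,NOTCH3,48.29,66.67,1.09,true
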