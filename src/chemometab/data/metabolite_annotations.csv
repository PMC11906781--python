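feature_id,metabolite,hmdb_id,rt_min,calc_mw,observed_mz,formula,adduct,printed_ppm,pathway_ids,loading_pc1,loading_pc2,vip_score,quadrant
C123,N-Acylsphingosine,HMDB0011773,0.748,509.47983,510.48709,C32H63NO3,[M+H]+,-1.91,1,0.003597256,-0.001319728,1.185327,right
C403,Sphingosine 1-phosphate,HMDB0000277,3.129,379.24834,380.25561,C18H38NO5P,[M+H]+,-1.11,1,,,1.366234,
C688,Hypotaurine,HMDB0000965,4.137,109.01943,110.0267,C2H7NO2S,[M+H]+,-2.96,2,-0.003185744,0.000440457,1.220676,left
C749,L-Cystine,HMDB0000192,5.24,240.02355,241.03082,C6H12N2O4S2,[M+H]+,-1.26,4,0.00354993,-0.000771474,1.019291,right
C671,Glutamic acid,HMDB0000148,3.996,147.05295,148.06022,C5H9NO4,[M+H]+,-1.42,3,-0.00387789,-0.00037018,1.001649,down
C733,Ethanolamine phosphate,HMDB0000224,4.723,141.01893,142.02621,C2H8NO4P,[M+H]+,-1.13,"1;5",-0.00379413,-0.000386708,1.051176,down
C681,Ophthalmate,HMDB0005765,4.03,289.12702,290.13429,C11H19N3O6,[M+H]+,-1.27,4,-0.003254398,-6.39909E-05,1.425411,down
C718,sn-Glycero-3-phosphocholine,HMDB0000086,4.433,257.10247,258.10975,C8H20NO6P,[M+H]+,-1.36,5,0.001894981,-0.003769861,1.426471,right
C240,Sphinganine,HMDB0000269,1.522,301.29768,302.30496,C18H39NO2,[M+H]+,-1.32,1,-0.001778901,0.003479727,1.461257,left
C633,Taurine,HMDB0000251,3.832,125.0144,126.0217,C2H7NO3S,[M+H]+,-1.43,2,-0.003428438,0.001303504,1.230748,left
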