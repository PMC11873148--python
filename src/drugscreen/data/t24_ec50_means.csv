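drug,cell_line,ec50_mean_uM,ec50_sem_uM
Berzosertib,Control A6,1.936,0.2246
Berzosertib,STAG2 KO G2,1.033,0.1367
Berzosertib,STAG2 KO H2,0.7738,0.1474
PI-103,Control A6,0.3269,0.07084
PI-103,STAG2 KO G2,0.9653,0.4807
PI-103,STAG2 KO H2,1.416,0.2284
Prexasertib,Control A6,1.443,0.1758
Prexasertib,STAG2 KO G2,2.182,0.3476
Prexasertib,STAG2 KO H2,1.446,0.1872
Rigosertib,Control A6,0.03457,0.008127
Rigosertib,STAG2 KO G2,0.03118,0.005892
Rigosertib,STAG2 KO H2,0.03039,0.004357
TAK-733,Control A6,0.003291,0.003291
TAK-733,STAG2 KO G2,0.001842,0.001461
TAK-733,STAG2 KO H2,0.001788,0.001788
Olaparib,Control A6,79.95,3.83
Olaparib,STAG2 KO G2,19.3,2.326
Olaparib,STAG2 KO H2,11.52,0.8954
Talazoparib,Control A6,0.3487,0.07194
Talazoparib,STAG2 KO G2,0.4626,0.126
Talazoparib,STAG2 KO H2,0.3282,0.1258
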