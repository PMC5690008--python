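scan,roi,mean_hu,sd_hu,cnr
pCT,Air 1,68,11,80.7
pCT,Air 2,68,11,80.7
pCT,PMP,853,7,27.0
pCT,LDPE,940,7,16.9
pCT,Polystyrene,994,7,12.7
pCT,Acrylic,1145,9,2.2
pCT,Delrin,1363,9,21.3
pCT,Teflon,1936,10,66.8
Raw CBCT,Air 1,302,21,26.7
Raw CBCT,Air 2,294,23,25.8
Raw CBCT,PMP,834,16,8.3
Raw CBCT,LDPE,901,16,5.5
Raw CBCT,Polystyrene,939,17,3.8
Raw CBCT,Acrylic,1043,19,0.6
Raw CBCT,Delrin,1199,17,7.1
Raw CBCT,Teflon,1621,21,21.7
Scat. Corr.,Air 1,185,22,33.9
Scat. Corr.,Air 2,184,31,26.2
Scat. Corr.,PMP,877,17,9.9
Scat. Corr.,LDPE,958,17,6.6
Scat. Corr.,Polystyrene,1005,18,4.4
Scat. Corr.,Acrylic,1119,17,0.2
Scat. Corr.,Delrin,1327,18,8.8
Scat. Corr.,Teflon,1872,20,28.8
Varian default,Air 1,27,6,34.2
Varian default,Air 2,32,14,31.4
Varian default,PMP,785,30,6.8
Varian default,LDPE,881,34,4.2
Varian default,Polystyrene,940,32,3.0
Varian default,Acrylic,1105,33,0.7
Varian default,Delrin,1321,41,4.9
Varian default,Teflon,1965,37,18.7
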