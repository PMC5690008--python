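mu_low,mu_high,material,mu_mat,rho_mat
0.0,2.5e-4,Vacuum,0.0,0.0
2.5e-4,0.09,Air,5.18e-4,1.205e-3
0.09,0.189,PMP,0.178,0.83
0.189,0.209,LDPE,0.200,0.93
0.209,0.23,Polystyrene,0.217,1.06
0.23,0.251,Water,0.243,1.00
0.251,0.287,Acrylic,0.259,1.19
0.287,0.4,Delrin,0.315,1.41
0.4,inf,Teflon,0.485,2.10
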