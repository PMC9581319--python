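param,factorA,factorB,mean,sd,n
k,Glera,Omega,70.5,19.3,15
k,Glera,FC,81.8,21.8,15
k,Glera,W&T,79.6,32.3,15
k,Teroldego,Omega,87.7,32.7,15
k,Teroldego,FC,112,34.9,15
k,Teroldego,W&T,108,27.4,15
k,Cabernet Sauvignon,Omega,85.3,20.9,15
k,Cabernet Sauvignon,FC,114,23.2,15
k,Cabernet Sauvignon,W&T,93.9,20.4,15
r,Glera,Omega,0.13,0.02,15
r,Glera,FC,0.12,0.04,15
r,Glera,W&T,0.11,0.03,15
r,Teroldego,Omega,0.13,0.03,15
r,Teroldego,FC,0.12,0.03,15
r,Teroldego,W&T,0.1,0.03,15
r,Cabernet Sauvignon,Omega,0.14,0.03,15
r,Cabernet Sauvignon,FC,0.11,0.02,15
r,Cabernet Sauvignon,W&T,0.13,0.02,15
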