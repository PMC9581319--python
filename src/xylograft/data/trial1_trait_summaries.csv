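trait,factorA,factorB,mean,sd,n
necrosis_percent,Glera,W&T,56.6,1.8,3
necrosis_percent,Glera,Omega,36.1,3,3
necrosis_percent,Glera,FC,31.1,1.4,3
necrosis_percent,Teroldego,W&T,30.9,7.6,3
necrosis_percent,Teroldego,Omega,37.3,4.2,3
necrosis_percent,Teroldego,FC,63,0.9,3
necrosis_percent,Cabernet Sauvignon,W&T,20.2,3.1,3
necrosis_percent,Cabernet Sauvignon,Omega,21.7,4.2,3
necrosis_percent,Cabernet Sauvignon,FC,43.8,1,3
vd,Glera,W&T,101,15.1,5
vd,Glera,Omega,137,30.3,5
vd,Glera,FC,125,18.3,5
vd,Teroldego,W&T,130,24.9,5
vd,Teroldego,Omega,110,21.2,5
vd,Teroldego,FC,125,29.2,5
vd,Cabernet Sauvignon,W&T,97.9,4.7,5
vd,Cabernet Sauvignon,Omega,112,23.7,5
vd,Cabernet Sauvignon,FC,85.2,6.5,5
vaf,Glera,W&T,23.7,3.7,5
vaf,Glera,Omega,22.1,1.6,5
vaf,Glera,FC,21.5,2.8,5
vaf,Teroldego,W&T,21,3.7,5
vaf,Teroldego,Omega,17.8,1.4,5
vaf,Teroldego,FC,20.2,2.2,5
vaf,Cabernet Sauvignon,W&T,18.6,1.3,5
vaf,Cabernet Sauvignon,Omega,18.7,2.9,5
vaf,Cabernet Sauvignon,FC,18.6,3.2,5
dh,Glera,W&T,31.6,3.1,5
dh,Glera,Omega,25.7,2.6,5
dh,Glera,FC,27.4,2.2,5
dh,Teroldego,W&T,26.3,4.1,5
dh,Teroldego,Omega,26.4,2.7,5
dh,Teroldego,FC,25.7,4.1,5
dh,Cabernet Sauvignon,W&T,27.8,2.8,5
dh,Cabernet Sauvignon,Omega,27,3.6,5
dh,Cabernet Sauvignon,FC,30.9,3,5
kst,Glera,W&T,34.5,7.4,5
kst,Glera,Omega,32.1,14.5,5
kst,Glera,FC,39.9,11.1,5
kst,Teroldego,W&T,41.1,12.7,5
kst,Teroldego,Omega,31,6.8,5
kst,Teroldego,FC,31.5,7.5,5
kst,Cabernet Sauvignon,W&T,28.9,9.2,5
kst,Cabernet Sauvignon,Omega,26,7.2,5
kst,Cabernet Sauvignon,FC,33.8,14.6,5
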