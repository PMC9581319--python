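stratum_cultivar,stratum_time,label,callogenesis,involvement,callus_type,external_callus,necrosis,space,printed_rank
Glera,T1,Omega,3,"3a, 3b, 3c, 3d",0,0,np,Yes,1
Glera,T1,W&T,2,"3a, 3b, 3c, 3d",0,0,np,Yes,2
Glera,T1,FC,2,"3a, 2b, 3c, 3d",0,0,np,Yes,3
Glera,T3,Omega,4,"3a, 3b, 3c, 3d",1,1,"S, R",Yes,1
Glera,T3,W&T,3,"2a, 3b, 2c, 3d",1,1,"S, R",Yes,2
Glera,T3,FC,3,"3a, 3b, 3c, 3d",1; -1,1,"S, R",Yes,3
Cabernet Sauvignon,T1,Omega,3,"3a, 3b, 3c, 3d",0,0,np,Yes,1
Cabernet Sauvignon,T1,W&T,2,"3a, 3b, 3c, 3d",0,0,np,Yes,2
Cabernet Sauvignon,T1,FC,3,"3a, 3b, 3c, 3d",0,0,np,Yes,1
Cabernet Sauvignon,T3,Omega,4,"3a, 3b, 3c, 3d",1,1,"S, R",No,2
Cabernet Sauvignon,T3,W&T,4,"3a, 3b, 3c, 3d",1,1,"S, R",No,1
Cabernet Sauvignon,T3,FC,2,"3a, 3b, 3c, 3d",1; -1,1,"S, R",Yes,3
Teroldego,T1,Omega,2,"1a, 1b, 3c, 3d",0,0,np,Yes,2
Teroldego,T1,W&T,3,"1a, 3b, 3c, 3d",0,0,np,Yes,1
Teroldego,T1,FC,2,"2a, 2b, 3c, 3d",0,0,np,Yes,2
Teroldego,T3,Omega,3,"3a, 3b, 3c, 3d",2; -1,1,S,Yes,2
Teroldego,T3,W&T,4,"3a, 3b, 3c, 3d",2; -1,1,S,Yes,1
Teroldego,T3,FC,2,"3a, 3b, 3c, 3d",2; -1,1,"S, R",Yes,3
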