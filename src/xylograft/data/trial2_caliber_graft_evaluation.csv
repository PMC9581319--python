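stratum_time,label,callogenesis,involvement,callus_type,external_callus,necrosis,space,printed_rank
T1,Omega-Thin,1,"2a, 1b, 1d, 1c",0,0,np,Yes,3
T1,Omega-Thick,1,"3a, 2c, 2d",0,0,np,Yes,2
T1,W&T-Thin,1,"1a, 2b, 3c",0,0,S e R,No,5
T1,W&T-Thick,1,"3a, 1b, 2c",0,0,S e R,Yes,5
T1,FC-Thin,2,"3a, 3c, 2d",1,0,np,No,1
T1,FC-Thick,1,"3a, 2c, 2d",0,0,np,No,2
T3,Omega-Thin,4,"3a, 3b, 3c, 3d",1,1,S,No,1
T3,Omega-Thick,3,"3a, 3b, 3c, 3d",2,1,S and R,Yes,2
T3,W&T-Thin,2,"3a, 3b, 3c, 3d",1; -1,1,S and R,Yes,4
T3,W&T-Thick,3,"3a, 3b, 3c, 3d",1; -1,1,R,Yes,3
T3,FC-Thin,3,"3a, 3b, 3c, 3d",1; -1,1,R,Yes,3
T3,FC-Thick,3,"3a, 3b, 3c, 3d",1; -1,1,R,No,3
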