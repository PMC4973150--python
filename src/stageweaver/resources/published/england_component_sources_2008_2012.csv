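site,component,source,variable,completeness_count,completeness_pct,contribution_count,contribution_pct
colorectal,T,audit,pT,32648,19.9,32017,19.5
colorectal,T,audit,serosal_involvement_or_perforation,5209,3.2,710,0.4
colorectal,T,central,pT,77997,47.6,52761,32.2
colorectal,T,audit,cT,48204,29.4,16113,9.8
colorectal,T,audit,mri_T,22056,13.5,2295,1.4
colorectal,T,central,cT,5773,3.5,754,0.5
colorectal,T,central,iT,104047,63.5,11358,6.9
colorectal,T,,missing,,,47907,29.2
colorectal,N,audit,pN,32666,19.9,32518,19.8
colorectal,N,audit,positive_node_count,14523,8.9,310,0.2
colorectal,N,central,pN,74212,45.3,49351,30.1
colorectal,N,central,positive_node_count,35695,21.8,4656,2.8
colorectal,N,audit,cN,50108,30.6,16141,9.9
colorectal,N,audit,mri_N,20387,12.4,1319,0.8
colorectal,N,central,cN,6576,4.0,1261,0.8
colorectal,N,central,iN,101453,61.9,9574,5.8
colorectal,N,,missing,,,48785,29.8
colorectal,M,audit,cM,51542,31.4,50548,30.8
colorectal,M,audit,distant_metastasis,17890,10.9,8727,5.3
colorectal,M,audit,liver_ct,75714,46.2,1064,0.6
colorectal,M,central,cM,13212,8.1,6548,4.0
colorectal,M,audit,pM,10333,6.3,3248,2.0
colorectal,M,central,pM,10936,6.7,4170,2.5
colorectal,M,central,iM,67948,41.5,18800,11.5
colorectal,M,derived,clinical_examination,,,3294,2.0
colorectal,M,,missing,,,67516,41.2
colorectal,stage,audit,dukes_p,30239,18.4,2206,1.3
colorectal,stage,audit,dukes_c,80036,48.8,1098,0.7
colorectal,stage,central,pStage,4351,2.7,38,<0.01
colorectal,stage,central,cStage,508,0.3,5,<0.01
colorectal,stage,central,iStage,57596,35.1,1189,0.7
colorectal,stage,central,dukes,108105,66.0,4003,2.4
lung,T,audit,pT,15427,9.2,15427,9.2
lung,T,central,pT,14933,8.9,5970,3.6
lung,T,audit,cT,107171,63.7,89265,53.1
lung,T,central,cT,7952,4.7,1217,0.7
lung,T,central,iT,91917,54.7,11437,6.8
lung,T,,missing,,,44842,26.7
lung,N,audit,pN,15177,9.0,15177,9.0
lung,N,central,pN,15180,9.0,6914,4.1
lung,N,central,positive_node_count,3511,2.1,841,0.5
lung,N,audit,cN,107300,63.8,88336,52.5
lung,N,central,cN,8085,4.8,1274,0.8
lung,N,central,iN,91693,54.5,11349,6.7
lung,N,,missing,,,44267,26.3
lung,M,audit,cM,107057,63.7,107057,63.7
lung,M,central,cM,8987,5.3,1894,1.1
lung,M,audit,pM,10845,6.4,648,0.4
lung,M,central,pM,9675,5.8,2944,1.8
lung,M,central,iM,92930,55.3,14197,8.4
lung,M,derived,clinical_examination,,,3056,1.8
lung,M,,missing,,,38362,22.8
lung,stage,audit,pStage,16946,10.1,20,<0.01
lung,stage,audit,cStage,105410,62.7,485,0.3
lung,stage,central,pStage,2117,1.3,41,<0.01
lung,stage,central,cStage,679,0.4,7,<0.01
lung,stage,central,iStage,85267,50.7,1520,0.9
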