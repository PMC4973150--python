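site,edition,component,code,rank
colorectal,5th,T,T0,0
colorectal,5th,T,Tis,1
colorectal,5th,T,T1,2
colorectal,5th,T,T2,3
colorectal,5th,T,T3,4
colorectal,5th,T,T4,5
colorectal,5th,N,N0,0
colorectal,5th,N,N1,1
colorectal,5th,N,N2,2
colorectal,5th,M,M0,0
colorectal,5th,M,M1,1
colorectal,7th,T,T0,0
colorectal,7th,T,Tis,1
colorectal,7th,T,T1,2
colorectal,7th,T,T2,3
colorectal,7th,T,T3,4
colorectal,7th,T,T4,5
colorectal,7th,T,T4a,6
colorectal,7th,T,T4b,7
colorectal,7th,N,N0,0
colorectal,7th,N,N1,1
colorectal,7th,N,N1a,2
colorectal,7th,N,N1b,3
colorectal,7th,N,N1c,4
colorectal,7th,N,N2,5
colorectal,7th,N,N2a,6
colorectal,7th,N,N2b,7
colorectal,7th,M,M0,0
colorectal,7th,M,M1,1
colorectal,7th,M,M1a,2
colorectal,7th,M,M1b,3
lung,6th,T,T0,0
lung,6th,T,Tis,1
lung,6th,T,T1,2
lung,6th,T,T2,3
lung,6th,T,T3,4
lung,6th,T,T4,5
lung,6th,N,N0,0
lung,6th,N,N1,1
lung,6th,N,N2,2
lung,6th,N,N3,3
lung,6th,M,M0,0
lung,6th,M,M1,1
lung,7th,T,T0,0
lung,7th,T,Tis,1
lung,7th,T,T1,2
lung,7th,T,T1a,3
lung,7th,T,T1b,4
lung,7th,T,T2,5
lung,7th,T,T2a,6
lung,7th,T,T2b,7
lung,7th,T,T3,8
lung,7th,T,T4,9
lung,7th,N,N0,0
lung,7th,N,N1,1
lung,7th,N,N2,2
lung,7th,N,N3,3
lung,7th,M,M0,0
lung,7th,M,M1,1
lung,7th,M,M1a,2
lung,7th,M,M1b,3
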