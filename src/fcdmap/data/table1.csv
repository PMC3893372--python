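group,pair,atp_case,age,sex,seizures
asd,1,UMB-1627,5.0,F,N
asd,2,AN13961,7.5,M,Y
asd,3,AN00754,13.–,M,Y
asd,4,IBR-425-02,4.2,M,N
asd,5,AN19511,8.–,M,N
asd,6,AN02338,17.2,F,N
asd,7,AN09730,22.9,M,Y
control,1,UMB-1499,4.5,F,N
control,2,UMB-4898,7.7,M,N
control,3,BTB-3638,14.3,M,N
control,4,AN02456,4.–,F,N
control,5,UMB-1708,8.1,F,N
control,6,UMB-1843,15.9,F,N
control,7,UMB-1646,23.2,M,N
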