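source,label,statistic,printed,exact
registration_mandible,Attempts,mean_sd,1.45 ± 0.69,1
registration_mandible,FRE,mean_sd,1.15 ± 0.25,1
registration_mandible,TRE_CONDYLE,mean_sd,0.91 ± 0.2,0
registration_mandible,TRE_CENTER,mean_sd,0.81 ± 0.2,1
registration_graft,Attempts,mean_sd,2.73 ± 3,1
registration_graft,FRE,mean_sd,1.94 ± 0.76,1
registration_graft,TRE_CONDYLE,mean_sd,1.1 ± 0.38,1
registration_graft,TRE_CENTER,mean_sd,0.77 ± 0.26,1
cbct,Tx_total,mean_sd,2.16 ± 1.1,1
cbct,CON,mean_sd,2.95 ± 1.59,1
cbct,ANG,mean_sd,2.37 ± 1.4,1
cbct,JUN,mean_sd,1.13 ± 0.75,1
navigation,CON,mean_sd,2.41 ± 2.32,1
navigation,ANG,mean_sd,1.92 ± 1.32,1
navigation,JUN,mean_sd,2.08 ± 1.41,0
agreement,CON,pearson_r,0.83,1
agreement,ANG,pearson_r,0.74,1
agreement,JUN,pearson_r,0.44,0
agreement,CON,loa,-3.2 / 2.1,1
agreement,ANG,loa,-2.4 / 1.5,1
agreement,JUN,loa,-1.5 / 3.5,0
agreement,JUN,max_abs_diff,3.57,1
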