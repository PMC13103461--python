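case_id,label,source,value
1,Attempts,registration_mandible,3
2,Attempts,registration_mandible,1
3,Attempts,registration_mandible,1
4,Attempts,registration_mandible,2
5,Attempts,registration_mandible,1
6,Attempts,registration_mandible,1
7,Attempts,registration_mandible,2
8,Attempts,registration_mandible,2
9,Attempts,registration_mandible,1
10,Attempts,registration_mandible,1
11,Attempts,registration_mandible,1
1,FRE,registration_mandible,1.17
2,FRE,registration_mandible,1.42
3,FRE,registration_mandible,1.44
4,FRE,registration_mandible,1.35
5,FRE,registration_mandible,1.14
6,FRE,registration_mandible,0.9
7,FRE,registration_mandible,0.86
8,FRE,registration_mandible,1.14
9,FRE,registration_mandible,1.48
10,FRE,registration_mandible,1.08
11,FRE,registration_mandible,0.72
1,TRE_CONDYLE,registration_mandible,0.94
2,TRE_CONDYLE,registration_mandible,1.14
3,TRE_CONDYLE,registration_mandible,1.13
4,TRE_CONDYLE,registration_mandible,1.10
5,TRE_CONDYLE,registration_mandible,0.84
6,TRE_CONDYLE,registration_mandible,0.74
7,TRE_CONDYLE,registration_mandible,0.62
8,TRE_CONDYLE,registration_mandible,0.84
9,TRE_CONDYLE,registration_mandible,1.12
10,TRE_CONDYLE,registration_mandible,0.88
11,TRE_CONDYLE,registration_mandible,0.59
1,TRE_CENTER,registration_mandible,0.88
2,TRE_CENTER,registration_mandible,1.06
3,TRE_CENTER,registration_mandible,1.09
4,TRE_CENTER,registration_mandible,0.95
5,TRE_CENTER,registration_mandible,0.67
6,TRE_CENTER,registration_mandible,0.68
7,TRE_CENTER,registration_mandible,0.49
8,TRE_CENTER,registration_mandible,0.73
9,TRE_CENTER,registration_mandible,0.93
10,TRE_CENTER,registration_mandible,0.86
11,TRE_CENTER,registration_mandible,0.56
1,Attempts,registration_graft,9
2,Attempts,registration_graft,2
3,Attempts,registration_graft,1
4,Attempts,registration_graft,1
5,Attempts,registration_graft,4
6,Attempts,registration_graft,1
7,Attempts,registration_graft,1
8,Attempts,registration_graft,1
9,Attempts,registration_graft,8
10,Attempts,registration_graft,1
11,Attempts,registration_graft,1
1,FRE,registration_graft,1.51
2,FRE,registration_graft,1.91
3,FRE,registration_graft,1.32
4,FRE,registration_graft,2.01
5,FRE,registration_graft,2.44
6,FRE,registration_graft,1.51
7,FRE,registration_graft,4.0
8,FRE,registration_graft,1.94
9,FRE,registration_graft,1.35
10,FRE,registration_graft,1.64
11,FRE,registration_graft,1.73
1,TRE_CONDYLE,registration_graft,1.25
2,TRE_CONDYLE,registration_graft,1.19
3,TRE_CONDYLE,registration_graft,0.74
4,TRE_CONDYLE,registration_graft,0.99
5,TRE_CONDYLE,registration_graft,1.26
6,TRE_CONDYLE,registration_graft,0.79
7,TRE_CONDYLE,registration_graft,2.12
8,TRE_CONDYLE,registration_graft,1.03
9,TRE_CONDYLE,registration_graft,0.8
10,TRE_CONDYLE,registration_graft,0.97
11,TRE_CONDYLE,registration_graft,0.97
1,TRE_CENTER,registration_graft,0.88
2,TRE_CENTER,registration_graft,0.9
3,TRE_CENTER,registration_graft,0.57
4,TRE_CENTER,registration_graft,0.63
5,TRE_CENTER,registration_graft,0.86
6,TRE_CENTER,registration_graft,0.52
7,TRE_CENTER,registration_graft,1.44
8,TRE_CENTER,registration_graft,0.76
9,TRE_CENTER,registration_graft,0.55
10,TRE_CENTER,registration_graft,0.69
11,TRE_CENTER,registration_graft,0.68
1,Tx_total,cbct,1.39
2,Tx_total,cbct,1.82
3,Tx_total,cbct,3.42
4,Tx_total,cbct,4.13
5,Tx_total,cbct,1.96
6,Tx_total,cbct,1.5
7,Tx_total,cbct,3.87
8,Tx_total,cbct,1.35
9,Tx_total,cbct,1.54
10,Tx_total,cbct,1.8
11,Tx_total,cbct,1.02
1,Segment_1,cbct,1.79
2,Segment_1,cbct,1.56
3,Segment_1,cbct,3.86
4,Segment_1,cbct,6.08
5,Segment_1,cbct,1.86
6,Segment_1,cbct,2.18
7,Segment_1,cbct,3.82
8,Segment_1,cbct,1.49
9,Segment_1,cbct,1.94
10,Segment_1,cbct,1.93
11,Segment_1,cbct,1.06
1,Segment_2,cbct,0.81
2,Segment_2,cbct,2.02
3,Segment_2,cbct,3.06
4,Segment_2,cbct,3.86
5,Segment_2,cbct,1.96
6,Segment_2,cbct,1.15
7,Segment_2,cbct,3.98
8,Segment_2,cbct,1.23
9,Segment_2,cbct,1.13
10,Segment_2,cbct,1.65
11,Segment_2,cbct,0.98
4,Segment_3,cbct,1.43
5,Segment_3,cbct,2.04
6,Segment_3,cbct,0.61
7,Segment_3,cbct,3.72
4,Segment_4,cbct,1.11
1,CON,cbct,1.04
2,CON,cbct,2.33
3,CON,cbct,4.01
4,CON,cbct,6.68
5,CON,cbct,2.02
6,CON,cbct,3.62
7,CON,cbct,4.04
8,CON,cbct,2.38
9,CON,cbct,2.71
10,CON,cbct,2.41
11,CON,cbct,1.21
1,ANG,cbct,0.93
2,ANG,cbct,2.16
3,ANG,cbct,4.56
4,ANG,cbct,5.43
5,ANG,cbct,1.82
6,ANG,cbct,1.62
7,ANG,cbct,2.91
8,ANG,cbct,1.51
9,ANG,cbct,1.74
10,ANG,cbct,1.69
11,ANG,cbct,1.69
1,JUN,cbct,1.12
2,JUN,cbct,1.91
3,JUN,cbct,0.32
4,JUN,cbct,0.82
5,JUN,cbct,2.45
6,JUN,cbct,0.31
7,JUN,cbct,2.21
8,JUN,cbct,0.76
9,JUN,cbct,1.24
10,JUN,cbct,0.81
11,JUN,cbct,0.5
1,CON,navigation,1.09
2,CON,navigation,1.42
3,CON,navigation,1.51
4,CON,navigation,9.16
5,CON,navigation,1.38
6,CON,navigation,2.48
7,CON,navigation,2.79
8,CON,navigation,0.93
9,CON,navigation,2.27
10,CON,navigation,1.23
11,CON,navigation,2.23
1,ANG,navigation,1.42
2,ANG,navigation,0.71
3,ANG,navigation,1.73
4,ANG,navigation,5.64
5,ANG,navigation,1.19
6,ANG,navigation,1.05
7,ANG,navigation,2.23
8,ANG,navigation,1.72
9,ANG,navigation,2.17
10,ANG,navigation,1.43
11,ANG,navigation,1.8
1,JUN,navigation,1.89
2,JUN,navigation,3.11
3,JUN,navigation,2.29
4,JUN,navigation,2.02
5,JUN,navigation,1.12
6,JUN,navigation,1.42
7,JUN,navigation,5.78
8,JUN,navigation,1.08
9,JUN,navigation,1.27
10,JUN,navigation,0.72
11,JUN,navigation,2.22
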