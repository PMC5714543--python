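patient,location,posterior,gtv_cc,ptv_ck_cc,ptv_vmat_cc,prescription_gy,motion_3d_mm
1,RUL,0,1.2,6.1,11.2,60,7.6
2,RUL,0,73.8,118.7,188.1,60,22.8
3,RUL,0,7.5,20.3,34.8,60,4.6
4,RML,0,2.5,9.2,16.7,60,8.5
5,RUL,0,31.7,63.1,88.1,60,2.1
6,RML,0,7.8,22.7,40.8,60,4.6
7,RML,0,3.7,12.7,21.0,60,3.7
8,RLL,1,0.6,4.2,8.2,60,6.0
9,RLL,1,4.2,16.7,27.5,60,9.2
10,LLL,1,77.9,109.0,130.7,48,4.0
11,RLL,1,13.0,31.5,46.9,60,3.6
12,LUL,1,15.4,33.4,60.2,48,11.0
13,RUL,1,8.1,23.1,32.8,60,7.2
14,RLL,1,10.2,27.8,53.3,60,20.0
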