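patient,prescription_gy,fractions,ck_mu_per_gy,vmat_mu_per_gy,ck_beam_on_min,vmat_beam_on_min
1,60,3,167,68,16.7,11.2
2,60,3,259,58,25.9,11.5
3,60,3,172,65,17.2,14.3
4,60,3,236,61,23.6,10.9
5,60,3,204,60,20.4,12.5
6,60,3,205,46,20.5,8.5
7,60,3,200,53,20.0,10.8
8,60,3,195,46,19.5,8.3
9,60,3,357,54,35.7,10.7
10,48,6,193,82,15.5,14.3
11,60,3,287,55,28.7,9.9
12,48,6,271,88,21.7,13.3
13,60,3,190,57,19.0,10.7
14,60,3,199,54,19.9,9.9
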