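organ,ck_d1_gy,vmat_d1_gy
cord,21.5,30.1
esophagus,24.5,53.2
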