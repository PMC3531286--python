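surface,c_s,c_f,c_l,gamma
body,5.57,2.30,-1.74,1.93
head,19.52,1.24,-0.99,0.14
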