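sample_a	sample_b	pi_hat
NEL_M0008	TAU_F0006	0.1867
NEL_M0007	TAU_F0004	0.175
TAU_M0008	TAU_F0004	0.1271
TAU_M0010	TAU_F0004	0.1848
NEL_M0003	TAU_F0002	0.632
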