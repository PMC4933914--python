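sample_id	sex	population	qc_lrr_sd	qc_baf_drift	qc_waviness	BW	PWG
NEL_F0001	female	NEL	0.199400	0.007350	0.026900	-0.089886	0.107677
NEL_F0002	female	NEL	0.213500	0.005310	0.016300	-1.806011	0.225254
NEL_F0003	female	NEL	0.194200	0.002750	0.033500	-2.119992	0.404998
NEL_F0004	female	NEL	0.234700	0.002410	0.002200	1.482192	0.060457
NEL_F0005	female	NEL	0.123900	0.006360	0.009800	0.682272	-0.928257
NEL_F0006	female	NEL	0.121900	0.004560	0.025700	2.705376	1.880898
NEL_F0007	female	NEL	0.177500	0.002680	0.025500	-0.354956	0.398434
NEL_F0008	female	NEL	0.231600	0.001810	0.019000	-0.357153	0.245864
NEL_F0009	female	NEL	0.129800	0.006110	0.035700	1.579799	1.480699
NEL_F0010	female	NEL	0.246500	0.004740	0.006100	-0.547571	-0.371755
NEL_M0001	male	NEL	0.102600	0.001020	0.008500	-0.164473	-0.244899
NEL_M0002	male	NEL	0.114400	0.002200	0.026600	2.022991	3.764840
NEL_M0003	male	NEL	0.202800	0.003900	0.001400	-1.340620	2.189787
NEL_M0004	male	NEL	0.219500	0.005000	0.025000	-0.145607	1.342033
NEL_M0005	male	NEL	0.125000	0.006380	0.006200	1.450401	2.413774
NEL_M0006	male	NEL	0.238200	0.000490	0.033100	0.649677	0.244807
NEL_M0007	male	NEL	0.149900	0.004930	0.034600	1.491623	3.927013
NEL_M0008	male	NEL	0.140500	0.005160	0.019300	-0.651461	1.589125
NEL_M0009	male	NEL	0.247800	0.005240	0.026100	0.139615	1.408506
NEL_M0010	male	NEL	0.180200	0.000270	0.021100	0.462866	0.474383
TAU_F0001	female	TAU	0.238600	0.001830	0.019200	-0.790082	-0.001213
TAU_F0002	female	TAU	0.189600	0.000300	0.037100	-0.493457	-1.781933
TAU_F0003	female	TAU	0.275300	0.001830	0.002100	-1.282764	1.699671
TAU_F0004	female	TAU	0.244100	0.002400	0.032300	1.618119	1.124223
TAU_F0005	female	TAU	0.251200	0.004060	0.021400	2.161746	-0.787008
TAU_F0006	female	TAU	0.144800	0.005830	0.033700	-1.098901	0.005305
TAU_F0007	female	TAU	0.107600	0.003250	0.000900	-0.134492	-1.067887
TAU_F0008	female	TAU	0.166700	0.004280	0.039900	1.094771	-0.613775
TAU_F0009	female	TAU	0.199500	0.002590	0.026200	0.104903	-0.450270
TAU_F0010	female	TAU	0.266200	0.001450	0.014000	-1.080424	-0.054165
TAU_M0001	male	TAU	0.275900	0.000830	0.012800	-0.779296	1.810177
TAU_M0002	male	TAU	0.226900	0.000130	0.015000	-1.533185	2.199674
TAU_M0003	male	TAU	0.137700	0.000200	0.010300	0.137474	0.760613
TAU_M0004	male	TAU	0.189200	0.000330	0.038700	1.911501	2.231666
TAU_M0005	male	TAU	0.186600	0.007530	0.029500	-0.268195	1.239629
TAU_M0006	male	TAU	0.166900	0.002120	0.020300	-0.469146	1.459505
TAU_M0007	male	TAU	0.226400	0.005190	0.002100	-1.291681	1.603981
TAU_M0008	male	TAU	0.148100	0.000620	0.006600	-0.323085	2.670604
TAU_M0009	male	TAU	0.260400	0.001040	0.018700	0.666866	1.589085
TAU_M0010	male	TAU	0.110000	0.006920	0.025500	-0.968686	0.700236
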