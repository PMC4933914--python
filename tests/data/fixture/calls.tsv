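sample_id	chrom	start	end	cn	n_probes
NEL_F0001	chr1	400500	430500	0	11
NEL_F0002	chr1	400500	430500	0	11
NEL_F0003	chr1	400500	430500	0	11
NEL_F0004	chr1	400500	430500	0	11
NEL_F0005	chr1	400500	430500	0	11
NEL_F0006	chr1	400500	430500	0	11
NEL_F0007	chr1	400500	430500	0	11
NEL_F0008	chr1	400500	430500	0	11
NEL_F0009	chr1	400500	430500	0	11
NEL_F0010	chr1	400500	430500	0	11
TAU_F0001	chr1	400500	430500	0	11
TAU_F0002	chr1	400500	430500	0	11
TAU_F0003	chr1	400500	430500	0	11
TAU_F0004	chr1	400500	430500	0	11
TAU_F0005	chr1	400500	430500	0	11
TAU_F0006	chr1	400500	430500	0	11
TAU_F0007	chr1	400500	430500	0	11
TAU_F0008	chr1	400500	430500	0	11
TAU_F0009	chr1	400500	430500	0	11
TAU_F0010	chr1	400500	430500	0	11
TAU_M0001	chr1	910500	988500	1	27
NEL_F0002	chr1	913500	985500	1	25
NEL_M0006	chr1	913500	985500	1	25
TAU_M0006	chr1	913500	985500	1	25
TAU_F0003	chr1	916500	985500	1	24
NEL_F0004	chr1	919500	982500	1	22
NEL_M0010	chr1	919500	994500	1	26
TAU_F0004	chr1	922500	985500	1	22
TAU_M0005	chr1	922500	988500	1	23
NEL_F0001	chr1	922500	994500	1	25
NEL_M0008	chr1	922500	994500	1	25
TAU_M0010	chr1	922500	994500	1	25
TAU_M0006	chr1	1504500	1519500	1	6
TAU_M0004	chr1	1504500	1522500	1	7
TAU_M0002	chr1	1507500	1519500	1	5
TAU_M0007	chr1	1513500	1516500	1	2
NEL_F0003	chr1	1576500	1582500	1	3
NEL_F0007	chr1	1579500	1582500	1	2
TAU_M0008	chr1	1579500	1585500	1	3
NEL_F0002	chr1	1582500	1582500	1	1
NEL_F0004	chr1	1582500	1582500	1	1
NEL_F0010	chr1	1582500	1582500	1	1
NEL_M0007	chr1	1582500	1582500	1	1
NEL_M0009	chr1	1582500	1582500	1	1
TAU_F0002	chr1	1582500	1582500	1	1
TAU_M0007	chr1	1582500	1582500	1	1
NEL_F0006	chr1	1582500	1585500	1	2
TAU_M0006	chr1	1582500	1588500	1	3
TAU_M0010	chr1	1582500	1591500	1	4
NEL_F0001	chr2	298500	319500	3	8
NEL_F0003	chr2	298500	319500	3	8
NEL_F0006	chr2	298500	319500	3	8
NEL_F0010	chr2	298500	319500	3	8
TAU_F0001	chr2	298500	319500	3	8
TAU_F0002	chr2	298500	319500	3	8
TAU_F0005	chr2	298500	319500	3	8
TAU_F0009	chr2	298500	319500	3	8
NEL_F0003	chr2	1360500	1369500	3	4
NEL_F0001	chr2	1498500	1552500	1	19
NEL_F0004	chr2	1498500	1552500	1	19
NEL_F0005	chr2	1498500	1552500	1	19
NEL_F0006	chr2	1498500	1552500	1	19
NEL_F0007	chr2	1498500	1552500	1	19
NEL_F0008	chr2	1498500	1552500	1	19
NEL_F0009	chr2	1498500	1552500	1	19
NEL_M0001	chr2	1498500	1552500	1	19
NEL_M0002	chr2	1498500	1552500	1	19
NEL_M0004	chr2	1498500	1552500	1	19
NEL_M0005	chr2	1498500	1552500	1	19
NEL_M0006	chr2	1498500	1552500	1	19
NEL_M0008	chr2	1498500	1552500	1	19
NEL_M0009	chr2	1498500	1552500	1	19
TAU_F0009	chr2	1498500	1552500	1	19
TAU_M0009	chr2	1498500	1552500	1	19
TAU_M0007	chr2	1690500	1795500	1	36
NEL_F0004	chr2	1693500	1786500	1	32
TAU_F0006	chr2	1696500	1795500	1	34
NEL_F0006	chr2	1702500	1792500	1	31
TAU_M0002	chr2	1702500	1798500	1	33
TAU_F0003	chr2	1882500	1885500	1	2
NEL_M0010	chr2	1882500	1894500	1	5
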