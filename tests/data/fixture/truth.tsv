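kind	name	chrom	start	end	class	cn	n_carriers	true_freq
fp	FP1	chr1	400500	430500	Y-like	0	20	
fp	FP2	chr2	298500	319500	X-like	3	8	
diff	DIFF1	chr2	1498500	1552500	NEL=0.73;TAU=0.055	1	16	
locus	L1	chr2	1696500	1792500		1	5	0.066279
locus	L2	chr2	1879500	1891500		1	2	0.103691
locus	L3	chr1	1315500	1318500		1	0	0.073227
locus	L4	chr1	1582500	1585500		1	13	0.500000
locus	L5	chr1	1927500	1930500		1	0	0.003096
locus	L6	chr2	1366500	1375500		3	1	0.095074
locus	L7	chr1	916500	988500		1	12	0.363637
locus	L8	chr1	1510500	1519500		1	4	0.043045
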